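# Methods

This note documents the statistical models the package implements, the
defaults it ships, and the choices made where the methodology was
genuinely open.

## Data model

A survey is a set of georeferenced host plants. Each plant carries
integer larval counts for three instar groups — 1st+2nd pooled (the two
are indistinguishable in the field), 3rd, and 4th — plus a derived
"average" series (the per-plant mean over the three groups), morphology
covariates (plant height and crown width in cm, ground diameter in mm)
and optionally a split of each group's count over five 20-cm height
classes (0–20 … 81–100 cm). Coordinates are planar metres; lon/lat
input is projected with a local equirectangular projection about the
centroid, which is sub-metre accurate at the sub-kilometre extents of a
single field site. Coincident sample points are rejected rather than
jittered, because they make the kriging system singular.

## Semivariogram estimation

The empirical semivariogram is the classical (Matheron) estimator,
omnidirectional, with pairs binned as (k·w, (k+1)·w] by separation
distance. Defaults: lag width w = 10 m (the survey spacing) and maximum
lag equal to half the maximum pairwise distance — the standard
rules-of-thumb; both are configurable. Empty bins are dropped; γ(0) = 0
by convention with the nugget as the limit from the right. No trend
removal or transformation is applied before estimation.

## Variogram models and fitting

Four families are implemented, all parameterised by nugget C₀, sill
C₀+C and an *effective* range A, so that the fitted "range" is a single
comparable number across families (the convention of GS+/ArcGIS-style
software):

* spherical: γ = C₀ + C(1.5 h/A − 0.5 (h/A)³) for h ≤ A, else C₀+C
* exponential: γ = C₀ + C(1 − e^(−3h/A))
* gaussian: γ = C₀ + C(1 − e^(−3h²/A²))
* linear: γ = C₀ + C·min(h/A, 1)

Fitting minimises Σ N(h_b)·(γ_model − γ_emp)² subject to C₀ ≥ 0, C ≥ 0,
A ∈ (0, 2·max_lag], via bounded trust-region least squares with a
deterministic multistart over initial ranges (0.1–2 × max_lag).
Cressie-style N/γ² and unweighted schemes are available by flag. The
returned fit is never worse (in weighted SSE) than the best flat
pure-nugget model, which is always evaluated as a fallback. The linear
family is implemented but excluded from the default model-selection
candidate set (spherical, exponential, gaussian), matching the three
families the motivating analysis actually compared.

## Ordinary kriging

Prediction uses the standard ordinary-kriging system in semivariogram
form with a Lagrange multiplier enforcing unbiasedness; the
neighbourhood is global (all samples for every target), appropriate at
n ≈ 63 and avoiding an arbitrary search radius. Systems with condition
number above 10¹² are reported as singular together with the offending
geometry. The nugget is treated as micro-scale variance: data-to-target
semivariances at exactly zero distance use the right-limit (the
nugget), so a nugget-free model interpolates exactly at data locations
while a pure-nugget model smooths every prediction to the sample mean.
Kriging variances are clipped to zero within −10⁻⁹.

Leave-one-out cross-validation predicts each sample from the remaining
n−1 and reports mean error, RMSE, and the slope β₀, intercept β₁ and R²
of the OLS regression of *observed on predicted* (the ArcGIS
cross-validation convention; the direction is otherwise arbitrary).
With degenerate constant predictions the regression is undefined and
(β₀, β₁, R²) are reported as (0, mean(obs), 0).

Model selection ranks the candidate families on the five criteria —
|β₀−1|, |β₁|, −R², |ME|, RMSE, all ascending — and picks the lowest
mean rank, breaking ties by RMSE and then by a fixed family order
(spherical, exponential, gaussian, linear). Rank aggregation was chosen
because the five stated criteria routinely disagree on real metric
tables; no single-criterion rule reproduces sensible choices.

Surfaces are predicted on a regular grid covering the sample bounding
box padded by one spacing, default resolution 2 m (no standard exists;
2 m resolves the 10 m design comfortably), exported as Esri ASCII grid.

## Spatial dependence (LSD)

LSD is computed from the fitted nugget and sill. Two conventions exist
in the literature and they sum to one: the *structural* ratio
C/(C₀+C) and the Cambardella-style *nugget ratio* C₀/(C₀+C). The
default is structural, because the motivating analysis's tabulated
values all follow it; the nugget-ratio is exposed for users replicating
Cambardella-style classifications. Note the inherited quirk: applying
the strong (< 0.25) / moderate / weak (> 0.75) thresholds to the
structural ratio inverts the usual Cambardella direction — a survey
with a *small* structural share classifies as *strong* dependence. The
package applies the thresholds to whichever ratio the user selects, as
the source analysis did, and does not attempt to resolve the intent;
boundary values 0.25 and 0.75 are assigned to "moderate".

The distribution label is operationalised as: *random* when the
structural share of the sill is below 5% (pure-nugget fit); *regular*
when the empirical semivariance decreases significantly with lag
(Spearman ρ < 0, p < 0.05) — reported for completeness but not expected
in aggregated insect data; *aggregate* when the semivariance rises with
lag and the fitted range exceeds the minimum lag.

## Poisson GLM

Observations are (plant × height-class) cells; the response is the cell
count and "distribution height" is the class midpoint in cm (10, 30,
50, 70, 90) treated as a continuous 1-df term. Covariates are left on
their raw cm/mm scales. The default term set is the four main effects
plus the single distribution-height × ground-diameter interaction; all
three height interactions can be requested and pruned by VIF screening.
The fit is a log-link Poisson GLM by IRLS (relative-deviance tolerance
1e-8, 100 iterations; the fitting engine is statsmodels), with per-term
Wald χ² = (β̂/SE)² on 1 df. No exposure offset (all plants observed
equally) and no overdispersion correction are applied. VIF screening
regresses each retained predictor on the others (with intercept) and
iteratively removes the highest VIF above 5 until all pass; perfectly
collinear terms get VIF = ∞ and go first.

## Vertical summaries

Per-class statistics are over all plants, zeros included. Quartiles use
linear interpolation; the per-class standard deviation is the sample
(n−1) form, defined as 0 for a single plant. The modal class is the
arg-max of class means, ties to the lower class. Counts on plants
taller than 100 cm are carried in the top class, with a warning.

## Synthetic surveys

The generator emulates the survey design: a near-square lattice of
quadrat centres at 10 m spacing truncated to 63 points (layouts are
deterministic), morphology from truncated normals, and counts from a
log-Gaussian Cox-style construction. The expected count of one
(plant × class × group) cell is

    λ = exp(η_GLM + f + hotspot) · 5 · u_class

where η_GLM is the cell's linear predictor under known coefficients,
f a zero-mean latent Gaussian random field (structured part realised by
Cholesky factorisation of C(d) = sill − γ(d) with a 1e-10 diagonal
jitter, nugget added as independent noise), hotspot an optional radial
log-trend (default "stage": young instars centre-loaded, 4th instars
edge-loaded, amplitude 0.6), and u the vertical-profile weight
renormalised over the classes below the plant's height (a profile with
no feasible class raises an error). The linear predictor is per *cell*,
so the per-plant group total is the 5-cell sum. Cells are drawn as
independent Poissons, which is distributionally identical to drawing
the plant total and splitting it multinomially. With the field off, the
profile uniform/None and all classes feasible, cells are exactly
independent Poisson(exp(Xβ)) — the configuration used to validate the
GLM machinery against a correctly-specified model.

Defaults and their reasoning:

* **Latent-field truths** keep each group's published fitted range and
  nugget:sill ratio (young instars: short-range Gaussian, high nugget
  share; old instars: long-range spherical, low nugget share) but set
  the log-scale sill to 0.16 (field sd 0.4 ≈ 40% CV of infestation
  intensity between plants). The published sills are count-scale
  semivariances; using them verbatim as log-scale variances would imply
  far heavier overdispersion than insect-count data show. Any model can
  be passed verbatim to `simulate_latent_field`, which is what the
  parameter-recovery study does.
* **GLM truth** uses the published coefficient magnitudes and signs
  (distribution height +0.002, plant height +0.004, crown width
  +0.003, ground diameter −0.010, interaction +0.0001), an intercept of
  0 and group offsets (0, +0.3, −0.4) making the 3rd instar the most
  abundant, yielding realistic per-plant totals (tens of larvae).
* **Morphology** is synthetic (no distributions were published):
  plant height ~ N(100, 20²) cm truncated at 40, crown width
  ~ N(70, 15²) cm truncated at 20, ground diameter ~ N(12, 3²) mm
  truncated at 4 — plausible desert-shrub scales; covariates are drawn
  independently.
* **Vertical profiles** place 1st+2nd instars mostly above 60 cm, 3rd
  instars in 41–60 cm, 4th instars in 21–50 cm.

All randomness flows from one seed through named `SeedSequence`
substreams (morphology, one per group's field, counts); a fixed seed
gives byte-identical CSV output.

What the generator does *not* emulate: temporal dynamics across repeat
survey dates, correlation among morphology covariates, interspecific
effects (boring pests, grazing), and non-lattice sampling. Passing
tests therefore demonstrate the estimators' correctness under the
stated generative assumptions, not robustness to every feature of real
field data.

## Validation study sizes

The recovery studies are sized to run comfortably on a desk machine:
variogram/oracle equivalence on 50 random instances of ≤ 200 points;
kriging weight checks over 1,000 random model/target draws; Gaussian
random-field parameter recovery on a 200-point lattice with 20
replicates (median relative errors of nugget, sill and range each
within 25% at the spherical truth C₀ = 0.100, sill = 0.260,
A = 52.5 m); GLM recovery on 400 plants × 5 classes = 2,000 cells with
20 replicates (each coefficient within 3 SE of truth in ≥ 95% of
replicates under the correctly-specified configuration; morphology
coefficient signs recovered in ≥ 18/20 full-default surveys).

## Known limitations

* Isotropy is assumed throughout; no directional variograms.
* No universal/co-kriging; the trend is assumed constant (ordinary
  kriging's local-mean assumption).
* The Poisson GLM ignores spatial correlation between cells of nearby
  plants (no GLMM); standard errors are accordingly optimistic for
  strongly structured data.
* Published coefficient and cross-validation tables from the motivating
  survey cannot be reproduced numerically without the undeposited raw
  data; the package validates the machinery on synthetic data and the
  published worked ratios instead.
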