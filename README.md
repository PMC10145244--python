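# geopest

Geostatistical analysis of insect pest count surveys.

`geopest` is a Python package for ecologists analysing georeferenced
counts of insects on host plants — the motivating case being larvae of
the leaf beetle *Chrysolina aeruginosa* on the desert shrub *Artemisia
ordosica*, surveyed as 63 checkerboard sample points at 10 m spacing,
with per-plant larval counts split by instar group (1st+2nd pooled,
3rd, 4th) and by 20-cm height class. It covers the full workflow such a
survey needs:

* **Empirical semivariograms.** The omnidirectional estimator
  γ(h) = 1/(2N(h)) Σ [Z(xᵢ) − Z(xᵢ+h)]², binned by lag distance.
* **Variogram model fitting.** Spherical, exponential, Gaussian and
  linear families (effective-range parameterisation), fitted by
  weighted least squares with pair-count weights.
* **Ordinary kriging.** Global-neighbourhood prediction with a Lagrange
  multiplier enforcing Σwᵢ = 1, leave-one-out cross-validation scored by
  the five standard metrics (β₀, β₁, R², RMSE, ME), rank-aggregation
  model selection, and regular-grid surface prediction.
* **Spatial-dependence classification.** LSD = C/(C₀+C) (structural
  convention; the nugget-ratio C₀/(C₀+C) is available), classed as
  strong (< 0.25), moderate (0.25–0.75) or weak (> 0.75), plus an
  aggregate/random/regular distribution label.
* **Poisson GLM.** Cell counts (plant × height class) modelled on
  distribution height, plant height, crown width and ground diameter
  with a log link, after iterative VIF > 5 collinearity screening.
* **Vertical distribution.** Per-height-class means, medians, quartiles
  and the modal class per instar group.
* **Synthetic surveys.** A generator producing checkerboard layouts,
  latent Gaussian random fields with known variograms, Poisson count
  noise, morphology covariates and stage-dependent vertical placement,
  so the whole pipeline is testable without field data.

The geostatistical estimators are scikit-learn-style
(`VariogramEstimator`, `OrdinaryKriging`, `PoissonCountGLM` with
`fit`/`predict`); the module-level functions wrap them.

## Worked example

```python
from geopest import (SimulationConfig, simulate_survey, empirical_variogram,
                     fit_variogram, loo_cross_validate, select_model,
                     compute_lsd)
from geopest.samples import InstarGroup
from geopest.structure import build_structure

pts = simulate_survey(SimulationConfig(seed=42))     # 63 plants
emp = empirical_variogram(pts, InstarGroup.AVG)      # lag width 10 m
models = {f: fit_variogram(emp, f)
          for f in ("spherical", "exponential", "gaussian")}
cvs = {f: loo_cross_validate(pts, InstarGroup.AVG, m)
       for f, m in models.items()}
best = select_model(cvs)
row = build_structure(InstarGroup.AVG, models[best], emp)
print(best, round(row.lsd, 3), row.dependence_class, row.distribution)
```

prints

```
spherical 0.239 strong aggregate
```

i.e. for this simulated survey the spherical model wins the
cross-validation ranking; its fitted nugget (17.19) is a large share of
the sill (22.59), so the structural ratio LSD = (sill − nugget)/sill =
0.239 falls below 0.25 (strong spatial dependence under the convention
in which the thresholds are applied to the structural ratio), and the
rising semivariance marks an aggregated (patchy) larval distribution.

The same analysis from the shell, with kriged surface maps (`.asc`),
variogram plots, GLM and vertical reports and a hash manifest:

```sh
geopest run-all --simulate --seed 42 --out-dir out/
geopest run-all --input survey.csv --out-dir out/   # your own data
```

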