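"""Synthetic field-survey generator.

Emulates a checkerboard insect survey: a regular lattice of sample
plants (default 63 points at 10 m spacing), plant morphology drawn from
truncated normals, a latent Gaussian random field per instar group
giving spatially aggregated infestation intensity, Poisson count noise,
and stage-dependent vertical placement over five 20-cm height classes.

The construction is log-Gaussian Cox style: the expected count in one
(plant x height-class) cell is

    lambda = exp(eta_glm + f + hotspot) * 5 * u_class

where ``eta_glm`` is the morphology linear predictor with known
coefficients, ``f`` the latent spatial field, ``hotspot`` an optional
radial trend (young instars centre-loaded, old instars edge-loaded),
and ``u_class`` the vertical-profile weight renormalised over the
classes a plant's height actually offers. With no field, no hotspot
and a uniform feasible profile the cell counts are exactly independent
Poisson draws from the GLM mean, which makes the generator a
correctly-specified test bed for the regression stage. Each cell count
is drawn Poisson at its own rate — distributionally identical to
drawing the plant total and splitting it multinomially.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.spatial.distance import cdist
from scipy.stats import truncnorm

from .samples import (
    HEIGHT_CLASS_BOUNDS,
    HEIGHT_CLASS_MIDPOINTS,
    InstarGroup,
    OBSERVED_GROUPS,
    SamplePoint,
    SurveyDesign,
)
from .variogram import VariogramModel

__all__ = [
    "SimulationConfig",
    "default_variogram_truth",
    "default_vertical_profiles",
    "generate_layout",
    "simulate_latent_field",
    "simulate_survey",
    "load_config",
    "save_config",
]

#: Log-scale sill of the default latent fields. The default truths keep
#: each group's fitted range and nugget:sill ratio but rescale the sill
#: to the log scale (field sd 0.4, i.e. ~40% coefficient of variation of
#: infestation intensity between plants — a moderate, realistic
#: aggregation level for insect counts).
LATENT_LOG_SILL = 0.16


def default_variogram_truth() -> dict[InstarGroup, VariogramModel]:
    """Latent-field truths per group: published spatial structure, log scale.

    Ranges (m) and nugget:sill ratios follow the fitted per-group count
    variograms (young instars: short-range Gaussian with high nugget
    share; old instars: long-range spherical with low nugget share);
    sills are rescaled to :data:`LATENT_LOG_SILL` on the log scale.
    """
    raw = {
        InstarGroup.I12: ("gaussian", 51.772, 0.932, 1.031),
        InstarGroup.I3: ("gaussian", 117.952, 0.670, 0.868),
        InstarGroup.I4: ("spherical", 131.278, 0.365, 1.178),
    }
    out = {}
    for g, (fam, rng, c0, sill) in raw.items():
        ratio = c0 / sill
        out[g] = VariogramModel(
            family=fam,
            nugget=ratio * LATENT_LOG_SILL,
            sill=LATENT_LOG_SILL,
            range=rng,
        )
    return out


def default_vertical_profiles() -> dict[InstarGroup, tuple[float, ...]]:
    """Stage-dependent height-class preferences (probabilities, sum 1).

    Young (1st+2nd) instars favour the upper plant (>60 cm), 3rd
    instars the middle (41-60 cm), 4th instars the middle-lower part.
    """
    return {
        InstarGroup.I12: (0.05, 0.05, 0.15, 0.35, 0.40),
        InstarGroup.I3: (0.05, 0.15, 0.45, 0.25, 0.10),
        InstarGroup.I4: (0.15, 0.35, 0.30, 0.15, 0.05),
    }


#: GLM truth defaults: slope magnitudes and signs follow the fitted
#: morphology effects (distribution height +, plant height +, crown
#: width +, ground diameter -, height x diameter interaction +); the
#: intercept is set so plants carry realistic totals (tens of larvae).
DEFAULT_GLM_TRUTH: dict[str, float] = {
    "intercept": 0.0,
    "distribution_height": 0.002,
    "plant_height": 0.004,
    "crown_width": 0.003,
    "ground_diameter": -0.010,
    "interaction": 0.0001,
}

#: Per-group additive intercept offsets (3rd instar most abundant).
DEFAULT_GROUP_OFFSETS: dict[InstarGroup, float] = {
    InstarGroup.I12: 0.0,
    InstarGroup.I3: 0.3,
    InstarGroup.I4: -0.4,
}

#: Morphology distributions: (mean, sd, lower truncation).
#: Desert-shrub scales; synthetic defaults, not field-measured values.
DEFAULT_MORPHOLOGY: dict[str, tuple[float, float, float]] = {
    "plant_height": (100.0, 20.0, 40.0),  # cm
    "crown_width": (70.0, 15.0, 20.0),  # cm
    "ground_diameter": (12.0, 3.0, 4.0),  # mm
}


@dataclass
class SimulationConfig:
    """Everything the survey generator needs; ``seed`` is mandatory.

    ``hotspot`` is one of ``stage`` (young instars centre-loaded, old
    instars edge-loaded), ``center``, ``edge`` (same radial trend for
    every group) or ``none``. ``variogram_truth=None`` disables the
    latent field; ``vertical_profile=None`` lets the GLM's
    distribution-height terms drive vertical placement alone.
    """

    seed: int
    design: SurveyDesign = field(default_factory=SurveyDesign)
    variogram_truth: dict[InstarGroup, VariogramModel] | None = field(
        default_factory=default_variogram_truth
    )
    glm_truth: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GLM_TRUTH)
    )
    group_offsets: dict[InstarGroup, float] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_OFFSETS)
    )
    vertical_profile: dict[InstarGroup, tuple[float, ...]] | None = field(
        default_factory=default_vertical_profiles
    )
    morphology: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MORPHOLOGY)
    )
    hotspot: str = "stage"
    hotspot_amplitude: float = 0.6

    def __post_init__(self) -> None:
        if self.hotspot not in ("stage", "center", "edge", "none"):
            raise ValueError(f"unknown hotspot mode {self.hotspot!r}")
        if self.vertical_profile is not None:
            for g, p in self.vertical_profile.items():
                if len(p) != 5 or abs(sum(p) - 1.0) > 1e-9 or min(p) < 0:
                    raise ValueError(
                        f"vertical profile for {g.value} must be 5 probabilities summing to 1"
                    )
        for name, (mean, sd, low) in self.morphology.items():
            if sd <= 0:
                raise ValueError(f"morphology sd for {name} must be > 0")


def generate_layout(design: SurveyDesign, seed: int | None = None) -> np.ndarray:
    """Checkerboard lattice of quadrat centres, (n_points, 2) metres.

    A near-square lattice at the design spacing, centred in the extent,
    truncated row-major to ``n_points``. Deterministic (the seed is
    accepted for interface uniformity only).
    """
    n = design.n_points
    side = math.ceil(math.sqrt(n))
    span = (side - 1) * design.spacing
    if span + design.quadrat_side > min(design.extent):
        raise ValueError(
            f"design infeasible: {side}x{side} lattice at {design.spacing} m "
            f"spacing does not fit extent {design.extent}"
        )
    x0 = (design.extent[0] - span) / 2.0
    y0 = (design.extent[1] - span) / 2.0
    pts = [
        (x0 + col * design.spacing, y0 + row * design.spacing)
        for row in range(side)
        for col in range(side)
    ]
    return np.array(pts[:n], dtype=float)


def simulate_latent_field(
    layout: np.ndarray,
    model: VariogramModel,
    seed: int | np.random.SeedSequence,
    jitter: float = 1e-10,
) -> np.ndarray:
    """Zero-mean Gaussian random field with the given variogram.

    The structured part has covariance C(d) = (sill - nugget) -
    gamma_struct(d), realised by Cholesky factorisation of the
    point-covariance matrix (with a small diagonal jitter); the nugget
    is added as independent noise. Deterministic per seed.
    """
    layout = np.asarray(layout, dtype=float)
    n = layout.shape[0]
    rng = np.random.default_rng(seed)
    c = model.structural
    d = cdist(layout, layout)
    # structural covariance: c - (gamma(d) - nugget) for d > 0, c on the diagonal
    gamma = model.gamma(d.ravel()).reshape(d.shape)
    cov = np.where(d > 0, model.sill - gamma, c)
    cov = cov + jitter * np.eye(n)
    if c > 0:
        try:
            chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "invalid covariance: matrix not positive semi-definite"
            ) from exc
        z = chol @ rng.standard_normal(n)
    else:
        z = np.zeros(n)
    if model.nugget > 0:
        z = z + math.sqrt(model.nugget) * rng.standard_normal(n)
    return z


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, low: float, size: int
) -> np.ndarray:
    a = (max(low, 0.0) - mean) / sd
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def _hotspot_term(
    mode: str, amplitude: float, group: InstarGroup, r_frac: np.ndarray
) -> np.ndarray:
    """Radial log-mean trend; ``r_frac`` is distance to centre over max."""
    if mode == "none" or amplitude == 0:
        return np.zeros_like(r_frac)
    if mode == "center":
        return amplitude * (1.0 - r_frac)
    if mode == "edge":
        return amplitude * r_frac
    # stage-dependent: young larvae centre-loaded, old larvae edge-loaded
    if group is InstarGroup.I12:
        return amplitude * (1.0 - r_frac)
    if group is InstarGroup.I4:
        return amplitude * r_frac
    return np.zeros_like(r_frac)


def simulate_survey(config: SimulationConfig) -> list[SamplePoint]:
    """Draw one complete synthetic survey.

    Returns validated-shape sample points with per-group counts and
    height-class records. Fixed seed implies byte-identical output.
    """
    ss = np.random.SeedSequence(config.seed)
    morph_ss, field_ss, count_ss = ss.spawn(3)
    layout = generate_layout(config.design, config.seed)
    n = layout.shape[0]

    rng_m = np.random.default_rng(morph_ss)
    morph = {
        name: _truncated_normal(rng_m, *config.morphology[name], size=n)
        for name in ("plant_height", "crown_width", "ground_diameter")
    }

    fields: dict[InstarGroup, np.ndarray] = {}
    field_children = field_ss.spawn(len(OBSERVED_GROUPS))
    for g, child in zip(OBSERVED_GROUPS, field_children):
        if config.variogram_truth is not None and g in config.variogram_truth:
            fields[g] = simulate_latent_field(layout, config.variogram_truth[g], child)
        else:
            fields[g] = np.zeros(n)

    centre = layout.mean(axis=0)
    r = np.linalg.norm(layout - centre, axis=1)
    r_frac = r / r.max() if r.max() > 0 else np.zeros(n)

    beta = config.glm_truth
    mids = np.asarray(HEIGHT_CLASS_MIDPOINTS)
    lowers = np.asarray([b[0] for b in HEIGHT_CLASS_BOUNDS])
    rng_c = np.random.default_rng(count_ss)

    points: list[SamplePoint] = []
    counts_all: list[dict[InstarGroup, int]] = [dict() for _ in range(n)]
    hcc_all: list[dict[InstarGroup, tuple[int, ...]]] = [dict() for _ in range(n)]
    for g in OBSERVED_GROUPS:
        hot = _hotspot_term(config.hotspot, config.hotspot_amplitude, g, r_frac)
        profile = (
            np.asarray(config.vertical_profile[g], dtype=float)
            if config.vertical_profile is not None
            else np.ones(5) / 5.0
        )
        for i in range(n):
            allowed = lowers < morph["plant_height"][i]
            if not allowed.any() or not profile[allowed].sum() > 0:
                raise ValueError(
                    "vertical profile infeasible: no feasible height class "
                    f"for plant {i} (height {morph['plant_height'][i]:.1f} cm)"
                )
            u = np.where(allowed, profile, 0.0)
            u = u / u.sum()
            eta = (
                beta["intercept"]
                + config.group_offsets.get(g, 0.0)
                + beta["distribution_height"] * mids
                + beta["plant_height"] * morph["plant_height"][i]
                + beta["crown_width"] * morph["crown_width"][i]
                + beta["ground_diameter"] * morph["ground_diameter"][i]
                + beta["interaction"] * mids * morph["ground_diameter"][i]
                + fields[g][i]
                + hot[i]
            )
            lam = np.exp(eta) * 5.0 * u
            cells = rng_c.poisson(lam)
            hcc_all[i][g] = tuple(int(v) for v in cells)
            counts_all[i][g] = int(cells.sum())

    for i in range(n):
        points.append(
            SamplePoint(
                id=f"p{i + 1:03d}",
                x=float(layout[i, 0]),
                y=float(layout[i, 1]),
                counts=counts_all[i],
                plant_height=float(morph["plant_height"][i]),
                crown_width=float(morph["crown_width"][i]),
                ground_diameter=float(morph["ground_diameter"][i]),
                height_class_counts=hcc_all[i],
            )
        )
    return points


# ---------------------------------------------------------------------------
# Config (de)serialisation


def save_config(config: SimulationConfig, path: str | Path) -> None:
    """Write a simulation config as YAML."""
    doc: dict = {
        "seed": config.seed,
        "design": {
            "n_points": config.design.n_points,
            "spacing": config.design.spacing,
            "quadrat_side": config.design.quadrat_side,
            "extent": list(config.design.extent),
        },
        "glm_truth": dict(config.glm_truth),
        "group_offsets": {g.value: v for g, v in config.group_offsets.items()},
        "morphology": {k: list(v) for k, v in config.morphology.items()},
        "hotspot": config.hotspot,
        "hotspot_amplitude": config.hotspot_amplitude,
    }
    if config.variogram_truth is not None:
        doc["variogram_truth"] = {
            g.value: {
                "family": m.family,
                "nugget": m.nugget,
                "sill": m.sill,
                "range": m.range,
            }
            for g, m in config.variogram_truth.items()
        }
    if config.vertical_profile is not None:
        doc["vertical_profile"] = {
            g.value: list(p) for g, p in config.vertical_profile.items()
        }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_config(path: str | Path) -> SimulationConfig:
    """Read a YAML simulation config written by :func:`save_config`."""
    doc = yaml.safe_load(Path(path).read_text())
    if "seed" not in doc:
        raise ValueError("config must set a seed")
    design = SurveyDesign(**doc["design"]) if "design" in doc else SurveyDesign()
    if isinstance(design.extent, list):
        design.extent = tuple(design.extent)
    kwargs: dict = {"seed": int(doc["seed"]), "design": design}
    if "variogram_truth" in doc:
        kwargs["variogram_truth"] = {
            InstarGroup(k): VariogramModel(**v)
            for k, v in doc["variogram_truth"].items()
        }
    elif doc.get("no_latent_field"):
        kwargs["variogram_truth"] = None
    if "glm_truth" in doc:
        kwargs["glm_truth"] = {k: float(v) for k, v in doc["glm_truth"].items()}
    if "group_offsets" in doc:
        kwargs["group_offsets"] = {
            InstarGroup(k): float(v) for k, v in doc["group_offsets"].items()
        }
    if "vertical_profile" in doc:
        kwargs["vertical_profile"] = {
            InstarGroup(k): tuple(float(x) for x in v)
            for k, v in doc["vertical_profile"].items()
        }
    if "morphology" in doc:
        kwargs["morphology"] = {
            k: tuple(float(x) for x in v) for k, v in doc["morphology"].items()
        }
    for key in ("hotspot", "hotspot_amplitude"):
        if key in doc:
            kwargs[key] = doc[key]
    return SimulationConfig(**kwargs)
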