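"""Spatial-dependence classification from fitted variogram parameters.

The level of spatial dependence (LSD) is a ratio built from the nugget
C0 and the sill C0 + C of a fitted variogram. Two conventions are in
circulation:

* ``structural`` — C / (C0 + C), the spatially structured share of the
  total variance (the default here);
* ``nugget_ratio`` — C0 / (C0 + C), the Cambardella-style nugget share.

The two sum to one. LSD values below 0.25 are classed as strong
spatial dependence, values between 0.25 and 0.75 (inclusive) as
moderate, and values above 0.75 as weak. The thresholds are applied to
whichever convention is chosen.

A fitted variogram plus its empirical curve also yields a coarse
distribution label: *aggregate* (spatially clumped) when there is
non-trivial structural variance and the semivariance rises with lag,
*random* when the fit is (near) pure nugget, and *regular* for a
significantly decreasing semivariance.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import spearmanr

from .samples import InstarGroup
from .variogram import EmpiricalVariogram, VariogramModel

__all__ = [
    "SpatialStructure",
    "compute_lsd",
    "classify_dependence",
    "label_distribution",
    "build_structure",
]

#: Structural-variance share below which a fit is treated as pure nugget.
RANDOM_STRUCTURAL_FRACTION = 0.05

#: Significance level for a decreasing (regular) empirical variogram.
REGULAR_ALPHA = 0.05


@dataclass
class SpatialStructure:
    """One instar group's fitted spatial structure and its labels."""

    group: InstarGroup
    family: str
    range: float
    nugget: float
    sill: float
    lsd: float
    dependence_class: str
    distribution: str


def compute_lsd(nugget: float, sill: float, convention: str = "structural") -> float:
    """Level of spatial dependence from a nugget and a sill.

    ``structural`` returns (sill - nugget) / sill; ``nugget_ratio``
    returns nugget / sill. Requires 0 <= nugget <= sill and sill > 0.
    """
    if sill <= 0:
        raise ValueError("degenerate sill: sill must be > 0")
    if not 0 <= nugget <= sill:
        raise ValueError("require 0 <= nugget <= sill")
    if convention == "structural":
        return (sill - nugget) / sill
    if convention == "nugget_ratio":
        return nugget / sill
    raise ValueError(f"unknown LSD convention {convention!r}")


def classify_dependence(lsd: float) -> str:
    """Classify an LSD ratio as strong, moderate or weak dependence.

    Boundaries 0.25 and 0.75 are assigned to ``moderate``.
    """
    if not 0 <= lsd <= 1:
        raise ValueError(f"invalid ratio: LSD must be in [0, 1], got {lsd}")
    if lsd < 0.25:
        return "strong"
    if lsd <= 0.75:
        return "moderate"
    return "weak"


def label_distribution(model: VariogramModel, emp: EmpiricalVariogram) -> str:
    """Label the spatial pattern as aggregate, random or regular.

    ``random`` when the structural share of the sill is below 5%
    (pure-nugget fit); ``regular`` when the empirical semivariance
    decreases significantly with lag (Spearman rho < 0, p < 0.05);
    ``aggregate`` when the semivariance increases with lag and the
    fitted range exceeds the minimum lag. Anything else (no resolvable
    trend) falls back to ``random``.
    """
    if model.sill <= 0 or model.structural / model.sill < RANDOM_STRUCTURAL_FRACTION:
        return "random"
    rho, p = spearmanr(emp.lag_centers, emp.gamma)
    if rho < 0 and p < REGULAR_ALPHA:
        return "regular"
    if rho > 0 and model.range > float(emp.lag_centers.min()):
        return "aggregate"
    return "random"


def build_structure(
    group: InstarGroup,
    model: VariogramModel,
    emp: EmpiricalVariogram,
    convention: str = "structural",
) -> SpatialStructure:
    """Assemble the per-group structure report row."""
    lsd = compute_lsd(model.nugget, model.sill, convention)
    return SpatialStructure(
        group=group,
        family=model.family,
        range=model.range,
        nugget=model.nugget,
        sill=model.sill,
        lsd=lsd,
        dependence_class=classify_dependence(lsd),
        distribution=label_distribution(model, emp),
    )
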