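"""Poisson GLM of larval counts against plant morphology, with VIF
screening of collinear predictors.

The response is the larval count in one (plant x height-class) cell;
predictors are the cell's distribution height (class midpoint, cm) and
the plant's morphology (plant height cm, crown width cm, ground
diameter mm), plus the distribution-height x ground-diameter
interaction. Counts are modelled with a log link:

    count ~ Poisson(exp(X beta))

fitted by iteratively reweighted least squares. Before fitting,
predictors with a variance inflation factor above 5 can be removed one
at a time (highest first) until all remaining VIFs are below the
threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2

from .samples import (
    HEIGHT_CLASS_MIDPOINTS,
    HEIGHT_CLASSES,
    InstarGroup,
    OBSERVED_GROUPS,
    SamplePoint,
)

__all__ = [
    "DEFAULT_TERMS",
    "GlmResult",
    "VifReport",
    "vif_screen",
    "fit_poisson_glm",
    "to_long_format",
    "PoissonCountGLM",
]

#: Default model terms. ``a:b`` denotes the product (interaction) of two
#: columns. Only the distribution-height x ground-diameter interaction is
#: included by default.
DEFAULT_TERMS: tuple[str, ...] = (
    "distribution_height",
    "plant_height",
    "crown_width",
    "ground_diameter",
    "distribution_height:ground_diameter",
)


@dataclass
class GlmResult:
    """Per-term Poisson GLM estimates with Wald chi-square tests."""

    terms: list[str]
    estimates: np.ndarray
    std_errors: np.ndarray
    wald_chisq: np.ndarray
    p_values: np.ndarray
    df: np.ndarray
    converged: bool
    n_iter: int
    deviance: float = float("nan")

    def coef(self, term: str) -> float:
        return float(self.estimates[self.terms.index(term)])

    def se(self, term: str) -> float:
        return float(self.std_errors[self.terms.index(term)])


@dataclass
class VifReport:
    """Outcome of iterative VIF screening."""

    retained: list[str]
    dropped: list[tuple[str, float]] = field(default_factory=list)
    final_vifs: dict[str, float] = field(default_factory=dict)


def _vif_one(X: np.ndarray, j: int) -> float:
    """VIF of column j: 1 / (1 - R^2) of x_j regressed on the others."""
    y = X[:, j]
    others = np.delete(X, j, axis=1)
    design = np.column_stack([np.ones(len(y)), others])
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot <= 0:
        return float("inf")  # constant column is perfectly collinear with intercept
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    if r2 >= 1.0 - 1e-12:
        return float("inf")
    return 1.0 / (1.0 - r2)


def vif_screen(design: pd.DataFrame, threshold: float = 5.0) -> VifReport:
    """Iteratively drop the highest-VIF predictor until all VIFs <= threshold.

    ``design`` is an observation-by-term numeric table (no intercept
    column; the auxiliary regressions include one). Perfectly collinear
    terms have infinite VIF and are removed first.
    """
    if design.shape[1] < 2:
        raise ValueError("need at least 2 terms to screen")
    if design.shape[0] <= design.shape[1]:
        raise ValueError("need more observations than terms")
    retained = list(design.columns)
    dropped: list[tuple[str, float]] = []
    while len(retained) >= 2:
        X = design[retained].to_numpy(dtype=float)
        vifs = {t: _vif_one(X, j) for j, t in enumerate(retained)}
        worst = max(retained, key=lambda t: vifs[t])
        if vifs[worst] <= threshold:
            return VifReport(retained=retained, dropped=dropped, final_vifs=vifs)
        dropped.append((worst, vifs[worst]))
        retained.remove(worst)
    return VifReport(retained=retained, dropped=dropped, final_vifs={retained[0]: 1.0})


def _build_design(data: pd.DataFrame, terms: Sequence[str]) -> pd.DataFrame:
    cols = {}
    for t in terms:
        if ":" in t:
            a, b = t.split(":")
            cols[t] = data[a].to_numpy(dtype=float) * data[b].to_numpy(dtype=float)
        else:
            cols[t] = data[t].to_numpy(dtype=float)
    return pd.DataFrame(cols, index=data.index)


def fit_poisson_glm(
    data: pd.DataFrame,
    formula_terms: Sequence[str] = DEFAULT_TERMS,
    response: str = "count",
) -> GlmResult:
    """Fit a log-link Poisson GLM of ``response`` on ``formula_terms``.

    ``data`` is the long-format cell table (see :func:`to_long_format`).
    Interaction terms are written ``a:b``. An intercept is always
    included. Fitting uses IRLS with relative-deviance convergence at
    1e-8 or 100 iterations; per-term Wald chi-square statistics use 1
    degree of freedom.
    """
    y = data[response].to_numpy(dtype=float)
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("counts must be non-negative integers")
    X = _build_design(data, formula_terms)
    exog = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
    model = sm.GLM(y, exog, family=sm.families.Poisson())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=100, tol=1e-8)
    est = np.asarray(res.params)
    se = np.asarray(res.bse)
    if np.any(np.abs(est) > 30):
        warnings.warn(
            "very large coefficient magnitude; possible separation-like divergence",
            RuntimeWarning,
            stacklevel=2,
        )
    wald = (est / se) ** 2
    terms = ["intercept", *formula_terms]
    return GlmResult(
        terms=terms,
        estimates=est,
        std_errors=se,
        wald_chisq=wald,
        p_values=chi2.sf(wald, df=1),
        df=np.ones(len(terms), dtype=int),
        converged=bool(res.converged),
        n_iter=int(getattr(res, "fit_history", {}).get("iteration", 0) or 0),
        deviance=float(res.deviance),
    )


def to_long_format(
    points: Sequence[SamplePoint],
    groups: Sequence[InstarGroup] = OBSERVED_GROUPS,
) -> pd.DataFrame:
    """One row per (plant x height class): the GLM observation table.

    ``count`` sums the requested groups within the cell;
    ``distribution_height`` is the class midpoint in cm. Plants without
    height-class records are skipped.
    """
    rows = []
    for p in points:
        if p.height_class_counts is None:
            continue
        for ci, (label, mid) in enumerate(zip(HEIGHT_CLASSES, HEIGHT_CLASS_MIDPOINTS)):
            total = 0
            have = False
            for g in groups:
                hc = p.height_class_counts.get(g)
                if hc is not None:
                    total += hc[ci]
                    have = True
            if not have:
                continue
            rows.append(
                {
                    "plant_id": p.id,
                    "height_class": label,
                    "count": total,
                    "distribution_height": mid,
                    "plant_height": p.plant_height,
                    "crown_width": p.crown_width,
                    "ground_diameter": p.ground_diameter,
                }
            )
    if not rows:
        raise ValueError("no vertical records")
    return pd.DataFrame(rows)


class PoissonCountGLM:
    """Scikit-learn-style Poisson regressor with optional VIF screening.

    Parameters
    ----------
    terms : sequence of str
        Model terms (``a:b`` for interactions); default
        :data:`DEFAULT_TERMS`.
    vif_threshold : float or None
        If set, main-effect terms are VIF-screened before fitting and
        terms above the threshold removed (interactions built from
        retained columns are kept).

    Attributes
    ----------
    result_ : GlmResult
    vif_report_ : VifReport or None
    coef_ : ndarray (slope terms, log-link scale)
    intercept_ : float
    """

    def __init__(
        self,
        terms: Sequence[str] = DEFAULT_TERMS,
        vif_threshold: float | None = None,
    ) -> None:
        self.terms = terms
        self.vif_threshold = vif_threshold

    def get_params(self, deep: bool = True) -> dict:
        return {"terms": self.terms, "vif_threshold": self.vif_threshold}

    def set_params(self, **params) -> "PoissonCountGLM":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: pd.DataFrame, y: Sequence[float]) -> "PoissonCountGLM":
        """Fit on a covariate table ``X`` and count vector ``y``."""
        terms = list(self.terms)
        self.vif_report_ = None
        if self.vif_threshold is not None:
            mains = [t for t in terms if ":" not in t]
            report = vif_screen(_build_design(X, mains), self.vif_threshold)
            self.vif_report_ = report
            kept = set(report.retained)
            terms = [
                t
                for t in terms
                if (":" not in t and t in kept)
                or (":" in t and all(p in kept for p in t.split(":")))
            ]
        data = X.copy()
        data["count"] = np.asarray(y)
        self.result_ = fit_poisson_glm(data, terms)
        self.terms_ = terms
        self.intercept_ = float(self.result_.estimates[0])
        self.coef_ = self.result_.estimates[1:]
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Expected counts exp(X beta) for new covariates."""
        if not hasattr(self, "result_"):
            raise RuntimeError("estimator is not fitted")
        design = _build_design(X, self.terms_).to_numpy(dtype=float)
        eta = self.intercept_ + design @ self.coef_
        return np.exp(eta)
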