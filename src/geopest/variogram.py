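"""Empirical semivariogram estimation and parametric variogram fitting.

The empirical (omnidirectional) semivariogram is

    gamma(h) = 1 / (2 N(h)) * sum_{i} [Z(x_i) - Z(x_i + h)]^2

over the N(h) unordered point pairs whose separation falls in the lag
bin around h. Four parametric families (spherical, exponential,
gaussian, linear) are fitted to it by weighted least squares. All
families use the *effective-range* convention, so the fitted range A is
the lag at which the model reaches (for exponential and gaussian,
effectively reaches, at 95%) its sill — the single comparable "range"
number reported by the common geostatistics packages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.distance import pdist

from .samples import InstarGroup, SamplePoint, coords_array, values_array

__all__ = [
    "FAMILIES",
    "EmpiricalVariogram",
    "VariogramModel",
    "VariogramFitError",
    "model_gamma",
    "empirical_variogram",
    "empirical_variogram_xy",
    "fit_variogram",
    "VariogramEstimator",
]

#: Parametric families, in canonical (tie-break) order. ``linear`` is
#: implemented but excluded from the default model-selection candidates.
FAMILIES: tuple[str, ...] = ("spherical", "exponential", "gaussian", "linear")

DEFAULT_CANDIDATE_FAMILIES: tuple[str, ...] = ("spherical", "exponential", "gaussian")


class VariogramFitError(RuntimeError):
    """Raised when no feasible variogram fit can be obtained."""


@dataclass
class EmpiricalVariogram:
    """Binned omnidirectional semivariogram.

    Attributes
    ----------
    lag_centers : ndarray
        Bin mid-lags in metres, strictly increasing; empty bins dropped.
    gamma : ndarray
        Semivariance per bin (squared count units).
    n_pairs : ndarray
        Number of point pairs N(h) per retained bin (all >= 1).
    max_lag, lag_width : float
        Binning parameters actually used.
    """

    lag_centers: np.ndarray
    gamma: np.ndarray
    n_pairs: np.ndarray
    max_lag: float
    lag_width: float


@dataclass
class VariogramModel:
    """A parametric variogram: family, nugget C0, sill C0+C, range A.

    ``range`` is the effective range in metres. The linear family rises
    linearly from the nugget to the sill at ``range`` and is flat
    beyond. ``structural`` is the spatially structured variance
    C = sill - nugget.
    """

    family: str
    nugget: float
    sill: float
    range: float

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if not (0 <= self.nugget <= self.sill):
            raise ValueError("require 0 <= nugget <= sill")
        if not self.range > 0:
            raise ValueError("range must be > 0")
        for v in (self.nugget, self.sill, self.range):
            if not np.isfinite(v):
                raise ValueError("non-finite variogram parameter")

    @property
    def structural(self) -> float:
        return self.sill - self.nugget

    def gamma(self, h):
        return model_gamma(self, h)


def model_gamma(model: VariogramModel, h) -> np.ndarray | float:
    """Evaluate the model semivariance at lag(s) ``h`` (metres).

    gamma(0) = 0 exactly (the nugget is the limit from the right).
    """
    h_arr = np.asarray(h, dtype=float)
    if np.any(h_arr < 0):
        raise ValueError("negative lag")
    c0, c, a = model.nugget, model.structural, model.range
    r = h_arr / a
    if model.family == "spherical":
        g = np.where(r <= 1.0, c * (1.5 * r - 0.5 * r**3), c)
    elif model.family == "exponential":
        g = c * (1.0 - np.exp(-3.0 * r))
    elif model.family == "gaussian":
        g = c * (1.0 - np.exp(-3.0 * r**2))
    else:  # linear
        g = c * np.minimum(r, 1.0)
    out = np.where(h_arr > 0, c0 + g, 0.0)
    return float(out) if np.isscalar(h) or out.ndim == 0 else out


def empirical_variogram_xy(
    coords: np.ndarray,
    values: np.ndarray,
    max_lag: float | None = None,
    lag_width: float = 10.0,
) -> EmpiricalVariogram:
    """Empirical semivariogram from a coordinate array and value vector.

    ``max_lag`` defaults to half the maximum pairwise distance. Bins are
    ``(k*lag_width, (k+1)*lag_width]``; bins with no pairs are dropped.
    """
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    if coords.shape[0] < 2:
        raise ValueError("insufficient samples: need at least 2 points")
    d = pdist(coords)
    if max_lag is None:
        max_lag = float(d.max()) / 2.0
    if not max_lag > lag_width > 0:
        raise ValueError("require max_lag > lag_width > 0")
    sq = pdist(values[:, None], metric="sqeuclidean")
    mask = (d > 0) & (d <= max_lag)
    if not mask.any():
        raise ValueError("no pairs in range")
    n_bins = int(np.ceil(max_lag / lag_width))
    edges = lag_width * np.arange(n_bins + 1)
    edges[-1] = max_lag  # last bin may be narrower
    # bin k holds pairs with edges[k] < d <= edges[k+1]
    idx = np.searchsorted(edges, d[mask], side="left") - 1
    idx = np.clip(idx, 0, n_bins - 1)
    n_pairs = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=sq[mask], minlength=n_bins)
    keep = n_pairs > 0
    centers = 0.5 * (edges[:-1] + edges[1:])
    return EmpiricalVariogram(
        lag_centers=centers[keep],
        gamma=sums[keep] / (2.0 * n_pairs[keep]),
        n_pairs=n_pairs[keep],
        max_lag=float(max_lag),
        lag_width=float(lag_width),
    )


def empirical_variogram(
    points: Sequence[SamplePoint],
    group: InstarGroup,
    max_lag: float | None = None,
    lag_width: float = 10.0,
) -> EmpiricalVariogram:
    """Empirical semivariogram of the counts of ``group`` over the survey."""
    return empirical_variogram_xy(
        coords_array(points), values_array(points, group), max_lag, lag_width
    )


def _wls_weights(emp: EmpiricalVariogram, scheme: str, gamma_model=None) -> np.ndarray:
    n = emp.n_pairs.astype(float)
    if scheme == "npairs":
        return n
    if scheme == "equal":
        return np.ones_like(n)
    if scheme == "cressie":
        g = np.maximum(np.asarray(gamma_model, dtype=float), 1e-12)
        return n / g**2
    raise ValueError(f"unknown weight scheme {scheme!r}")


def fit_variogram(
    emp: EmpiricalVariogram, family: str, weights: str = "npairs"
) -> VariogramModel:
    """Fit (nugget, sill, range) to an empirical variogram.

    Minimises sum_b w_b (gamma_model(h_b) - gamma_emp(h_b))^2 with
    w_b = N(h_b) by default (``weights`` in {"npairs", "equal",
    "cressie"}), subject to 0 <= nugget, structural variance >= 0 and
    range in (0, 2*max_lag]. A deterministic multistart over initial
    ranges guards against local minima; the returned fit is never worse
    than the best pure-nugget (flat) model.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    if emp.lag_centers.size < 3:
        raise ValueError("insufficient bins: need at least 3")
    h = emp.lag_centers
    g_emp = emp.gamma
    a_max = 2.0 * emp.max_lag

    def sse(params: np.ndarray) -> float:
        m = VariogramModel(family, params[0], params[0] + params[1], params[2])
        w = _wls_weights(emp, weights, gamma_model=m.gamma(h))
        return float(np.sum(w * (m.gamma(h) - g_emp) ** 2))

    def residuals(params: np.ndarray) -> np.ndarray:
        c0, c, a = params
        m = VariogramModel(family, c0, c0 + c, a)
        w = _wls_weights(emp, weights, gamma_model=m.gamma(h))
        return np.sqrt(w) * (m.gamma(h) - g_emp)

    g_max = float(g_emp.max())
    scale = g_max if g_max > 0 else 1.0
    c0_init = max(float(g_emp[0]), 0.0)
    best: tuple[float, np.ndarray] | None = None
    for frac in (0.1, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0):
        a0 = min(frac * emp.max_lag, a_max)
        x0 = np.array([0.5 * c0_init, max(g_max - 0.5 * c0_init, 0.05 * scale), a0])
        try:
            res = least_squares(
                residuals,
                x0,
                bounds=([0.0, 0.0, 1e-6], [np.inf, np.inf, a_max]),
                method="trf",
            )
        except Exception:
            continue
        if not np.all(np.isfinite(res.x)):
            continue
        cost = sse(res.x)
        if best is None or cost < best[0]:
            best = (cost, res.x)
    # pure-nugget baseline: flat model at the weighted mean semivariance
    w_flat = _wls_weights(emp, weights if weights != "cressie" else "npairs")
    flat = float(np.sum(w_flat * g_emp) / np.sum(w_flat))
    flat_params = np.array([flat, 0.0, emp.max_lag])
    flat_cost = sse(flat_params)
    if best is None or flat_cost < best[0]:
        best = (flat_cost, flat_params)
    if best is None:
        raise VariogramFitError("fit failed")
    c0, c, a = best[1]
    return VariogramModel(family=family, nugget=float(c0), sill=float(c0 + c), range=float(a))


class VariogramEstimator:
    """Scikit-learn-style estimator: empirical variogram + parametric fit.

    Parameters
    ----------
    family : str
        One of ``spherical``, ``exponential``, ``gaussian``, ``linear``.
    max_lag : float or None
        Maximum lag in metres (default: half the max pairwise distance).
    lag_width : float
        Lag bin width in metres (default 10, the survey spacing).
    weights : str
        Fitting weight scheme: ``npairs`` (default), ``equal``, ``cressie``.

    Attributes
    ----------
    empirical_ : EmpiricalVariogram
    model_ : VariogramModel
    nugget_, sill_, range_ : float
    """

    def __init__(
        self,
        family: str = "spherical",
        max_lag: float | None = None,
        lag_width: float = 10.0,
        weights: str = "npairs",
    ) -> None:
        self.family = family
        self.max_lag = max_lag
        self.lag_width = lag_width
        self.weights = weights

    def get_params(self, deep: bool = True) -> dict:
        return {
            "family": self.family,
            "max_lag": self.max_lag,
            "lag_width": self.lag_width,
            "weights": self.weights,
        }

    def set_params(self, **params) -> "VariogramEstimator":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: np.ndarray, y: np.ndarray) -> "VariogramEstimator":
        """Fit to coordinates ``X`` (n, 2) and values ``y`` (n,)."""
        self.empirical_ = empirical_variogram_xy(
            X, y, max_lag=self.max_lag, lag_width=self.lag_width
        )
        self.model_ = fit_variogram(self.empirical_, self.family, self.weights)
        self.nugget_ = self.model_.nugget
        self.sill_ = self.model_.sill
        self.range_ = self.model_.range
        return self

    def predict(self, h) -> np.ndarray:
        """Model semivariance at lag(s) ``h``."""
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted")
        return model_gamma(self.model_, h)
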