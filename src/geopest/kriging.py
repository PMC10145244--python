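"""Ordinary kriging: prediction, leave-one-out cross-validation, model
selection and surface gridding.

Ordinary kriging predicts Z at an unsampled location as a weighted sum
of the observations, with weights solving the semivariogram-based
system

    [ Gamma  1 ] [ w ]   [ gamma_0 ]
    [ 1^T    0 ] [ mu] = [ 1       ]

where Gamma[i, j] = gamma(d_ij) and gamma_0[i] = gamma(d_i,target); the
Lagrange multiplier mu enforces unbiasedness (sum of weights = 1). The
kriging variance is w . gamma_0 + mu.

Candidate variogram models are scored by leave-one-out
cross-validation with five metrics — slope beta0 and intercept beta1 of
the regression of observed on predicted, R^2, RMSE and mean error — and
ranked by aggregating the five criteria (beta0 near 1, beta1 near 0,
R^2 large, ME near 0, RMSE small).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import lu_factor, lu_solve
from scipy.spatial.distance import cdist, squareform, pdist

from .samples import InstarGroup, SamplePoint, coords_array, values_array
from .variogram import VariogramModel, model_gamma

__all__ = [
    "SingularKrigingSystemError",
    "CrossValidation",
    "KrigingSurface",
    "OrdinaryKriging",
    "krige_point",
    "loo_cross_validate",
    "select_model",
    "krige_grid",
]

#: Family precedence used for final tie-breaking in model selection.
FAMILY_ORDER: tuple[str, ...] = ("spherical", "exponential", "gaussian", "linear")


class SingularKrigingSystemError(RuntimeError):
    """Raised when the kriging system is numerically singular."""


def _gamma_to_targets(model: VariogramModel, d: np.ndarray) -> np.ndarray:
    """Data-to-target semivariances with the nugget as micro-scale variance.

    At zero distance the limit from the right (the nugget) is used, so a
    nugget-free model interpolates exactly at data points while a pure
    nugget model smooths every target towards the sample mean.
    """
    g = np.asarray(model_gamma(model, d), dtype=float)
    return np.where(np.asarray(d) == 0, model.nugget, g)


@dataclass
class CrossValidation:
    """Leave-one-out kriging predictions and selection metrics.

    ``beta0`` and ``beta1`` are the slope and intercept of the ordinary
    least squares regression of observed on predicted; ``r2`` its
    coefficient of determination; ``rmse`` the root mean square
    prediction error; ``me`` the mean error (predicted - observed).
    """

    predictions: np.ndarray
    observed: np.ndarray
    beta0: float
    beta1: float
    r2: float
    rmse: float
    me: float


@dataclass
class KrigingSurface:
    """Regular prediction grid of kriging estimates and variances."""

    grid_x: np.ndarray
    grid_y: np.ndarray
    estimates: np.ndarray  # shape (len(grid_y), len(grid_x))
    variances: np.ndarray
    model: VariogramModel


class OrdinaryKriging:
    """Ordinary kriging predictor with a fixed variogram model.

    Scikit-learn-style regressor: ``fit(X, y)`` stores the data and
    factorises the kriging matrix; ``predict(X)`` solves for each
    target. The neighbourhood is global (all fitted points are used for
    every prediction).

    Parameters
    ----------
    model : VariogramModel
        The (already fitted) variogram to krige with.
    cond_threshold : float
        Condition number above which the system is declared singular.

    Attributes
    ----------
    X_ : ndarray of shape (n, 2)
    y_ : ndarray of shape (n,)
    """

    def __init__(self, model: VariogramModel, cond_threshold: float = 1e12) -> None:
        self.model = model
        self.cond_threshold = cond_threshold

    def get_params(self, deep: bool = True) -> dict:
        return {"model": self.model, "cond_threshold": self.cond_threshold}

    def set_params(self, **params) -> "OrdinaryKriging":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: np.ndarray, y: np.ndarray) -> "OrdinaryKriging":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must have shape (n, 2)")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        if X.shape[0] < 2:
            raise ValueError("need at least 2 points")
        n = X.shape[0]
        gamma_mat = squareform(model_gamma(self.model, pdist(X)))
        a = np.zeros((n + 1, n + 1))
        a[:n, :n] = gamma_mat
        a[:n, n] = 1.0
        a[n, :n] = 1.0
        cond = np.linalg.cond(a)
        if not np.isfinite(cond) or cond > self.cond_threshold:
            raise SingularKrigingSystemError(
                f"singular kriging system (condition number {cond:.3g}, "
                f"n={n} points)"
            )
        self.X_ = X
        self.y_ = y
        self._lu = lu_factor(a)
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "X_"):
            raise RuntimeError("estimator is not fitted")

    def weights(self, target: Sequence[float]) -> tuple[np.ndarray, float]:
        """Kriging weights and Lagrange multiplier for one target."""
        self._check_fitted()
        n = self.X_.shape[0]
        d = cdist(self.X_, np.atleast_2d(target)).ravel()
        g0 = _gamma_to_targets(self.model, d)
        b = np.append(g0, 1.0)
        sol = lu_solve(self._lu, b)
        return sol[:n], float(sol[n])

    def predict(self, X: np.ndarray, return_std: bool = False):
        """Kriging estimates (and optionally standard errors) at targets."""
        self._check_fitted()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n = self.X_.shape[0]
        g0 = _gamma_to_targets(self.model, cdist(self.X_, X))  # (n, m)
        b = np.vstack([g0, np.ones(X.shape[0])])
        sol = lu_solve(self._lu, b)
        w, mu = sol[:n], sol[n]
        est = w.T @ self.y_
        if not return_std:
            return est
        var = np.einsum("im,im->m", w, g0) + mu
        var = np.where(var < 0, np.where(var > -1e-9, 0.0, var), var)
        var = np.clip(var, 0.0, None)
        return est, np.sqrt(var)


def krige_point(
    points: Sequence[SamplePoint],
    group: InstarGroup,
    model: VariogramModel,
    target: Sequence[float],
) -> tuple[float, float, np.ndarray]:
    """Ordinary-kriging estimate, variance and weights at one location."""
    ok = OrdinaryKriging(model).fit(coords_array(points), values_array(points, group))
    w, mu = ok.weights(target)
    g0 = _gamma_to_targets(model, cdist(ok.X_, np.atleast_2d(target)).ravel())
    est = float(w @ ok.y_)
    var = float(w @ g0 + mu)
    if var < 0:
        var = 0.0 if var > -1e-9 else var
    return est, var, w


def _cv_metrics(pred: np.ndarray, obs: np.ndarray) -> tuple[float, float, float]:
    """(beta0, beta1, r2) of the OLS regression observed ~ predicted."""
    if np.var(pred) < 1e-30:
        # degenerate: constant predictions; no regression is defined
        return 0.0, float(np.mean(obs)), 0.0
    beta0, beta1 = np.polyfit(pred, obs, 1)
    if np.var(obs) < 1e-30:
        r2 = 1.0 if np.allclose(pred, obs) else 0.0
    else:
        r = np.corrcoef(pred, obs)[0, 1]
        r2 = float(r * r)
    return float(beta0), float(beta1), r2


def loo_cross_validate(
    points: Sequence[SamplePoint], group: InstarGroup, model: VariogramModel
) -> CrossValidation:
    """Leave-one-out cross-validation of a variogram model.

    Each observation is predicted by ordinary kriging from all other
    points; the five selection metrics are computed from the resulting
    (predicted, observed) pairs.
    """
    coords = coords_array(points)
    obs = values_array(points, group)
    n = coords.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points for cross-validation")
    pred = np.empty(n)
    for i in range(n):
        mask = np.arange(n) != i
        try:
            ok = OrdinaryKriging(model).fit(coords[mask], obs[mask])
            pred[i] = ok.predict(coords[i])[0]
        except SingularKrigingSystemError as exc:
            raise SingularKrigingSystemError(
                f"singular system when leaving out point index {i}: {exc}"
            ) from exc
    err = pred - obs
    beta0, beta1, r2 = _cv_metrics(pred, obs)
    return CrossValidation(
        predictions=pred,
        observed=obs,
        beta0=beta0,
        beta1=beta1,
        r2=r2,
        rmse=float(np.sqrt(np.mean(err**2))),
        me=float(np.mean(err)),
    )


def select_model(cv_results: Mapping[str, CrossValidation]) -> str:
    """Pick the best variogram family from cross-validation metrics.

    Candidates are ranked on each of five criteria — |beta0 - 1|
    ascending, |beta1| ascending, R^2 descending, |ME| ascending, RMSE
    ascending — and the winner is the family with the lowest mean rank.
    Ties are broken by RMSE, then by canonical family order.
    """
    from scipy.stats import rankdata

    finite = {
        fam: cv
        for fam, cv in cv_results.items()
        if all(np.isfinite(v) for v in (cv.beta0, cv.beta1, cv.r2, cv.rmse, cv.me))
    }
    if not finite:
        raise ValueError("no selectable model: all candidates have non-finite metrics")
    fams = list(finite)
    crits = np.array(
        [
            [abs(finite[f].beta0 - 1.0) for f in fams],
            [abs(finite[f].beta1) for f in fams],
            [-finite[f].r2 for f in fams],
            [abs(finite[f].me) for f in fams],
            [finite[f].rmse for f in fams],
        ]
    )
    ranks = np.vstack([rankdata(row) for row in crits])
    mean_rank = ranks.mean(axis=0)

    def order_key(j: int) -> tuple:
        fam = fams[j]
        fam_idx = FAMILY_ORDER.index(fam) if fam in FAMILY_ORDER else len(FAMILY_ORDER)
        return (mean_rank[j], finite[fam].rmse, fam_idx)

    return fams[min(range(len(fams)), key=order_key)]


def krige_grid(
    points: Sequence[SamplePoint],
    group: InstarGroup,
    model: VariogramModel,
    resolution: float = 2.0,
    pad: float = 10.0,
) -> KrigingSurface:
    """Ordinary-kriging surface on a regular grid over the survey.

    The grid covers the bounding box of the sample points padded by
    ``pad`` metres (default: one survey spacing) at ``resolution``-metre
    cell size, predicted from all samples (global neighbourhood).
    """
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    coords = coords_array(points)
    obs = values_array(points, group)
    x0, y0 = coords.min(axis=0) - pad
    x1, y1 = coords.max(axis=0) + pad
    gx = np.arange(x0, x1 + resolution / 2, resolution)
    gy = np.arange(y0, y1 + resolution / 2, resolution)
    xx, yy = np.meshgrid(gx, gy)
    targets = np.column_stack([xx.ravel(), yy.ravel()])
    ok = OrdinaryKriging(model).fit(coords, obs)
    est, std = ok.predict(targets, return_std=True)
    return KrigingSurface(
        grid_x=gx,
        grid_y=gy,
        estimates=est.reshape(xx.shape),
        variances=(std**2).reshape(xx.shape),
        model=model,
    )
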