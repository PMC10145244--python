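"""Ordinary kriging: hand-solved systems, unbiasedness, cross-validation
against an independent solver, and model selection."""

import numpy as np
import pytest

from geopest.kriging import (
    CrossValidation,
    OrdinaryKriging,
    SingularKrigingSystemError,
    krige_grid,
    krige_point,
    loo_cross_validate,
    select_model,
)
from geopest.samples import InstarGroup, SurveyDesign
from geopest.synthetic import generate_layout, simulate_latent_field
from geopest.variogram import VariogramModel, model_gamma

from conftest import make_points, random_points


def solve_ok_system(coords, values, model, target):
    """Independent oracle: assemble and solve the kriging system directly."""
    n = len(values)
    a = np.zeros((n + 1, n + 1))
    for i in range(n):
        for j in range(n):
            if i != j:
                a[i, j] = model_gamma(model, float(np.linalg.norm(coords[i] - coords[j])))
        a[i, n] = a[n, i] = 1.0
    b = np.array(
        [model_gamma(model, float(np.linalg.norm(c - target))) for c in coords] + [1.0]
    )
    sol = np.linalg.solve(a, b)
    w, mu = sol[:n], sol[n]
    return float(w @ values), float(w @ b[:n] + mu), w


class TestKrigePoint:
    def test_symmetry_two_equidistant_points(self, spherical_model):
        pts = make_points([(0.0, 0.0), (10.0, 0.0)], [2, 8])
        _, _, w = krige_point(pts, InstarGroup.I3, spherical_model, (5.0, 0.0))
        assert w == pytest.approx([0.5, 0.5])

    def test_pure_nugget_weights_are_uniform(self):
        # hand solution for n=3: all off-diagonal gammas equal the nugget,
        # so the system is symmetric in the points and w_i = 1/3
        model = VariogramModel("spherical", nugget=0.7, sill=0.7, range=30.0)
        pts = make_points([(0.0, 0.0), (20.0, 5.0), (7.0, 31.0)], [1, 5, 9])
        est, _, w = krige_point(pts, InstarGroup.I3, model, (12.0, 12.0))
        assert w == pytest.approx([1 / 3] * 3, abs=1e-10)
        assert est == pytest.approx(5.0)

    def test_exact_interpolation_without_nugget(self):
        model = VariogramModel("exponential", nugget=0.0, sill=1.0, range=40.0)
        pts = make_points([(0.0, 0.0), (10.0, 0.0), (0.0, 10.0), (10.0, 10.0)],
                          [3, 7, 1, 4])
        est, var, _ = krige_point(pts, InstarGroup.I3, model, (10.0, 0.0))
        assert est == pytest.approx(7.0, abs=1e-8)
        assert var == pytest.approx(0.0, abs=1e-8)

    def test_matches_independent_solver(self, rng, spherical_model):
        pts, coords, values = random_points(rng, 12)
        target = (43.0, 17.0)
        est, var, w = krige_point(pts, InstarGroup.I3, spherical_model, target)
        est_o, var_o, w_o = solve_ok_system(coords, values, spherical_model,
                                            np.array(target))
        assert est == pytest.approx(est_o, abs=1e-8)
        assert var == pytest.approx(var_o, abs=1e-8)
        np.testing.assert_allclose(w, w_o, atol=1e-8)

    def test_singular_system_reported(self):
        # two nearly coincident points with a nugget-free model
        model = VariogramModel("gaussian", nugget=0.0, sill=1.0, range=1000.0)
        pts = make_points([(0.0, 0.0), (1e-8, 0.0), (10.0, 10.0)], [1, 2, 3])
        with pytest.raises(SingularKrigingSystemError, match="condition number"):
            krige_point(pts, InstarGroup.I3, model, (5.0, 5.0))


class TestWeightInvariants:
    def test_weights_sum_to_one_random_draws(self, rng):
        families = ("spherical", "exponential", "gaussian", "linear")
        for _ in range(50):
            pts, coords, values = random_points(rng, int(rng.integers(5, 15)))
            nugget = float(rng.uniform(0, 1))
            model = VariogramModel(
                str(rng.choice(families)),
                nugget=nugget,
                sill=nugget + float(rng.uniform(0.05, 2)),
                range=float(rng.uniform(5, 200)),
            )
            ok = OrdinaryKriging(model).fit(coords, values)
            w, _ = ok.weights(rng.uniform(-20, 120, size=2))
            assert abs(w.sum() - 1.0) < 1e-8

    def test_variance_nonnegative(self, rng, spherical_model):
        pts, coords, values = random_points(rng, 20)
        ok = OrdinaryKriging(spherical_model).fit(coords, values)
        _, std = ok.predict(rng.uniform(0, 100, size=(200, 2)), return_std=True)
        assert np.all(std >= 0)


class TestCrossValidation:
    def test_constant_field(self, spherical_model):
        pts = make_points([(0, 0), (10, 0), (0, 10), (10, 10)], [4, 4, 4, 4])
        cv = loo_cross_validate(pts, InstarGroup.I3, spherical_model)
        assert cv.me == pytest.approx(0.0, abs=1e-9)
        assert cv.rmse == pytest.approx(0.0, abs=1e-9)

    def test_perfect_prediction_metrics(self):
        from geopest.kriging import _cv_metrics

        pred = np.array([1.0, 2.0, 5.0, 9.0])
        beta0, beta1, r2 = _cv_metrics(pred, pred.copy())
        assert beta0 == pytest.approx(1.0)
        assert beta1 == pytest.approx(0.0, abs=1e-12)
        assert r2 == pytest.approx(1.0)

    def test_matches_plain_loop_oracle(self, spherical_model):
        layout = generate_layout(SurveyDesign(n_points=30, extent=(120.0, 120.0)))
        values = np.round(
            3 + 2 * simulate_latent_field(layout, spherical_model, 7)
        ).clip(0)
        pts = make_points(layout, values)
        cv = loo_cross_validate(pts, InstarGroup.I3, spherical_model)
        preds = np.empty(len(pts))
        for i in range(len(pts)):
            keep = [j for j in range(len(pts)) if j != i]
            preds[i], _, _ = solve_ok_system(
                layout[keep], values[keep], spherical_model, layout[i]
            )
        np.testing.assert_allclose(cv.predictions, preds, atol=1e-8)
        err = preds - values
        assert cv.me == pytest.approx(err.mean())
        assert cv.rmse == pytest.approx(np.sqrt((err**2).mean()))
        b0, b1 = np.polyfit(preds, values, 1)
        assert cv.beta0 == pytest.approx(b0)
        assert cv.beta1 == pytest.approx(b1)

    def test_too_few_points(self, spherical_model):
        pts = make_points([(0, 0), (10, 0)], [1, 2])
        with pytest.raises(ValueError, match="at least 3"):
            loo_cross_validate(pts, InstarGroup.I3, spherical_model)


def _cv(beta0, beta1, r2, rmse, me):
    return CrossValidation(np.zeros(1), np.zeros(1), beta0, beta1, r2, rmse, me)


class TestSelectModel:
    def test_dominant_candidate_wins(self):
        cvs = {
            "spherical": _cv(1.0, 0.0, 0.9, 0.5, 0.0),
            "gaussian": _cv(1.4, 0.3, 0.5, 1.5, 0.4),
        }
        assert select_model(cvs) == "spherical"

    def test_published_third_instar_metrics_select_gaussian(self):
        # cross-validation metrics of the three candidates for 3rd-instar
        # counts; rank aggregation over the five criteria picks Gaussian
        cvs = {
            "spherical": _cv(1.143, 0.072, 0.025, 0.929, 1.569),
            "exponential": _cv(1.194, 0.089, 0.020, 0.908, 1.564),
            "gaussian": _cv(1.113, 0.044, 0.030, 0.902, 1.733),
        }
        assert select_model(cvs) == "gaussian"

    def test_tie_broken_by_family_order(self):
        same = _cv(1.1, 0.05, 0.5, 1.0, 0.2)
        cvs = {"gaussian": same, "exponential": same, "spherical": same}
        assert select_model(cvs) == "spherical"

    def test_all_nonfinite_rejected(self):
        cvs = {"spherical": _cv(np.nan, 0, 0, 1, 0)}
        with pytest.raises(ValueError, match="no selectable model"):
            select_model(cvs)


class TestKrigeGrid:
    def test_exactness_at_sample_node(self):
        model = VariogramModel("spherical", nugget=0.0, sill=1.0, range=40.0)
        pts = make_points([(0.0, 0.0), (10.0, 0.0), (0.0, 10.0), (10.0, 10.0)],
                          [2, 9, 4, 6])
        surf = krige_grid(pts, InstarGroup.I3, model, resolution=5.0, pad=10.0)
        ix = int(np.argmin(np.abs(surf.grid_x - 10.0)))
        iy = int(np.argmin(np.abs(surf.grid_y - 0.0)))
        assert surf.grid_x[ix] == pytest.approx(10.0)
        assert surf.estimates[iy, ix] == pytest.approx(9.0, abs=1e-8)

    def test_pure_nugget_surface_is_flat_at_mean(self):
        model = VariogramModel("spherical", nugget=1.0, sill=1.0, range=30.0)
        pts = make_points([(0, 0), (10, 0), (0, 10), (10, 10)], [1, 3, 5, 7])
        surf = krige_grid(pts, InstarGroup.I3, model, resolution=5.0)
        np.testing.assert_allclose(surf.estimates, 4.0, atol=1e-8)

    def test_central_hotspot_surfaces_peak_centrally(self):
        from geopest.synthetic import SimulationConfig, simulate_survey

        cfg = SimulationConfig(seed=9, hotspot="center", hotspot_amplitude=1.5,
                               variogram_truth=None)
        pts = simulate_survey(cfg)
        from geopest.variogram import empirical_variogram, fit_variogram

        emp = empirical_variogram(pts, InstarGroup.AVG)
        model = fit_variogram(emp, "spherical")
        surf = krige_grid(pts, InstarGroup.AVG, model, resolution=5.0)
        iy, ix = np.unravel_index(np.argmax(surf.estimates), surf.estimates.shape)
        xs = np.array([p.x for p in pts])
        ys = np.array([p.y for p in pts])
        # central cluster: middle half of the survey bounding box
        cx0, cx1 = np.quantile(xs, [0.25, 0.75])
        cy0, cy1 = np.quantile(ys, [0.25, 0.75])
        assert cx0 <= surf.grid_x[ix] <= cx1
        assert cy0 <= surf.grid_y[iy] <= cy1
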