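"""Semivariogram estimation and model fitting, checked against
brute-force pair enumeration and closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from geopest.samples import InstarGroup
from geopest.variogram import (
    FAMILIES,
    VariogramEstimator,
    VariogramModel,
    empirical_variogram,
    empirical_variogram_xy,
    fit_variogram,
    model_gamma,
)

from conftest import make_points, random_points


def brute_force_variogram(coords, values, max_lag, lag_width):
    """Independent oracle: explicit double loop over all unordered pairs."""
    n = len(values)
    n_bins = int(np.ceil(max_lag / lag_width))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.hypot(*(coords[i] - coords[j])))
            if d <= 0 or d > max_lag:
                continue
            b = min(int(np.ceil(d / lag_width)) - 1, n_bins - 1)
            sums[b] += (values[i] - values[j]) ** 2
            counts[b] += 1
    keep = counts > 0
    return sums[keep] / (2 * counts[keep]), counts[keep]


class TestEmpiricalVariogram:
    def test_constant_field_gives_zero(self, rng):
        coords = rng.uniform(0, 50, size=(20, 2))
        emp = empirical_variogram_xy(coords, np.full(20, 7.0), max_lag=40, lag_width=5)
        assert np.allclose(emp.gamma, 0.0)

    def test_three_colinear_points_by_hand(self):
        # x = 0,1,2 with Z = 0,1,2: two pairs at lag 1, gamma = (1+1)/(2*2) = 0.5
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        emp = empirical_variogram_xy(coords, np.array([0.0, 1.0, 2.0]),
                                     max_lag=1.5, lag_width=1.0)
        assert emp.n_pairs.tolist() == [2]
        assert emp.gamma == pytest.approx([0.5])

    def test_matches_brute_force_on_random_points(self, rng):
        points, coords, values = random_points(rng, 50)
        emp = empirical_variogram(points, InstarGroup.I3, max_lag=60, lag_width=8)
        g, n = brute_force_variogram(coords, values, 60, 8)
        np.testing.assert_array_equal(emp.n_pairs, n)
        np.testing.assert_allclose(emp.gamma, g, atol=1e-10)

    def test_permutation_invariance(self, rng):
        points, _, _ = random_points(rng, 30)
        emp1 = empirical_variogram(points, InstarGroup.I3, max_lag=50, lag_width=10)
        perm = [points[i] for i in rng.permutation(len(points))]
        emp2 = empirical_variogram(perm, InstarGroup.I3, max_lag=50, lag_width=10)
        np.testing.assert_allclose(emp1.gamma, emp2.gamma)
        np.testing.assert_array_equal(emp1.n_pairs, emp2.n_pairs)

    def test_insufficient_points(self):
        with pytest.raises(ValueError, match="insufficient samples"):
            empirical_variogram_xy(np.zeros((1, 2)), np.zeros(1), 10, 1)

    def test_no_pairs_in_range(self):
        coords = np.array([[0.0, 0.0], [100.0, 0.0]])
        with pytest.raises(ValueError, match="no pairs in range"):
            empirical_variogram_xy(coords, np.array([0.0, 1.0]), max_lag=10, lag_width=1)

    def test_default_max_lag_is_half_max_distance(self, rng):
        points, coords, _ = random_points(rng, 25)
        emp = empirical_variogram(points, InstarGroup.I3, lag_width=5)
        from scipy.spatial.distance import pdist

        assert emp.max_lag == pytest.approx(pdist(coords).max() / 2)


class TestModelGamma:
    @pytest.mark.parametrize("family", FAMILIES)
    def test_zero_at_origin(self, family):
        m = VariogramModel(family, nugget=0.3, sill=1.0, range=50.0)
        assert model_gamma(m, 0.0) == 0.0

    def test_spherical_reaches_sill_at_range(self):
        m = VariogramModel("spherical", nugget=0.365, sill=1.178, range=131.278)
        assert model_gamma(m, 131.278) == pytest.approx(1.178)
        assert model_gamma(m, 500.0) == pytest.approx(1.178)

    def test_gaussian_closed_form(self):
        m = VariogramModel("gaussian", nugget=0.0, sill=1.0, range=10.0)
        assert model_gamma(m, 10.0) == pytest.approx(1 - np.exp(-3), rel=1e-12)

    def test_negative_lag_rejected(self):
        m = VariogramModel("linear", nugget=0.0, sill=1.0, range=10.0)
        with pytest.raises(ValueError, match="negative lag"):
            model_gamma(m, -1.0)

    @pytest.mark.parametrize("family", FAMILIES)
    @given(
        nugget=st.floats(0, 1),
        c=st.floats(0.01, 2),
        a=st.floats(1, 200),
    )
    @settings(max_examples=30, deadline=None)
    def test_nondecreasing_in_lag(self, family, nugget, c, a):
        m = VariogramModel(family, nugget=nugget, sill=nugget + c, range=a)
        h = np.linspace(0, 2 * a, 200)
        g = model_gamma(m, h)
        assert np.all(np.diff(g) >= -1e-12)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            VariogramModel("spherical", nugget=1.0, sill=0.5, range=10.0)
        with pytest.raises(ValueError):
            VariogramModel("spherical", nugget=0.0, sill=1.0, range=-5.0)
        with pytest.raises(ValueError):
            VariogramModel("cubic", nugget=0.0, sill=1.0, range=5.0)


class TestFitVariogram:
    def _emp_from_model(self, model, max_lag=120.0, lag_width=10.0):
        from geopest.variogram import EmpiricalVariogram

        centers = np.arange(lag_width / 2, max_lag, lag_width)
        return EmpiricalVariogram(
            lag_centers=centers,
            gamma=np.asarray(model.gamma(centers)),
            n_pairs=np.full(centers.size, 50),
            max_lag=max_lag,
            lag_width=lag_width,
        )

    def test_recovers_noiseless_spherical(self):
        truth = VariogramModel("spherical", nugget=0.1, sill=0.26, range=52.5)
        fit = fit_variogram(self._emp_from_model(truth), "spherical")
        assert fit.nugget == pytest.approx(truth.nugget, rel=1e-3, abs=1e-6)
        assert fit.sill == pytest.approx(truth.sill, rel=1e-3)
        assert fit.range == pytest.approx(truth.range, rel=1e-3)

    @pytest.mark.parametrize("family", ["exponential", "gaussian", "linear"])
    def test_recovers_noiseless_other_families(self, family):
        truth = VariogramModel(family, nugget=0.2, sill=1.0, range=40.0)
        fit = fit_variogram(self._emp_from_model(truth), family)
        assert fit.nugget == pytest.approx(truth.nugget, rel=1e-2, abs=1e-4)
        assert fit.sill == pytest.approx(truth.sill, rel=1e-2)
        assert fit.range == pytest.approx(truth.range, rel=1e-2)

    def test_flat_variogram_fits_pure_nugget(self):
        from geopest.variogram import EmpiricalVariogram

        centers = np.arange(5.0, 100.0, 10.0)
        emp = EmpiricalVariogram(centers, np.full(centers.size, 2.5),
                                 np.full(centers.size, 30), 100.0, 10.0)
        fit = fit_variogram(emp, "spherical")
        assert fit.sill == pytest.approx(2.5, rel=1e-6)
        assert fit.structural == pytest.approx(0.0, abs=1e-6)

    def test_never_worse_than_pure_nugget(self, rng):
        points, _, _ = random_points(rng, 40)
        emp = empirical_variogram(points, InstarGroup.I3, max_lag=60, lag_width=10)
        w = emp.n_pairs.astype(float)
        flat = np.sum(w * emp.gamma) / w.sum()
        sse_flat = np.sum(w * (emp.gamma - flat) ** 2)
        for family in FAMILIES:
            fit = fit_variogram(emp, family)
            sse_fit = np.sum(w * (np.asarray(fit.gamma(emp.lag_centers)) - emp.gamma) ** 2)
            assert sse_fit <= sse_flat + 1e-9

    def test_too_few_bins(self):
        from geopest.variogram import EmpiricalVariogram

        emp = EmpiricalVariogram(np.array([5.0, 15.0]), np.array([1.0, 2.0]),
                                 np.array([4, 4]), 20.0, 10.0)
        with pytest.raises(ValueError, match="insufficient bins"):
            fit_variogram(emp, "spherical")


class TestVariogramEstimator:
    def test_fit_sets_attributes(self, rng):
        _, coords, values = random_points(rng, 40)
        est = VariogramEstimator(family="exponential", max_lag=60).fit(coords, values)
        assert est.model_.family == "exponential"
        assert est.nugget_ <= est.sill_
        assert est.range_ > 0
        g = est.predict([0.0, 10.0, 60.0])
        assert g[0] == 0.0 and np.all(np.diff(g) >= 0)

    def test_get_set_params_round_trip(self):
        est = VariogramEstimator()
        est.set_params(family="gaussian", lag_width=5.0)
        assert est.get_params()["family"] == "gaussian"
        with pytest.raises(ValueError):
            est.set_params(bogus=1)
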