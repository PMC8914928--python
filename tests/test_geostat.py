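"""Normalization, variogram estimation/fitting and kriging."""

import warnings

import numpy as np
import pytest

import spatialaq as sa
from spatialaq.errors import SingularKrigingSystem, VariogramFitError
from spatialaq.geostat import EmpiricalVariogram, VariogramModel, normalize


def covariance_kriging_oracle(coords, z, vg, target):
    """Independent ordinary-kriging solve in covariance form.

    Uses C(h) = sill - gamma(h) and the bordered covariance system — the
    textbook dual of the semivariance formulation solved by the package.
    """
    n = len(z)
    sill = vg.nugget + vg.partial_sill
    h = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    C = sill - vg(h)
    np.fill_diagonal(C, sill)
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = C
    A[n, :n] = 1.0
    A[:n, n] = 1.0
    c0 = sill - vg(np.linalg.norm(coords - target, axis=1))
    b = np.append(c0, 1.0)
    sol = np.linalg.solve(A, b)
    lam = sol[:n]
    return float(lam @ z), lam


def sample_skewness(x):
    x = np.asarray(x, float)
    m = x.mean()
    m2 = np.mean((x - m) ** 2)
    m3 = np.mean((x - m) ** 3)
    return m3 / m2**1.5


class TestNormalize:
    def test_round_trip_on_chosen_transform(self, rng):
        x = rng.normal(10, 2, 200)
        z, t = normalize(x)
        np.testing.assert_allclose(t.inverse(z), x, atol=1e-9)

    def test_normal_sample_kept_nearly_identity(self, rng):
        x = rng.normal(0, 1, 500)
        z, _ = normalize(x)
        # whatever transform wins, the output must stay close to normal
        assert abs(sample_skewness(z)) < 0.25

    def test_lognormal_sample_skewness_reduced(self, rng):
        x = np.exp(rng.normal(0, 1, 400))
        z, t = normalize(x)
        assert abs(sample_skewness(z)) < abs(sample_skewness(x))
        np.testing.assert_allclose(t.inverse(z), x, rtol=1e-7, atol=1e-9)

    def test_constant_input_identity_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            z, t = normalize(np.full(20, 3.0))
        assert t.kind == "identity"
        np.testing.assert_array_equal(z, np.full(20, 3.0))

    def test_short_input_identity_with_warning(self):
        with pytest.warns(UserWarning, match="fewer than 10"):
            _, t = normalize(np.arange(5.0))
        assert t.kind == "identity"

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            normalize(np.array([1.0, np.nan, 2.0]))


class TestEmpiricalVariogram:
    def test_single_pair_single_bin(self):
        d = sa.PointDataset(
            np.r_[np.zeros(9), 10.0], np.zeros(10),
            np.r_[np.full(9, 1.0), 5.0],
        )
        emp = sa.empirical_variogram(d, n_lags=1, max_dist=20.0)
        # bin pools all pairs; check against the direct Matheron sum
        diffs = []
        for i in range(10):
            for j in range(i + 1, 10):
                dist = abs(d.x[i] - d.x[j])
                if 0 < dist <= 20.0:
                    diffs.append((d.values[i] - d.values[j]) ** 2)
        assert emp.semivariance[0] == pytest.approx(
            np.sum(diffs) / (2 * len(diffs))
        )

    def test_matches_brute_force_binning(self, rng):
        pts = rng.uniform(0, 100, size=(40, 2))
        vals = rng.normal(size=40)
        d = sa.PointDataset(pts[:, 0], pts[:, 1], vals)
        n_lags, max_dist = 6, 60.0
        emp = sa.empirical_variogram(d, n_lags=n_lags, max_dist=max_dist)
        edges = np.linspace(0, max_dist, n_lags + 1)
        for b, (center, gamma, count) in enumerate(
            zip(emp.lag_centers, emp.semivariance, emp.pair_counts)
        ):
            k = int(round(center / (max_dist / n_lags) - 0.5))
            sq, c = 0.0, 0
            for i in range(40):
                for j in range(i + 1, 40):
                    h = np.hypot(*(pts[i] - pts[j]))
                    if edges[k] < h <= edges[k + 1] or (
                        k == 0 and 0 < h <= edges[1]
                    ):
                        if np.digitize(h, edges) - 1 == k:
                            sq += (vals[i] - vals[j]) ** 2
                            c += 1
            assert count == c
            assert gamma == pytest.approx(sq / (2 * c))

    def test_white_noise_is_flat_at_the_variance(self, rng):
        pts = rng.uniform(0, 1000, size=(400, 2))
        vals = rng.normal(0, 2, 400)
        d = sa.PointDataset(pts[:, 0], pts[:, 1], vals)
        emp = sa.empirical_variogram(d, n_lags=8)
        var = vals.var(ddof=1)
        np.testing.assert_allclose(emp.semivariance, var, rtol=0.25)

    def test_too_few_points_rejected(self):
        d = sa.PointDataset([0, 1, 2.0], [0, 0, 0.0], [1, 2, 3.0])
        with pytest.raises(ValueError):
            sa.empirical_variogram(d)


class TestFitVariogram:
    def test_noise_free_self_consistency_within_1pct(self):
        truth = VariogramModel("exponential", nugget=0.0, partial_sill=1.0,
                               range_=50.0)
        h = np.linspace(5, 300, 20)
        emp = EmpiricalVariogram(
            lag_centers=h, semivariance=truth(h),
            pair_counts=np.full(20, 100, dtype=int),
        )
        fit = sa.fit_variogram(emp, model="exponential")
        assert fit.partial_sill == pytest.approx(1.0, rel=0.01)
        assert fit.range_ == pytest.approx(50.0, rel=0.01)
        assert fit.nugget == pytest.approx(0.0, abs=0.01)

    @pytest.mark.parametrize("model", ["spherical", "gaussian"])
    def test_other_models_self_consistent(self, model):
        truth = VariogramModel(model, nugget=0.2, partial_sill=2.0,
                               range_=80.0)
        h = np.linspace(5, 300, 25)
        emp = EmpiricalVariogram(h, truth(h), np.full(25, 50, dtype=int))
        fit = sa.fit_variogram(emp, model=model)
        np.testing.assert_allclose(fit(h), truth(h), rtol=0.02, atol=0.02)

    def test_pure_nugget_flags_unidentifiable_range(self, rng):
        h = np.linspace(10, 200, 10)
        emp = EmpiricalVariogram(
            h, np.full(10, 4.0) + rng.normal(0, 1e-3, 10),
            np.full(10, 30, dtype=int),
        )
        with pytest.warns(UserWarning, match="nugget"):
            fit = sa.fit_variogram(emp)
        assert fit.nugget + fit.partial_sill == pytest.approx(4.0, rel=0.05)
        assert fit.partial_sill <= 0.05

    def test_too_few_bins_rejected(self):
        emp = EmpiricalVariogram(np.array([1.0, 2.0]), np.array([1.0, 2.0]),
                                 np.array([5, 5]))
        with pytest.raises(VariogramFitError):
            sa.fit_variogram(emp)

    def test_range_recovery_on_simulated_fields(self):
        """Seeded exponential fields, n=400, true range 100 km: the fitted
        range parameter lands within a factor of 2 in >= 80% of seeds."""
        hits = 0
        for seed in range(20):
            f = sa.simulate_field(
                sa.FieldSpec(bbox=(0, 0, 1000, 1000), n_points=400,
                             covariance="exponential", range_=100.0,
                             sill=1.0, nugget=0.0, seed=seed)
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                emp = sa.empirical_variogram(f, n_lags=15)
                fit = sa.fit_variogram(emp, model="exponential")
            if 50.0 <= fit.range_ <= 200.0:
                hits += 1
        assert hits >= 16


class TestOrdinaryKriging:
    @pytest.fixture
    def vg(self):
        return VariogramModel("exponential", nugget=0.0, partial_sill=1.0,
                              range_=100.0)

    def test_exact_at_data_points_zero_nugget(self, rng, vg):
        pts = rng.uniform(0, 300, size=(30, 2))
        vals = rng.normal(50, 5, 30)
        d = sa.PointDataset(pts[:, 0], pts[:, 1], vals)
        pred = sa.ordinary_kriging(d, vg, pts)
        np.testing.assert_allclose(pred.estimate, vals, atol=1e-8)

    def test_weights_sum_to_one_everywhere(self, rng, vg):
        pts = rng.uniform(0, 300, size=(25, 2))
        d = sa.PointDataset(pts[:, 0], pts[:, 1], rng.normal(size=25))
        targets = rng.uniform(-50, 350, size=(40, 2))
        pred = sa.ordinary_kriging(d, vg, targets, return_weights=True)
        np.testing.assert_allclose(pred.weights.sum(axis=0), 1.0, atol=1e-10)

    def test_symmetric_pair_gets_half_weights(self, vg):
        d = sa.PointDataset([-10.0, 10.0], [0.0, 0.0], [7.0, 7.0])
        pred = sa.ordinary_kriging(d, vg, np.array([[0.0, 0.0]]),
                                   return_weights=True)
        np.testing.assert_allclose(pred.weights[:, 0], [0.5, 0.5], atol=1e-10)
        assert pred.estimate[0] == pytest.approx(7.0, abs=1e-10)

    def test_matches_covariance_form_oracle(self, vg):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(10, 50))
            pts = rng.uniform(0, 400, size=(n, 2))
            vals = rng.normal(60, 8, n)
            d = sa.PointDataset(pts[:, 0], pts[:, 1], vals)
            targets = rng.uniform(0, 400, size=(5, 2))
            pred = sa.ordinary_kriging(d, vg, targets)
            for t, s0 in enumerate(targets):
                want, _ = covariance_kriging_oracle(pts, vals, vg, s0)
                assert pred.estimate[t] == pytest.approx(want, abs=1e-6)

    def test_local_neighborhood_mode_close_to_global(self, rng, vg):
        pts = rng.uniform(0, 300, size=(60, 2))
        vals = rng.normal(50, 5, 60)
        d = sa.PointDataset(pts[:, 0], pts[:, 1], vals)
        targets = rng.uniform(50, 250, size=(10, 2))
        full = sa.ordinary_kriging(d, vg, targets)
        local = sa.ordinary_kriging(d, vg, targets, n_neighbors=30)
        np.testing.assert_allclose(local.estimate, full.estimate, atol=0.5)
        assert np.all(local.variance >= 0)

    def test_duplicate_points_raise_with_guidance(self, vg):
        d = sa.PointDataset([0.0, 0.0, 10.0], [0.0, 0.0, 0.0],
                            [1.0, 1.0, 2.0])
        with pytest.raises(SingularKrigingSystem, match="deduplicate"):
            sa.ordinary_kriging(d, vg, np.array([[5.0, 0.0]]))

    def test_variance_nonnegative_and_zero_on_data(self, rng, vg):
        pts = rng.uniform(0, 200, size=(20, 2))
        d = sa.PointDataset(pts[:, 0], pts[:, 1], rng.normal(size=20))
        pred = sa.ordinary_kriging(d, vg, pts)
        assert np.all(pred.variance >= 0)
        np.testing.assert_allclose(pred.variance, 0.0, atol=1e-8)


class TestSimpleKriging:
    def test_exact_at_data_and_reverts_to_mean_far_away(self, rng):
        from spatialaq.geostat import simple_kriging

        vg = VariogramModel("exponential", nugget=0.0, partial_sill=1.0,
                            range_=50.0)
        pts = rng.uniform(0, 200, size=(20, 2))
        vals = rng.normal(60, 5, 20)
        d = sa.PointDataset(pts[:, 0], pts[:, 1], vals)
        at_data = simple_kriging(d, vg, pts)
        np.testing.assert_allclose(at_data.estimate, vals, atol=1e-8)
        far = simple_kriging(d, vg, np.array([[5000.0, 5000.0]]))
        assert far.estimate[0] == pytest.approx(vals.mean(), abs=1e-6)
        assert far.variance[0] == pytest.approx(vg.sill, abs=1e-6)


class TestKrigeField:
    def test_back_transform_round_trip_at_data_points(self):
        f = sa.simulate_field(
            sa.FieldSpec(bbox=(0, 0, 600, 600), n_points=80, range_=150.0,
                         sill=25.0, nugget=0.0, mean=60.0, seed=9)
        )
        pred, vg, transform = sa.krige_field(f, f.coords)
        # normalize -> krige -> inverse at data-coincident targets returns
        # the original observations when the fitted nugget plays no role
        np.testing.assert_allclose(pred.estimate, f.values, atol=1e-6)
        assert pred.back_transform == transform.kind

    def test_grid_prediction_covers_bbox(self):
        f = sa.simulate_field(sa.FieldSpec(n_points=60, seed=2, sill=4.0))
        targets = sa.prediction_grid(f.bbox(), 250.0)
        pred, _, _ = sa.krige_field(f, targets)
        assert len(pred.estimate) == len(targets)
        assert np.all(np.isfinite(pred.estimate))


class TestIndicatorKriging:
    def test_all_above_threshold_gives_ones(self, rng):
        pts = rng.uniform(0, 300, size=(20, 2))
        d = sa.PointDataset(pts[:, 0], pts[:, 1], rng.uniform(80, 90, 20))
        with pytest.warns(UserWarning, match="one side"):
            pred, vg = sa.indicator_kriging(d, 50.0, rng.uniform(0, 300, (6, 2)))
        np.testing.assert_array_equal(pred.estimate, 1.0)
        assert vg is None

    def test_probabilities_clipped_to_unit_interval(self):
        f = sa.simulate_field(
            sa.FieldSpec(bbox=(0, 0, 800, 800), n_points=150, range_=200.0,
                         sill=100.0, nugget=0.0, mean=55.0, seed=4)
        )
        targets = sa.prediction_grid(f.bbox(), 100.0)
        pred, _ = sa.indicator_kriging(f, 50.0, targets)
        assert np.all(pred.estimate >= 0.0)
        assert np.all(pred.estimate <= 1.0)

    def test_exact_indicator_at_data_points(self):
        f = sa.simulate_field(
            sa.FieldSpec(bbox=(0, 0, 800, 800), n_points=120, range_=200.0,
                         sill=100.0, nugget=0.0, mean=55.0, seed=6)
        )
        pred, _ = sa.indicator_kriging(f, 50.0, f.coords)
        want = (f.values > 50.0).astype(float)
        np.testing.assert_allclose(pred.estimate, want, atol=1e-6)

    def test_transition_crosses_half_between_clusters(self, rng):
        # low-valued cluster on the left, high-valued on the right
        xl = rng.uniform(0, 100, 25)
        xr = rng.uniform(400, 500, 25)
        y = rng.uniform(0, 100, 50)
        vals = np.r_[rng.normal(20, 1, 25), rng.normal(80, 1, 25)]
        d = sa.PointDataset(np.r_[xl, xr], y, vals)
        transect = np.column_stack([np.linspace(0, 500, 51),
                                    np.full(51, 50.0)])
        pred, _ = sa.indicator_kriging(d, 50.0, transect)
        assert pred.estimate[0] < 0.2
        assert pred.estimate[-1] > 0.8
        crossings = np.nonzero(np.diff(pred.estimate >= 0.5))[0]
        assert len(crossings) >= 1
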