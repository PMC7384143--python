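import numpy as np
import pytest

from leafprod.gridding import GridSpec
from leafprod.regress import DegenerateInputError
from leafprod.spatial import (estimate_spatial_covariance, modified_t_test,
                              hierarchical_partition, venn_partition3,
                              soil_pca, SpatialCovariance)
from leafprod.synthetic import GRFSpec, simulate_grf


def _grid_coords(n=15, size=50.0):
    return GridSpec(n, n, size).centres()[["x", "y"]].to_numpy()


class TestSpatialCovariance:
    def test_white_noise_off_diagonals_average_zero(self, rng):
        coords = _grid_coords(14)  # n = 196
        n = coords.shape[0]
        means = []
        for _ in range(10):
            a = rng.standard_normal(n)
            b = rng.standard_normal(n)
            cov = estimate_spatial_covariance(a, b, coords)
            off = cov.sigma_a[~np.eye(n, dtype=bool)]
            means.append(off.mean())
        assert abs(np.mean(means)) < 0.05

    def test_constant_surface_errors(self, rng):
        coords = _grid_coords(4)
        with pytest.raises(DegenerateInputError):
            estimate_spatial_covariance(np.ones(16), rng.normal(size=16), coords)

    def test_single_class_fills_uniformly(self, rng):
        coords = _grid_coords(4)
        cov = estimate_spatial_covariance(rng.normal(size=16),
                                          rng.normal(size=16), coords,
                                          n_classes=1)
        off = cov.sigma_a[~np.eye(16, dtype=bool)]
        assert np.unique(off).size == 1


class TestModifiedTTest:
    def test_identity_covariance_recovers_classical_test(self, rng):
        n = 30
        a, b = rng.standard_normal(n), rng.standard_normal(n)
        eye = SpatialCovariance(np.eye(n), np.eye(n), np.array([0.0]),
                                np.array([]), np.array([]))
        res = modified_t_test(a, b, covariance=eye)
        assert res.m_hat == pytest.approx(n)
        assert res.df == pytest.approx(n - 2)

    def test_ar_like_three_point_effective_sample_size(self, rng):
        # independent trace-formula oracle for the 3-point banded matrix
        S = np.array([[1, .5, .25], [.5, 1, .5], [.25, .5, 1]])
        B = np.eye(3) - np.ones((3, 3)) / 3
        m_oracle = 1 + np.trace(B @ S) ** 2 / np.trace(B @ S @ B @ S)
        cov = SpatialCovariance(S, S, np.array([0.0]), np.array([]), np.array([]))
        res = modified_t_test(rng.normal(size=3), rng.normal(size=3),
                              covariance=cov)
        assert res.m_hat == pytest.approx(m_oracle)
        assert res.m_hat == pytest.approx(2.849, abs=5e-4)

    def test_autocorrelated_fields_lose_effective_samples(self, rng):
        coords = _grid_coords(12)
        spec = GRFSpec(0.0, 1.0, 250.0)
        below = 0
        for _ in range(20):
            a = simulate_grf(coords, spec, rng, {})
            b = simulate_grf(coords, spec, rng, {})
            res = modified_t_test(a, b, coords)
            below += res.m_hat < res.n
        assert below >= 19


class TestHierarchicalPartition:
    def test_two_predictor_closed_form(self, rng):
        # construct data whose subset R^2 are known, then compare with the
        # averaging-over-orderings formula evaluated directly on the ledger
        n = 2000
        x1 = rng.standard_normal(n)
        x2 = 0.5 * x1 + rng.standard_normal(n)
        y = x1 + 0.5 * x2 + rng.standard_normal(n)
        res = hierarchical_partition(y, np.column_stack([x1, x2]))
        r1 = res.subset_r2[(0,)]
        r2 = res.subset_r2[(1,)]
        r12 = res.subset_r2[(0, 1)]
        assert res.independent[0] == pytest.approx(0.5 * r1 + 0.5 * (r12 - r2))
        assert res.independent[1] == pytest.approx(0.5 * r2 + 0.5 * (r12 - r1))
        assert res.independent.sum() + 0 == pytest.approx(r12)

    def test_single_predictor_has_no_joint_effect(self, rng):
        y = rng.standard_normal(50)
        x = y + rng.standard_normal(50)
        res = hierarchical_partition(y, x)
        assert res.independent[0] == pytest.approx(res.full_r2)
        assert res.joint[0] == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_design_has_zero_joint_effects(self):
        n = 64
        t = np.arange(n)
        X = np.column_stack([np.cos(2 * np.pi * t / n),
                             np.sin(2 * np.pi * t / n),
                             np.cos(4 * np.pi * t / n)])
        y = X @ np.array([1.0, 0.5, 0.25]) + 0.0
        res = hierarchical_partition(y, X)
        marg = np.array([res.subset_r2[(i,)] for i in range(3)])
        np.testing.assert_allclose(res.independent, marg, atol=1e-10)
        np.testing.assert_allclose(res.joint, 0.0, atol=1e-10)

    def test_sum_of_independent_effects_is_full_r2(self, rng):
        for k in (2, 3, 4, 5):
            X = rng.standard_normal((200, k)) @ (
                np.eye(k) + 0.4 * rng.standard_normal((k, k)))
            y = X @ rng.standard_normal(k) + rng.standard_normal(200)
            res = hierarchical_partition(y, X)
            assert res.independent.sum() == pytest.approx(res.full_r2, abs=1e-10)

    def test_too_many_predictors_rejected(self, rng):
        with pytest.raises(ValueError):
            hierarchical_partition(rng.normal(size=40),
                                   rng.normal(size=(40, 9)))


class TestVennPartition3:
    def test_orthogonal_predictors_no_shared_variance(self):
        n = 64
        t = np.arange(n)
        A = np.cos(2 * np.pi * t / n)
        B = np.sin(2 * np.pi * t / n)
        C = np.cos(4 * np.pi * t / n)
        y = 1.0 * A + 2.0 * B + 3.0 * C + 0.0
        vp = venn_partition3(y, A, B, C)
        assert vp.triple == pytest.approx(0.0, abs=1e-10)
        assert all(abs(v) < 1e-10 for v in vp.pairwise.values())
        assert vp.components().sum() == pytest.approx(vp.full_r2)

    def test_duplicated_predictor_shares_everything(self, rng):
        n = 500
        A = rng.standard_normal(n)
        C = rng.standard_normal(n)
        y = A + 0.3 * C + 0.5 * rng.standard_normal(n)
        vp = venn_partition3(y, A, A + 0.0, C)
        assert vp.unique["A"] == pytest.approx(0.0, abs=1e-8)
        assert vp.unique["B"] == pytest.approx(0.0, abs=1e-8)
        assert vp.pairwise["AB"] > 0.3

    def test_components_sum_to_full_r2_any_design(self, rng):
        for _ in range(5):
            X = rng.standard_normal((120, 3))
            X[:, 1] += 0.6 * X[:, 0]
            y = X @ np.array([1.0, -0.5, 0.3]) + rng.standard_normal(120)
            vp = venn_partition3(y, X[:, 0], X[:, 1], X[:, 2])
            assert vp.components().sum() == pytest.approx(vp.full_r2, abs=1e-10)


class TestSoilPCA:
    def test_perfectly_correlated_columns(self, rng):
        v = rng.standard_normal(200)
        _, frac = soil_pca(v, 2 * v + 1, -0.5 * v)
        assert frac == pytest.approx(1.0)

    def test_independent_columns_approach_one_third(self, rng):
        n = 100_000
        _, frac = soil_pca(rng.standard_normal(n), rng.standard_normal(n),
                           rng.standard_normal(n))
        assert frac == pytest.approx(1 / 3, abs=0.02)

    def test_sign_convention_organic_carbon_positive(self, rng):
        n = 300
        oc = rng.standard_normal(n)
        scores, _ = soil_pca(0.5 * oc + rng.normal(0, .5, n), oc,
                             0.3 * oc + rng.normal(0, .5, n))
        assert np.corrcoef(scores, oc)[0, 1] > 0
        flipped, _ = soil_pca(-(0.5 * oc + rng.normal(0, .5, n)), oc,
                              0.3 * oc + rng.normal(0, .5, n))
        assert np.corrcoef(flipped, oc)[0, 1] > 0

    def test_zero_variance_column_errors(self, rng):
        with pytest.raises(DegenerateInputError):
            soil_pca(np.ones(50), rng.normal(size=50), rng.normal(size=50))
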