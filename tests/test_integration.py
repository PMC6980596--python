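import numpy as np
import pytest

import craniomorph as cm
from craniomorph.integration import TwoBlockPLS


def _grid_pls_oracle(X1, X2, n_grid=2000):
    """Maximize cov(X1 a, X2 b) over dense grids of unit vectors (2D blocks)."""
    X1c = X1 - X1.mean(axis=0)
    X2c = X2 - X2.mean(axis=0)
    thetas = np.linspace(0, 2 * np.pi, n_grid, endpoint=False)
    A = np.column_stack([np.cos(thetas), np.sin(thetas)])
    s1 = X1c @ A.T  # n x grid
    s2 = X2c @ A.T
    cov = s1.T @ s2 / (len(X1c) - 1)  # grid x grid of cov(X1 a_i, X2 b_j)
    best = np.unravel_index(np.argmax(cov), cov.shape)
    return cov[best], A[best[0]], A[best[1]]


class TestTwoBlockPLS:
    def test_copied_block_has_unit_first_correlation(self, rng):
        X1 = rng.normal(size=(25, 6))
        res = TwoBlockPLS.from_blocks(X1, X1.copy()).fit()
        assert res.r_pls == pytest.approx(1.0, abs=1e-10)

    def test_scalar_blocks_reduce_to_covariance_and_pearson(self, rng):
        x = rng.normal(size=40)
        y = 0.8 * x + rng.normal(scale=0.5, size=40)
        res = TwoBlockPLS.from_blocks(x[:, None], y[:, None]).fit()
        assert res.singular_values[0] == pytest.approx(abs(np.cov(x, y)[0, 1]))
        assert res.axis_correlations[0] == pytest.approx(np.corrcoef(x, y)[0, 1])

    def test_leading_axis_matches_grid_search_oracle(self, rng):
        X1 = rng.normal(size=(50, 2)) @ np.array([[2.0, 0.3], [0.1, 0.7]])
        X2 = X1 @ np.array([[0.5, 1.0], [-0.4, 0.2]]) + rng.normal(
            scale=0.4, size=(50, 2)
        )
        res = TwoBlockPLS.from_blocks(X1, X2).fit()
        sv_oracle, a, b = _grid_pls_oracle(X1, X2)
        assert res.singular_values[0] == pytest.approx(sv_oracle, rel=1e-4)
        assert abs(res.left_vectors[0] @ a) == pytest.approx(1.0, abs=1e-4)
        assert abs(res.right_vectors[0] @ b) == pytest.approx(1.0, abs=1e-4)

    def test_percent_covariance_and_frobenius_identity(self, rng):
        X = rng.normal(size=(30, 12))
        part = cm.ModulePartition({"a": tuple(range(2)), "b": tuple(range(2, 4))})
        res = cm.two_block_pls(X, part)
        assert res.percent_total_covariance.sum() == pytest.approx(100.0)
        X1 = X[:, part.column_indices("a")]
        X2 = X[:, part.column_indices("b")]
        C = (X1 - X1.mean(0)).T @ (X2 - X2.mean(0)) / (len(X) - 1)
        assert (res.singular_values**2).sum() == pytest.approx(
            (C**2).sum(), abs=1e-10
        )

    def test_zero_cross_covariance_flagged_degenerate(self):
        X1 = np.tile([[1.0, 2.0]], (10, 1))  # constant block
        X2 = np.random.default_rng(0).normal(size=(10, 2))
        with pytest.warns(UserWarning, match="zero cross-block"):
            res = TwoBlockPLS.from_blocks(X1, X2).fit()
        assert res.degenerate
        assert np.isnan(res.r_pls)

    def test_axis1_correlation_oriented_non_negative(self, rng):
        x = rng.normal(size=50)
        y = -x + rng.normal(scale=0.1, size=50)  # strongly anti-correlated
        res = TwoBlockPLS.from_blocks(x[:, None], y[:, None]).fit()
        assert res.axis_correlations[0] >= 0


class TestPermutationTest:
    def test_perfect_integration_reaches_minimum_p(self, rng):
        X1 = rng.normal(size=(40, 4))
        res = TwoBlockPLS.from_blocks(X1, X1 + rng.normal(scale=0.05, size=X1.shape)).fit(
            n_perm=999, seed=0
        )
        assert res.p_singular[0] == pytest.approx(1 / 1000)
        assert res.p_correlation[0] == pytest.approx(1 / 1000)

    def test_strong_shared_factor_always_detected(self):
        hits = 0
        for rep in range(10):
            rng = np.random.default_rng(rep)
            f = rng.normal(size=100)
            X1 = np.outer(f, rng.normal(size=4)) + rng.normal(scale=0.5, size=(100, 4))
            X2 = np.outer(f, rng.normal(size=5)) + rng.normal(scale=0.5, size=(100, 5))
            res = TwoBlockPLS.from_blocks(X1, X2).fit(n_perm=199, seed=rep)
            hits += res.p_singular[0] == pytest.approx(1 / 200)
        assert hits >= 9

    def test_seeded_runs_are_identical(self, rng):
        X = rng.normal(size=(25, 9))
        part = cm.ModulePartition({"a": (0,), "b": (1, 2)})
        r1 = cm.pls_permutation_test(X, part, n_perm=199, seed=3)
        r2 = cm.pls_permutation_test(X, part, n_perm=199, seed=3)
        np.testing.assert_array_equal(r1.p_singular, r2.p_singular)
        np.testing.assert_array_equal(r1.p_correlation, r2.p_correlation)


class TestIntegrationSuite:
    def test_axes_bounded_by_rank(self, small_fit, part31, small_dataset):
        groups = small_dataset.groups
        suites = cm.run_integration_suite(
            small_fit, part31, groups, component="symmetric", n_perm=0, seed=0
        )
        for scope, res in suites.items():
            n_scope = (
                len(groups) if scope == "all" else sum(g == scope for g in groups)
            )
            p1 = 3 * len(part31.indices("viscerocranium"))
            p2 = 3 * len(part31.indices("neurocranium"))
            assert res.n_axes <= min(p1, p2, n_scope - 1)

    def test_small_category_skipped(self, small_fit, part31, small_dataset):
        groups = list(small_dataset.groups)
        groups[0] = "rare"
        groups[1:] = [g if g != "rare" else "non-deformed" for g in groups[1:]]
        with pytest.warns(UserWarning, match="skipping category"):
            suites = cm.run_integration_suite(
                small_fit, part31, groups, component="symmetric", n_perm=0, seed=0
            )
        assert "rare" not in suites

    def test_refit_and_subset_both_supported(self, small_fit, part31, small_dataset):
        groups = small_dataset.groups
        refit = cm.run_integration_suite(
            small_fit, part31, groups, component="symmetric",
            refit_per_group=True, n_perm=0, seed=0,
        )
        subset = cm.run_integration_suite(
            small_fit, part31, groups, component="symmetric",
            refit_per_group=False, n_perm=0, seed=0,
        )
        # pooled results identical; per-category close but not identical
        assert refit["all"].r_pls == subset["all"].r_pls
        for g in ("oblique", "non-deformed"):
            assert refit[g].r_pls == pytest.approx(subset[g].r_pls, abs=0.15)
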