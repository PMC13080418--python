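import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st
from scipy.stats import multivariate_normal

from margirt.polychoric import (
    estimate_thresholds,
    polychoric_from_table,
    polychoric_matrix,
    polychoric_pair,
    truncate_sparse_categories,
)

from conftest import make_matrix


def grid_ml_rho(table: np.ndarray, coarse: float = 0.01, fine: float = 1e-4) -> float:
    """Brute-force grid-search ML oracle using scipy's own bivariate CDF.

    Coarse scan over (-0.99, 0.99), then a fine scan around the winner;
    independent of the package's CDF primitive and of its optimizer.
    """
    table = np.asarray(table, dtype=float)
    px = np.cumsum(table.sum(axis=1))[:-1] / table.sum()
    py = np.cumsum(table.sum(axis=0))[:-1] / table.sum()
    from scipy.special import ndtri

    tx, ty = ndtri(px), ndtri(py)
    ax = np.concatenate(([-np.inf], tx, [np.inf]))
    by = np.concatenate(([-np.inf], ty, [np.inf]))

    def nll(rho):
        cov = [[1.0, rho], [rho, 1.0]]
        F = np.zeros((ax.size, by.size))
        for i, a in enumerate(ax):
            for j, b in enumerate(by):
                if np.isinf(a) and a < 0 or np.isinf(b) and b < 0:
                    F[i, j] = 0.0
                else:
                    F[i, j] = multivariate_normal.cdf(
                        [min(a, 37), min(b, 37)], mean=[0, 0], cov=cov
                    )
        cells = np.clip(np.diff(np.diff(F, axis=0), axis=1), 1e-300, 1.0)
        return -np.sum(table * np.log(cells))

    grid = np.arange(-0.99, 0.99 + coarse, coarse)
    best = grid[np.argmin([nll(r) for r in grid])]
    lo, hi = best - coarse, best + coarse
    grid2 = np.arange(lo, hi + fine, fine)
    return float(grid2[np.argmin([nll(r) for r in grid2])])


class TestTruncation:
    def test_sparse_top_category_is_merged(self):
        x = np.repeat([0, 1, 2, 3, 4], [10, 10, 10, 10, 2]).astype(float)
        out = truncate_sparse_categories(x, min_count=3)
        _, counts = np.unique(out, return_counts=True)
        assert counts.tolist() == [10, 10, 10, 12]

    def test_no_merge_when_min_count_met(self):
        x = np.repeat([0, 1, 2], [5, 5, 5]).astype(float)
        assert np.array_equal(truncate_sparse_categories(x, 1), x)

    def test_iterative_merging(self):
        x = np.repeat([0, 1, 2], [9, 1, 1]).astype(float)
        out = truncate_sparse_categories(x, min_count=2)
        _, counts = np.unique(out, return_counts=True)
        assert counts.tolist() == [9, 2]

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            truncate_sparse_categories(np.array([np.nan, np.nan]), 1)

    @given(
        counts=st.lists(st.integers(0, 30), min_size=2, max_size=6),
        min_count=st.integers(1, 5),
    )
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_truncation_contract_on_arbitrary_counts(self, counts, min_count):
        assume(sum(counts) > 0)
        x = np.repeat(np.arange(len(counts)), counts).astype(float)
        out = truncate_sparse_categories(x, min_count)
        levels, merged = np.unique(out, return_counts=True)
        # labels contiguous from zero, size preserved, order preserved
        assert np.array_equal(levels, np.arange(levels.size))
        assert out.size == x.size
        assert np.all(np.diff(out[np.argsort(x, kind="stable")]) >= 0)
        if levels.size > 2:
            assert merged[-1] >= min_count


class TestThresholds:
    def test_even_binary_split_gives_zero(self):
        x = np.repeat([0, 1], 50).astype(float)
        assert estimate_thresholds(x) == pytest.approx([0.0], abs=1e-12)

    def test_symmetric_proportions_give_symmetric_thresholds(self):
        x = np.repeat([0, 1, 2], [25, 50, 25]).astype(float)
        tau = estimate_thresholds(x)
        assert tau[0] == pytest.approx(-tau[1], abs=1e-12)

    def test_thresholds_strictly_increasing(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 5, 500).astype(float)
        assert np.all(np.diff(estimate_thresholds(x)) > 0)

    def test_single_category_rejected(self):
        with pytest.raises(ValueError):
            estimate_thresholds(np.zeros(10))


class TestPairEstimate:
    def test_independent_table_gives_zero(self):
        t = np.outer([40, 30, 30], [25, 50, 25]) / 100.0
        assert abs(polychoric_from_table(t)) < 1e-6

    def test_2x2_matches_grid_search_oracle(self):
        t = np.array([[40.0, 10.0], [10.0, 40.0]])
        assert polychoric_from_table(t) == pytest.approx(grid_ml_rho(t), abs=1e-3)

    def test_simulation_consistency(self):
        rng = np.random.default_rng(1)
        z = rng.multivariate_normal([0, 0], [[1, 0.6], [0.6, 1]], 20000)
        cuts = [-1.0, -0.3, 0.4, 1.1]
        x = np.digitize(z[:, 0], cuts).astype(float)
        y = np.digitize(z[:, 1], cuts).astype(float)
        assert polychoric_pair(x, y) == pytest.approx(0.6, abs=0.02)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_3x3_tables_match_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        table = rng.integers(1, 40, size=(3, 3)).astype(float)
        assert polychoric_from_table(table) == pytest.approx(
            grid_ml_rho(table), abs=1e-3
        )

    def test_empty_pairwise_complete_rejected(self):
        x = np.array([0.0, np.nan, 1.0])
        y = np.array([np.nan, 1.0, np.nan])
        with pytest.raises(ValueError):
            polychoric_pair(x, y)


class TestMatrix:
    def test_two_items_equal_single_pair(self):
        rng = np.random.default_rng(5)
        z = rng.multivariate_normal([0, 0], [[1, 0.4], [0.4, 1]], 2000)
        X = np.column_stack([np.digitize(z[:, 0], [-0.5, 0.5]),
                             np.digitize(z[:, 1], [-0.5, 0.5])])
        mat = make_matrix(X, n_categories=3)
        res = polychoric_matrix(mat)
        pair = polychoric_pair(X[:, 0].astype(float), X[:, 1].astype(float))
        assert res.matrix()[0, 1] == pytest.approx(pair, abs=1e-10)
        assert (res.pair_n.to_numpy() == 2000).all()

    def test_one_factor_model_implied_structure(self):
        rng = np.random.default_rng(6)
        lam = np.array([0.8, 0.7, 0.6, 0.5])
        n = 8000
        f = rng.standard_normal(n)
        Y = lam[None, :] * f[:, None] + rng.standard_normal((n, 4)) * np.sqrt(
            1 - lam**2
        )
        X = np.stack([np.digitize(Y[:, j], [-0.8, 0.0, 0.9]) for j in range(4)], 1)
        res = polychoric_matrix(make_matrix(X, n_categories=4))
        implied = np.outer(lam, lam)
        np.fill_diagonal(implied, 1.0)
        assert np.abs(res.matrix() - implied).max() < 0.05

    def test_symmetry_and_unit_diagonal(self, small_cohort):
        pre, _ = small_cohort
        res = polychoric_matrix(pre.subset(pre.item_ids[:8]))
        R = res.matrix()
        assert np.array_equal(R, R.T)
        assert np.array_equal(np.diag(R), np.ones(8))

    def test_incompatible_pairwise_estimates_are_smoothed(self):
        # pairwise-complete estimation on disjoint person subsets can give
        # mutually inconsistent correlations (x~y, x~z but y~-z), which
        # breaks positive semi-definiteness and must trigger the repair
        rng = np.random.default_rng(7)
        a = rng.integers(0, 3, size=300).astype(float)
        b = rng.integers(0, 3, size=300).astype(float)
        c = rng.integers(0, 3, size=300).astype(float)
        nan = np.full(300, np.nan)
        x = np.concatenate([a, b, nan])
        y = np.concatenate([a, nan, c])
        z = np.concatenate([nan, b, 2.0 - c])
        X = np.column_stack([x, y, z])
        with pytest.warns(UserWarning):
            res = polychoric_matrix(make_matrix(X, n_categories=3))
        assert res.smoothed
        assert np.linalg.eigvalsh(res.matrix()).min() >= -1e-9
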