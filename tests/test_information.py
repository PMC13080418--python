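import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from margirt import information as im
from margirt.types import MarginalGRMItem


@pytest.fixture
def graded_item():
    return MarginalGRMItem("g", a=1.4, b=np.array([-1.0, 0.0, 0.8, 1.6]))


class TestPointInformation:
    def test_zero_discrimination_gives_zero(self):
        flat = MarginalGRMItem("f", a=0.0, b=np.array([]))
        assert np.all(im.point_item_information(flat, np.linspace(-4, 4, 9)) == 0)

    def test_matches_finite_difference_oracle(self, graded_item):
        """I(t) equals the expected negative second derivative of log pi."""
        eps = 1e-5
        for t in [-2.0, -0.3, 0.9, 2.5]:
            p = im.category_probabilities(graded_item, np.array([t - eps, t, t + eps]))
            lp = np.log(p)
            d2 = (lp[0] - 2 * lp[1] + lp[2]) / eps**2
            oracle = -(p[1] * d2).sum()
            got = im.point_item_information(graded_item, t)[0]
            assert got == pytest.approx(oracle, abs=1e-5)

    def test_symmetric_thresholds_give_symmetric_curve(self):
        item = MarginalGRMItem("s", a=1.1, b=np.array([-0.7, 0.7]))
        grid = np.linspace(-3, 3, 61)
        info = im.point_item_information(item, grid)
        assert np.allclose(info, info[::-1], atol=1e-12)

    def test_information_nonnegative_everywhere(self, graded_item):
        info = im.point_item_information(graded_item, np.linspace(-8, 8, 101))
        assert np.all(info >= 0)
        assert np.all(np.isfinite(info))

    @given(
        a=st.floats(0.05, 3.0),
        b=st.lists(st.floats(-3, 3), min_size=1, max_size=5, unique=True),
        metric=st.sampled_from(["ogive", "logistic"]),
    )
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_probabilities_and_information_well_formed(self, a, b, metric):
        item = MarginalGRMItem("h", a=a, b=np.sort(np.array(b)), metric=metric)
        grid = np.linspace(-6, 6, 25)
        probs = im.category_probabilities(item, grid)
        assert np.abs(probs.sum(axis=1) - 1).max() < 1e-12
        info = im.point_item_information(item, grid)
        assert np.all(info >= 0) and np.all(np.isfinite(info))


class TestTestInformation:
    def test_single_item_equals_item_information(self, graded_item):
        grid = np.linspace(-2, 2, 11)
        assert np.allclose(
            im.point_test_information([graded_item], grid),
            im.point_item_information(graded_item, grid),
        )

    def test_duplicated_item_doubles(self, graded_item):
        grid = np.linspace(-2, 2, 11)
        single = im.point_item_information(graded_item, grid)
        double = im.point_test_information([graded_item, graded_item], grid)
        assert np.allclose(double, 2 * single, atol=1e-14)

    def test_subset_monotonicity(self, registry):
        from margirt.synthetic import true_marginal_items

        specs, model = registry
        items = {it.item_id: it for it in true_marginal_items(model, specs)}
        core_om = [items[s.item_id] for s in specs
                   if s.inventory.value == "CORE_OM"]
        core_10 = [items[s.item_id] for s in specs if s.in_core10]
        grid = np.linspace(-4, 4, 41)
        assert np.all(
            im.point_test_information(core_10, grid)
            <= im.point_test_information(core_om, grid) + 1e-12
        )


class TestTotalInformation:
    def test_zero_curve_integrates_to_zero(self):
        assert im.total_information(lambda t: np.zeros_like(t)) == 0.0

    def test_logistic_2pl_closed_form(self):
        item = MarginalGRMItem("x", a=1.0, b=np.array([0.3]), metric="logistic")
        total = im.total_item_information(item, bounds=(-10, 10), n_nodes=201)
        assert total == pytest.approx(1.702, abs=1e-3)

    def test_interval_additivity(self, graded_item):
        fn = lambda t: im.point_item_information(graded_item, t)
        full = im.total_information(fn, bounds=(-6, 6), n_nodes=201)
        left = im.total_information(fn, bounds=(-6, 0), n_nodes=201)
        right = im.total_information(fn, bounds=(0, 6), n_nodes=201)
        assert full == pytest.approx(left + right, abs=1e-9)

    def test_bounds_truncation_adequate_for_central_items(self, registry):
        from margirt.synthetic import true_marginal_items

        specs, model = registry
        items = [it for it in true_marginal_items(model, specs)
                 if it.a > 0 and np.all(np.abs(it.b) < 3)]
        narrow = im.total_test_information(items, bounds=(-6, 6))
        wide = im.total_test_information(items, bounds=(-8, 8), n_nodes=141)
        assert abs(wide - narrow) / wide < 0.005

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            im.total_information(lambda t: t, bounds=(2, -2))


class TestSummaries:
    @pytest.mark.parametrize("total,n,expected", [
        (51.6, 10, 5.16), (26.2, 5, 5.24), (0.0, 7, 0.0),
    ])
    def test_averaging(self, total, n, expected):
        assert im.averaged_total_test_information(total, n) == pytest.approx(expected)

    def test_averaging_rejects_empty(self):
        with pytest.raises(ValueError):
            im.averaged_total_test_information(1.0, 0)

    def test_stdem_values_and_monotonicity(self):
        assert im.stdem(4.0)[0] == pytest.approx(0.5)
        assert im.stdem(1.0)[0] == pytest.approx(1.0)
        assert im.stdem(0.0)[0] == np.inf
        info = np.array([0.5, 1.0, 2.0, 9.0])
        sem = im.stdem(info)
        assert np.all(np.diff(sem) < 0)

    @pytest.mark.parametrize("n_items,factor", [(10, 1.0), (5, 2.0), (34, 10 / 34)])
    def test_scaled_point_curve(self, n_items, factor):
        curve = np.array([1.0, 2.0, 4.0])
        assert np.allclose(im.scaled_point_curve(curve, n_items), factor * curve)


class TestComparisonTable:
    def _series(self, d):
        return pd.Series(d)

    def test_ranked_with_adjacent_differences(self):
        totals = self._series({"A": 26.2, "B": 51.6, "C": 138.6, "D": 27.1})
        counts = self._series({"A": 5, "B": 10, "C": 34, "D": 9})
        averaged = totals / counts
        table = im.comparison_table(totals, averaged, counts)
        assert list(table["measure"]) == ["A", "B", "C", "D"]
        diffs = table["difference_in_averaged_information"].to_numpy()
        assert np.isnan(diffs[0])
        assert diffs[2] == pytest.approx(5.16 - 138.6 / 34, abs=1e-9)

    def test_identical_inventories_zero_difference(self):
        totals = self._series({"A": 10.0, "B": 10.0})
        counts = self._series({"A": 5, "B": 5})
        table = im.comparison_table(totals, totals / counts, counts)
        assert table["difference_in_averaged_information"].iloc[1] == 0.0

    def test_input_order_invariance(self):
        totals = self._series({"X": 5.0, "Y": 9.0, "Z": 7.0})
        counts = self._series({"X": 2, "Y": 3, "Z": 2})
        t1 = im.comparison_table(totals, totals / counts, counts)
        shuffled = ["Z", "X", "Y"]
        t2 = im.comparison_table(totals[shuffled], (totals / counts)[shuffled],
                                 counts[shuffled])
        assert list(t1["measure"]) == list(t2["measure"])
        assert np.allclose(
            t1["averaged_total_test_information"],
            t2["averaged_total_test_information"],
        )
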