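import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from topogaze.cubical import PersistencePair
from topogaze import summaries
from topogaze.summaries import (
    LANDSCAPE_GRID,
    average_landscape,
    betti_curve,
    hedges_g,
    integrated_betti,
    l1_distance,
    landscape,
    landscape_area,
    landscape_from_bars,
    landscape_permutation_test,
)


def bar(b, d, dim=0, essential=False):
    return PersistencePair(dim=dim, birth=b, death=d, essential=essential)


bars_strategy = st.lists(
    st.tuples(st.integers(0, 200), st.integers(1, 55)).map(lambda t: (t[0], t[0] + t[1])),
    min_size=1,
    max_size=12,
)


class TestBettiCurve:
    def test_single_bar_right_open(self):
        curve = betti_curve([bar(10, 20)], 0)
        assert curve[9] == 0 and curve[10] == 1 and curve[19] == 1 and curve[20] == 0

    def test_essential_counted_through_255(self):
        curve = betti_curve([bar(0, 255, essential=True)], 0)
        assert (curve == 1).all()

    def test_integrated_equals_total_persistence(self):
        assert integrated_betti(betti_curve([bar(0, 10)], 0)) == 10
        assert integrated_betti(betti_curve([], 0)) == 0
        assert integrated_betti(betti_curve([bar(0, 10), bar(5, 15)], 0)) == 20

    @given(bars=bars_strategy)
    @settings(max_examples=50, deadline=None)
    def test_conservation(self, bars):
        pairs = [bar(b, d) for b, d in bars]
        assert integrated_betti(betti_curve(pairs, 0)) == sum(d - b for b, d in bars)


class TestLandscape:
    def test_one_bar_triangle(self):
        ls = landscape([bar(0, 10)], 0, min_persistence=5)
        assert ls.n_layers == 1
        peak = ls.layers[0][LANDSCAPE_GRID == 5.0]
        assert peak == 5.0
        assert landscape_area(ls) == pytest.approx(25.0)  # (d-b)^2 / 4

    def test_persistence_threshold_discards_short_bars(self):
        assert landscape([bar(0, 4)], 0, min_persistence=5).n_layers == 0
        assert landscape([bar(0, 5)], 0, min_persistence=5).n_layers == 0  # strictly greater
        assert landscape([bar(0, 6)], 0, min_persistence=5).n_layers == 1

    def test_second_layer_peak(self):
        ls = landscape([bar(0, 10), bar(2, 8)], 0, min_persistence=0)
        assert ls.n_layers == 2
        assert ls.layers[1][LANDSCAPE_GRID == 5.0] == 3.0

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            landscape([bar(0, 10)], 0, min_persistence=-1)

    def test_odd_bar_area_exact(self):
        # peak at a half-integer: (12-3)^2/4 = 20.25 must come out exactly
        ls = landscape_from_bars([(3, 12)])
        assert landscape_area(ls) == pytest.approx(20.25)

    @given(bars=bars_strategy)
    @settings(max_examples=50, deadline=None)
    def test_layers_nested(self, bars):
        ls = landscape_from_bars(bars)
        for k in range(ls.n_layers - 1):
            assert (ls.layers[k] >= ls.layers[k + 1] - 1e-12).all()

    @given(bars=bars_strategy)
    @settings(max_examples=30, deadline=None)
    def test_area_equals_l1_to_empty(self, bars):
        ls = landscape_from_bars(bars)
        empty = landscape_from_bars([])
        assert l1_distance(ls, empty) == pytest.approx(landscape_area(ls))

    def test_disjoint_bars_areas_add(self):
        a = landscape_from_bars([(0, 10)])
        b = landscape_from_bars([(100, 140)])
        both = landscape_from_bars([(0, 10), (100, 140)])
        assert landscape_area(both) == pytest.approx(landscape_area(a) + landscape_area(b))


class TestAverageAndDistance:
    def test_average_of_identical_is_identity(self):
        ls = landscape_from_bars([(0, 20), (5, 30)])
        avg = average_landscape([ls, ls, ls])
        np.testing.assert_allclose(avg.layers, ls.layers)

    def test_average_with_empty_halves(self):
        ls = landscape_from_bars([(0, 10)])
        avg = average_landscape([ls, landscape_from_bars([])])
        np.testing.assert_allclose(avg.layers, 0.5 * ls.layers)

    def test_average_empty_list_rejected(self):
        with pytest.raises(ValueError):
            average_landscape([])

    def test_l1_symmetric_and_zero_on_self(self):
        a = landscape_from_bars([(0, 30), (10, 20)])
        b = landscape_from_bars([(50, 90)])
        assert l1_distance(a, a) == 0
        assert l1_distance(a, b) == pytest.approx(l1_distance(b, a))
        assert l1_distance(a, b) == pytest.approx(landscape_area(a) + landscape_area(b))


class TestPermutationTest:
    def test_identical_groups_give_p_one(self):
        ls = [landscape_from_bars([(0, 10 + i)]) for i in range(10)]
        stat, p = landscape_permutation_test(ls, list(reversed(ls)), n_perm=199, seed=0)
        assert stat == 0
        assert p == pytest.approx(1.0)

    def test_separated_groups_are_significant(self):
        group_a = [landscape_from_bars([(0, 30 + i)]) for i in range(10)]
        group_b = [landscape_from_bars([(150, 390 + 2 * i)]) for i in range(10)]
        _, p = landscape_permutation_test(group_a, group_b, n_perm=999, seed=1)
        assert p <= 0.05

    def test_scaling_both_groups_preserves_p(self):
        group_a = [landscape_from_bars([(0, 20 + i)]) for i in range(6)]
        group_b = [landscape_from_bars([(0, 40 + i)]) for i in range(6)]
        _, p1 = landscape_permutation_test(group_a, group_b, n_perm=299, seed=7)
        dbl = lambda g: [summaries.PersistenceLandscape(2 * ls.layers) for ls in g]
        _, p2 = landscape_permutation_test(dbl(group_a), dbl(group_b), n_perm=299, seed=7)
        assert p1 == p2

    def test_p_in_unit_interval_and_nperm_validated(self):
        a = [landscape_from_bars([(0, 10)])] * 3
        b = [landscape_from_bars([(0, 12)])] * 3
        _, p = landscape_permutation_test(a, b, n_perm=99, seed=3)
        assert 0 < p <= 1
        with pytest.raises(ValueError):
            landscape_permutation_test(a, b, n_perm=0)
        with pytest.raises(ValueError):
            landscape_permutation_test([], b)


class TestHedgesG:
    def test_equal_means_zero(self):
        assert hedges_g([1, 2, 3], [2, 1, 3]) == 0

    def test_hand_computed_example(self):
        # means 0.5 and 1.5, pooled sd sqrt(1/3), J = 1 - 3/23
        g = hedges_g([0, 0, 1, 1], [1, 1, 2, 2])
        assert g == pytest.approx(-np.sqrt(3) * (1 - 3 / 23), abs=1e-12)

    def test_antisymmetry(self, rng):
        x, y = rng.normal(size=8), rng.normal(1.0, size=9)
        assert hedges_g(x, y) == pytest.approx(-hedges_g(y, x))

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        x, y = rng.normal(size=12), rng.normal(0.8, 1.3, size=15)
        assert hedges_g(x, y) == pytest.approx(
            pingouin.compute_effsize(x, y, eftype="hedges"), rel=1e-6
        )

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            hedges_g([1], [1, 2])
        with pytest.raises(ValueError):
            hedges_g([1, 1], [1, 1])
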