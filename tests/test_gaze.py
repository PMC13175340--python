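import numpy as np
import pytest

import topogaze as tg
from topogaze.feature_maps import FeatureMap
from topogaze.gaze import (
    Fixation,
    WeightedECDF,
    complement_weights,
    heatmap,
    ks_stat,
    me_ecdf,
    mse_ecdf,
    uniform_weights,
    weighted_ecdf,
    window_weights,
)


def atom(value):
    """Degenerate one-point distribution as an ECDF."""
    return WeightedECDF(support=np.array([value], dtype=float), cumulative=np.array([1.0]))


def fmap(grid, window=10):
    grid = np.asarray(grid, dtype=float)
    return FeatureMap("density", window, grid,
                      (grid.shape[0] * window, grid.shape[1] * window), "BW")


class TestHeatmap:
    def test_single_fixation_peaks_at_centre(self):
        hm = heatmap([Fixation(x=20, y=15, duration_ms=200)], (31, 41), sigma=3)
        assert not hm.empty
        assert hm.values.sum() == pytest.approx(1.0)
        assert np.unravel_index(hm.values.argmax(), hm.values.shape) == (15, 20)

    def test_threshold_discards_short_fixations(self):
        hm = heatmap([Fixation(x=5, y=5, duration_ms=74)], (11, 11), sigma=2)
        assert hm.empty and (hm.values == 0).all()
        # exactly 75 ms does not qualify either ("lasting over 75 ms")
        assert heatmap([Fixation(x=5, y=5, duration_ms=75)], (11, 11), sigma=2).empty

    def test_mass_proportional_to_duration(self):
        fx = [Fixation(x=10, y=10, duration_ms=100), Fixation(x=50, y=50, duration_ms=300)]
        hm = heatmap(fx, (61, 61), sigma=2)
        m1 = hm.values[:30, :30].sum()
        m2 = hm.values[30:, 30:].sum()
        assert m2 / m1 == pytest.approx(3.0, rel=1e-3)

    def test_out_of_bounds_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamping"):
            hm = heatmap([Fixation(x=99, y=-3, duration_ms=200)], (20, 20), sigma=2)
        assert hm.values.sum() == pytest.approx(1.0)

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            heatmap([], (10, 10), sigma=0)


class TestWindowWeights:
    def test_uniform_heatmap_gives_uniform_weights(self):
        hm = tg.GazeHeatmap(values=np.full((20, 20), 1 / 400))
        w = window_weights(hm, 10)
        np.testing.assert_allclose(w, 0.25)

    def test_concentrated_mass(self):
        v = np.zeros((20, 20))
        v[2, 3] = 1.0
        w = window_weights(tg.GazeHeatmap(values=v), 10)
        assert w[0, 0] == 1.0 and w.sum() == 1.0

    def test_sentinel_heatmap_rejected(self):
        with pytest.raises(ValueError, match="uniform"):
            window_weights(tg.GazeHeatmap(values=np.zeros((10, 10)), empty=True), 5)

    def test_complement_uniform_over_unvisited(self):
        v = np.zeros((20, 20))
        v[0:10, 0:10] = 1 / 100
        w = complement_weights(tg.GazeHeatmap(values=v), 10, eps=0.0)
        np.testing.assert_allclose(w, [[0, 1 / 3], [1 / 3, 1 / 3]])

    def test_complement_fails_when_gaze_everywhere(self):
        hm = tg.GazeHeatmap(values=np.full((20, 20), 1 / 400))
        with pytest.raises(ValueError, match="not-looking"):
            complement_weights(hm, 10, eps=0.0)

    def test_complement_eps_keeps_near_zero_window(self):
        v = np.full((20, 20), 1 / 400)
        v[0:10, 0:10] = 1e-6
        v /= v.sum()
        w = complement_weights(tg.GazeHeatmap(values=v), 10, eps=0.05)
        assert w[0, 0] == 1.0


class TestWeightedECDF:
    def test_uniform_weights_step_quarters(self):
        fm = fmap([[1, 2], [3, 4]])
        e = weighted_ecdf(fm, uniform_weights(fm))
        np.testing.assert_allclose(e.support, [1, 2, 3, 4])
        np.testing.assert_allclose(e.cumulative, [0.25, 0.5, 0.75, 1.0])

    def test_all_weight_on_max_window(self):
        fm = fmap([[1, 2], [3, 4]])
        w = np.zeros((2, 2))
        w[1, 1] = 1.0
        e = weighted_ecdf(fm, w)
        assert e(3.9) == 0.0 and e(4) == 1.0

    def test_evaluates_to_one_beyond_max(self):
        fm = fmap([[5, 7]], window=10)
        e = weighted_ecdf(fm, uniform_weights(fm))
        assert e(1e9) == 1.0 and e(-1) == 0.0

    def test_weight_validation(self):
        fm = fmap([[1, 2]])
        with pytest.raises(ValueError):
            weighted_ecdf(fm, np.array([[0.5, -0.5]]))
        with pytest.raises(ValueError):
            weighted_ecdf(fm, np.array([[0.2, 0.2]]))


class TestECDFStatistics:
    def test_self_comparison_is_zero(self):
        e = atom(10)
        assert mse_ecdf(e, e) == 0 and me_ecdf(e, e) == 0 and ks_stat(e, e) == 0

    def test_step_min_vs_step_max(self):
        # ECDFs differ by 1 at value 0 and agree at 255 on the merged grid
        e_min, e_max = atom(0), atom(255)
        assert mse_ecdf(e_min, e_max) == pytest.approx(0.5)
        assert ks_stat(e_min, e_max) == 1.0
        # the lower-valued distribution has the HIGHER ecdf, so ME is negative
        assert me_ecdf(e_min, e_max) == pytest.approx(-0.5)

    def test_me_sign_convention_one_atom(self):
        """Positive ME means the first distribution sits at higher values."""
        assert me_ecdf(atom(20), atom(10)) == pytest.approx(0.5)
        assert me_ecdf(atom(10), atom(20)) == pytest.approx(-0.5)

    def test_quarter_mass_shift_ks(self):
        e1 = WeightedECDF(np.array([0.0, 255.0]), np.array([0.5, 1.0]))
        e2 = WeightedECDF(np.array([0.0, 255.0]), np.array([0.25, 1.0]))
        assert ks_stat(e1, e2) == pytest.approx(0.25)

    def test_uniform_weighting_matches_intrinsic(self):
        fm = fmap([[1, 5], [2, 8]])
        e1 = weighted_ecdf(fm, uniform_weights(fm))
        e2 = weighted_ecdf(fm, np.full((2, 2), 0.25))
        assert mse_ecdf(e1, e2) == 0

    def test_statistics_within_bounds(self, rng):
        for _ in range(20):
            v1 = np.sort(rng.uniform(0, 255, size=5))
            v2 = np.sort(rng.uniform(0, 255, size=7))
            e1 = WeightedECDF(v1, np.linspace(0.2, 1, 5))
            e2 = WeightedECDF(v2, np.linspace(0.1, 1, 7))
            assert 0 <= mse_ecdf(e1, e2) <= 1
            assert -1 <= me_ecdf(e1, e2) <= 1
            assert 0 <= ks_stat(e1, e2) <= 1


class TestPipelineBehaviour:
    def test_uniform_fixations_converge_to_intrinsic(self):
        """More uniform fixations -> gaze ECDF approaches the intrinsic one."""
        grid = np.arange(36, dtype=float).reshape(6, 6)
        fm = fmap(grid, window=20)
        e_int = weighted_ecdf(fm, uniform_weights(fm))
        errors = []
        for n in (30, 3000):
            fx = tg.simulate_fixations(fm, n=n, bias=0.0, seed=11)
            hm = heatmap(fx, fm.image_shape, sigma=6)
            errors.append(mse_ecdf(e_int, weighted_ecdf(fm, window_weights(hm, 20))))
        assert errors[1] < errors[0]
        assert errors[1] < 0.01

    def test_biased_fixations_positive_me(self):
        grid = np.zeros((6, 6))
        grid[1, 1] = grid[4, 4] = 200.0
        fm = FeatureMap("max_persistence", 20, grid, (120, 120), "BW")
        fx = tg.simulate_fixations(fm, n=150, bias=4.0, seed=5)
        hm = heatmap(fx, fm.image_shape, sigma=5)
        stats = tg.gaze_comparison(fm, hm)
        assert stats["me_looking_vs_notlooking"] > 0
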