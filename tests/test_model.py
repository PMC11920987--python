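import numpy as np
import pytest

from sagloc.model import (DEFAULT_POLAR_GRID, ModelParams, PmvPredictor,
                          binaural_combine, binaural_weight, distance_profile,
                          gaussian_kernel, nearest_bin, predict_pmv,
                          sensorimotor_smear, similarity, to_pmv)
from sagloc.peripheral import GradientProfile
from sagloc.schemes import flat_scheme


class TestDistance:
    def test_zero_at_identical_target(self, templates, grid):
        pl = templates.plane(0.0)
        target = GradientProfile(pl.left[10])
        d = distance_profile(templates, target, flat_scheme(grid), ear="left")
        assert d.d[10] == 0
        assert np.all(d.d >= 0)

    def test_one_hot_weight_selects_band(self, templates, grid):
        pl = templates.plane(0.0)
        target = GradientProfile(pl.left[0])
        w = np.zeros(grid.n_bands - 1)
        b_star = 12
        w[b_star] = 1.0
        d = distance_profile(templates, target, w, ear="left")
        np.testing.assert_allclose(
            d.d, np.abs(pl.left[:, b_star] - target.xi_tilde[b_star]), atol=1e-12)

    def test_matches_double_loop_oracle(self, templates, grid):
        rng = np.random.default_rng(11)
        pl = templates.plane(0.0)
        target = GradientProfile(rng.uniform(0, 5, grid.n_bands - 1))
        w = rng.uniform(0, 1, grid.n_bands - 1)
        w /= w.sum()
        d = distance_profile(templates, target, w, ear="right")
        for i in range(pl.polar.size):
            acc = sum(abs(pl.right[i, b] - target.xi_tilde[b]) * w[b]
                      for b in range(w.size))
            assert abs(d.d[i] - acc) < 1e-12

    def test_band_mismatch_raises(self, templates):
        with pytest.raises(ValueError):
            distance_profile(templates, GradientProfile(np.ones(5)), np.ones(5) / 5)


class TestSimilarity:
    def test_midpoint_at_distance_equal_s(self):
        assert similarity(np.array([0.7]), gamma=3.0, s=0.7)[0] == pytest.approx(0.5)

    def test_saturation(self):
        s = similarity(np.array([-1e4, 1e4]), gamma=5.0, s=0.0)
        assert s[0] == pytest.approx(1.0)
        assert s[1] == pytest.approx(0.0)

    def test_strictly_decreasing_in_distance(self):
        d = np.linspace(0, 5, 100)
        s = similarity(d, gamma=4.0, s=1.0)
        assert np.all(np.diff(s) < 0)

    def test_doubling_gamma_never_shrinks_contrast(self):
        d = np.linspace(-3, 3, 61)
        lo = np.abs(similarity(d, 2.0, 0.0) - 0.5)
        hi = np.abs(similarity(d, 4.0, 0.0) - 0.5)
        assert np.all(hi >= lo - 1e-12)

    def test_nonpositive_gamma_rejected(self):
        with pytest.raises(ValueError):
            similarity(np.array([1.0]), gamma=0.0, s=0.0)


class TestBinaural:
    def test_median_plane_is_simple_average(self):
        l, r = np.array([1.0, 0.0]), np.array([0.0, 1.0])
        np.testing.assert_allclose(binaural_combine(l, r, 0.0), [0.5, 0.5])

    def test_far_lateral_ipsilateral_dominates(self):
        assert binaural_weight(80.0) > 0.95        # left source -> left ear
        assert binaural_weight(-80.0) < 0.05

    def test_identical_ears_identity(self):
        s = np.linspace(0, 1, 10)
        for phi in (-60.0, 0.0, 45.0):
            np.testing.assert_allclose(binaural_combine(s, s, phi), s, atol=1e-15)


class TestSmear:
    def test_tiny_epsilon_is_identity(self):
        rng = np.random.default_rng(0)
        prof = rng.uniform(0, 1, DEFAULT_POLAR_GRID.size)
        out = sensorimotor_smear(prof, 0.01, DEFAULT_POLAR_GRID)
        assert np.max(np.abs(out - prof)) < 1e-6

    def test_delta_becomes_wrapped_gaussian(self):
        delta = np.zeros(DEFAULT_POLAR_GRID.size)
        delta[30] = 1.0
        out = sensorimotor_smear(delta, 12.79, DEFAULT_POLAR_GRID)
        expected = np.roll(gaussian_kernel(12.79, DEFAULT_POLAR_GRID), 30)
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_mass_conservation(self):
        rng = np.random.default_rng(4)
        prof = rng.uniform(0, 2, DEFAULT_POLAR_GRID.size)
        out = sensorimotor_smear(prof, 25.0, DEFAULT_POLAR_GRID)
        assert abs(out.sum() - prof.sum()) < 1e-12

    def test_irregular_grid_rejected(self):
        with pytest.raises(ValueError):
            sensorimotor_smear(np.ones(4), 5.0, np.array([0.0, 1.0, 5.0, 20.0]))


class TestPmv:
    def test_uniform_profile(self):
        pmv = to_pmv(np.ones(72), DEFAULT_POLAR_GRID)
        np.testing.assert_allclose(pmv.p, 1 / 72)

    def test_one_hot_profile(self):
        prof = np.zeros(72)
        prof[5] = 3.0
        pmv = to_pmv(prof, DEFAULT_POLAR_GRID)
        assert pmv.p[5] == 1.0

    def test_random_profiles_sum_to_one(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            pmv = to_pmv(rng.uniform(0, 1, 72), DEFAULT_POLAR_GRID)
            assert pmv.p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            to_pmv(np.zeros(72), DEFAULT_POLAR_GRID)


class TestForwardPass:
    def test_self_match_across_all_targets(self, templates, grid):
        pred = PmvPredictor(templates, flat_scheme(grid))
        pmvs = pred.pmv_matrix(ModelParams(6.0, 0.7, 1.0))  # eps < bin width
        np.testing.assert_allclose(pmvs.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(pmvs.argmax(axis=1) == np.arange(pmvs.shape[0]))

    def test_single_target_mode_at_target(self, templates, grid):
        pmv = predict_pmv(templates, (0.0, 30.0), ModelParams(6.0, 0.7, 1.0),
                          flat_scheme(grid))
        assert pmv.mode() == 30.0

    def test_larger_scatter_raises_entropy(self, templates, grid):
        pred = PmvPredictor(templates, flat_scheme(grid))
        small = pred.pmv_for_target(0.0, ModelParams(6.0, 0.7, 5.0))
        large = pred.pmv_for_target(0.0, ModelParams(6.0, 0.7, 50.0))
        assert large.entropy() > small.entropy()

    def test_extreme_sensitivity_flattens_pmv(self, templates, grid):
        pred = PmvPredictor(templates, flat_scheme(grid))
        mid = pred.pmv_for_target(0.0, ModelParams(6.0, 0.7, 12.79))
        low = pred.pmv_for_target(0.0, ModelParams(6.0, -15.0, 12.79))
        high = pred.pmv_for_target(0.0, ModelParams(6.0, 15.0, 12.79))
        assert low.entropy() > mid.entropy()
        assert high.entropy() > mid.entropy()

    def test_higher_gamma_sharpens_presmear_profile(self, templates, grid):
        pred = PmvPredictor(templates, flat_scheme(grid))
        def contrast(gamma):
            s = similarity(pred._d["left"][18], gamma, 0.7)
            return (s / s.sum()).max()
        gammas = [1.0, 2.0, 4.0, 8.0, 16.0]
        peaks = [contrast(g) for g in gammas]
        assert np.all(np.diff(peaks) >= -1e-12)


class TestNearestBin:
    def test_wraparound_assignment(self):
        # 269 deg is closer to the -90 bin (1 deg away across the seam)
        assert nearest_bin(269.0, DEFAULT_POLAR_GRID) == 0

    def test_tie_goes_to_lower_bin(self):
        # 2.5 deg sits exactly between the 0 and 5 deg bins
        idx = nearest_bin(2.5, DEFAULT_POLAR_GRID)
        assert DEFAULT_POLAR_GRID[idx] == 0.0
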