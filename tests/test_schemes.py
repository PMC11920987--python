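import numpy as np
import pytest

from sagloc.peripheral import ErbBandGrid, erb_band_centers
from sagloc.schemes import (bump_scheme, dt_scheme, flat_scheme,
                            group_sv_weights, lp_scheme, nr_scheme,
                            spatial_variance, sv_weights, make_scheme)
from sagloc.synthetic import SyntheticListenerSpec, make_dtf_set


class TestFlat:
    def test_uniform_weights(self, grid):
        w = flat_scheme(grid).weights
        np.testing.assert_allclose(w, 1.0 / 27, atol=1e-12)

    def test_degenerate_two_band_grid(self):
        g = ErbBandGrid(np.array([1000.0, 1100.0]))
        np.testing.assert_array_equal(flat_scheme(g).weights, [1.0])


class TestBump:
    def test_nr_peaks_at_band_nearest_8khz(self, grid):
        s = nr_scheme(grid)
        f = grid.gradient_frequencies
        assert np.argmax(s.weights) == np.argmin(np.abs(f - 8000))

    def test_dt_peaks_at_band_nearest_6khz(self, grid):
        s = dt_scheme(grid)
        f = grid.gradient_frequencies
        assert np.argmax(s.weights) == np.argmin(np.abs(f - 6000))

    def test_infinite_width_limit_is_flat(self, grid):
        s = bump_scheme(grid, 8000, width=1e6)
        np.testing.assert_allclose(s.weights, flat_scheme(grid).weights, atol=1e-6)

    def test_center_outside_span_raises(self, grid):
        with pytest.raises(ValueError):
            bump_scheme(grid, 100.0)


class TestLowPass:
    def test_strictly_decreasing(self, grid):
        w = lp_scheme(grid).weights
        assert np.all(np.diff(w) < 0)

    def test_decay_to_one_limit_is_flat(self, grid):
        s = lp_scheme(grid, decay=1 - 1e-9)
        np.testing.assert_allclose(s.weights, flat_scheme(grid).weights, atol=1e-6)

    def test_halving_per_octave_closed_form(self, grid):
        w = lp_scheme(grid, decay=0.5).weights
        f = grid.gradient_frequencies
        expected = 0.5 ** np.log2(f / 700.0)
        np.testing.assert_allclose(w, expected / expected.sum(), rtol=1e-12)

    def test_nondecreasing_decay_rejected(self, grid):
        with pytest.raises(ValueError):
            lp_scheme(grid, decay=1.0)


@pytest.fixture(scope="module")
def lateral_listener(grid):
    tset, _ = make_dtf_set(SyntheticListenerSpec(rng_seed=5),
                           lateral_planes=(-20.0, 0.0, 20.0), grid=grid)
    return tset


class TestSpatialVariance:
    def test_median_plane_identical_ears_equals_polar_variance(self, templates):
        import copy
        tset = copy.deepcopy(templates)
        pl = tset.plane(0.0)
        pl.right[:] = pl.left  # force identical ears
        nu = spatial_variance(tset, 0.0)
        np.testing.assert_allclose(nu.nu, pl.left.var(axis=0), rtol=1e-12)

    def test_constant_templates_give_zero(self, grid):
        from sagloc.model import PlaneTemplates, TemplateSet
        k, b = 24, grid.n_bands - 1
        const = np.tile(np.linspace(0, 3, b), (k, 1))
        pl = PlaneTemplates(0.0, np.linspace(-90, 255, k), const, const.copy())
        tset = TemplateSet("c", grid, {0.0: pl})
        # variance of constant columns is zero up to summation round-off
        np.testing.assert_allclose(spatial_variance(tset, 0.0).nu, 0.0,
                                   atol=1e-28)

    def test_matches_bruteforce_oracle(self, lateral_listener):
        from sagloc.model import binaural_weight
        nu = spatial_variance(lateral_listener, 20.0)
        pk, pm = lateral_listener.plane(20.0), lateral_listener.plane(-20.0)
        a = binaural_weight(20.0)
        expected = np.zeros(nu.nu.size)
        for b in range(nu.nu.size):
            vl_k = np.var([row[b] for row in pk.left])
            vr_k = np.var([row[b] for row in pk.right])
            vl_m = np.var([row[b] for row in pm.left])
            vr_m = np.var([row[b] for row in pm.right])
            expected[b] = 0.5 * (vl_k * a + vr_k * (1 - a)
                                 + vl_m * (1 - a) + vr_m * a)
        np.testing.assert_allclose(nu.nu, expected, atol=1e-9)

    def test_mirror_symmetry_is_exact(self, lateral_listener):
        nu_pos = spatial_variance(lateral_listener, 20.0)
        nu_neg = spatial_variance(lateral_listener, -20.0)
        np.testing.assert_array_equal(nu_pos.nu, nu_neg.nu)

    def test_missing_mirror_plane_raises(self, grid):
        tset, _ = make_dtf_set(SyntheticListenerSpec(rng_seed=5),
                               lateral_planes=(20.0,), grid=grid)
        with pytest.raises(ValueError):
            spatial_variance(tset, 20.0)


class TestSvWeights:
    def test_equal_variances_split_evenly(self, grid):
        from sagloc.schemes import SpatialVariance
        g = ErbBandGrid(np.array([1000.0, 1100.0, 1200.0]))
        nu = SpatialVariance(np.array([2.0, 2.0]), g, 0.0)
        np.testing.assert_array_equal(sv_weights(nu).weights, [0.5, 0.5])

    def test_direct_normalization(self):
        from sagloc.schemes import SpatialVariance
        g = ErbBandGrid(np.array([1000.0, 1100.0, 1200.0, 1300.0]))
        nu = SpatialVariance(np.array([0.0, 3.0, 1.0]), g, 0.0)
        np.testing.assert_allclose(sv_weights(nu).weights, [0, 0.75, 0.25])

    def test_scale_invariance(self, templates):
        from sagloc.schemes import SpatialVariance
        nu = spatial_variance(templates, 0.0)
        scaled = SpatialVariance(nu.nu * 7.3, nu.grid, 0.0)
        np.testing.assert_allclose(sv_weights(nu).weights,
                                   sv_weights(scaled).weights, atol=1e-12)

    def test_all_zero_raises(self):
        from sagloc.schemes import SpatialVariance
        g = ErbBandGrid(np.array([1000.0, 1100.0]))
        with pytest.raises(ValueError):
            sv_weights(SpatialVariance(np.array([0.0]), g, 0.0))


class TestGroupSv:
    def _scheme(self, grid, w):
        from sagloc.schemes import WeightingScheme
        w = np.zeros(grid.n_bands - 1) + np.asarray(w)
        return WeightingScheme("SV", w / w.sum(), grid, level="subject")

    def test_single_subject_identity(self, grid):
        s = self._scheme(grid, np.random.default_rng(0).uniform(0.1, 1, 27))
        np.testing.assert_array_equal(group_sv_weights([s]).weights, s.weights)

    def test_two_subject_symmetry(self):
        g = ErbBandGrid(np.array([1000.0, 1100.0, 1200.0]))
        a = self._scheme(g, [1.0, 0.0])
        b = self._scheme(g, [0.0, 1.0])
        np.testing.assert_allclose(group_sv_weights([a, b]).weights, [0.5, 0.5])

    def test_matches_mean_oracle(self, grid):
        rng = np.random.default_rng(9)
        subs = [self._scheme(grid, rng.uniform(0.01, 1, 27)) for _ in range(11)]
        expected = np.mean([s.weights for s in subs], axis=0)
        np.testing.assert_allclose(group_sv_weights(subs).weights, expected,
                                   atol=1e-12)

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            group_sv_weights([])


class TestSchemeInvariants:
    @pytest.mark.parametrize("name", ["Flat", "NR", "DT", "LP"])
    def test_sum_one_nonnegative(self, grid, name):
        s = make_scheme(name, grid)
        assert np.isclose(s.weights.sum(), 1.0, atol=1e-9)
        assert np.all(s.weights >= 0)

    def test_group_sv_peaks_in_upper_half_of_grid(self, grid):
        # the synthetic notch trajectory spans 6-12 kHz, so spatial variance
        # should concentrate in the upper bands (the high-frequency peak the
        # group-level SV scheme is known for)
        tsets = [make_dtf_set(SyntheticListenerSpec(rng_seed=s), grid=grid)[0]
                 for s in range(4)]
        gs = make_scheme("SV", grid, templates=tsets)
        assert np.argmax(gs.weights) >= gs.weights.size // 2

    def test_serialization_round_trip(self, grid):
        from sagloc.schemes import WeightingScheme
        s = nr_scheme(grid)
        back = WeightingScheme.from_frame(s.to_frame(), grid, name="NR")
        np.testing.assert_allclose(back.weights, s.weights, atol=1e-12)
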