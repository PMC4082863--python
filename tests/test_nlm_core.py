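import time

import numpy as np
import pytest

from nlm3d import (
    BoxOutOfBoundsError,
    InvalidParamsError,
    InvalidStrengthError,
    NLMParams,
    PadSpec,
    Volume,
    compute_h_squared,
    denoise_volume,
    denoise_voxel,
    pad_volume,
    patch_sqdist,
    random_volume,
)
from nlm3d.reference_oracle import nlm_naive

from conftest import max_rel_dev


class TestFilterStrength:
    @pytest.mark.parametrize(
        "beta,sigma,card,expected",
        [
            (1.0, 10.0, 11**3, 266200.0),
            (0.5, 2.0, 27, 108.0),
            (2.0, 1.0, 1, 4.0),
        ],
    )
    def test_h_squared_rule(self, beta, sigma, card, expected):
        assert compute_h_squared(beta, sigma, card) == expected

    @pytest.mark.parametrize("beta,sigma", [(1.0, 0.0), (0.0, 10.0), (-1.0, 1.0), (1.0, -2.0)])
    def test_nonpositive_strength_rejected(self, beta, sigma):
        with pytest.raises(InvalidStrengthError):
            compute_h_squared(beta, sigma, 27)

    def test_params_derive_h_squared_from_beta_sigma(self):
        p = NLMParams(search_edge=11, sim_edge=3, beta=1.0, sigma=10.0)
        assert p.h_squared == 266200.0
        q = NLMParams(search_edge=3, sim_edge=3, h=5.0)
        assert q.h_squared == 25.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(search_edge=4, sim_edge=3, h=1.0),  # even search
            dict(search_edge=5, sim_edge=2, h=1.0),  # even sim
            dict(search_edge=3, sim_edge=5, h=1.0),  # sim > search
            dict(search_edge=5, sim_edge=3),  # no strength at all
            dict(search_edge=5, sim_edge=3, h=1.0, beta=1.0, sigma=1.0),  # both
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises((InvalidParamsError, InvalidStrengthError)):
            NLMParams(**kwargs)


class TestPatchSqdist:
    def test_identical_centers_give_zero(self, rng):
        v = Volume(rng.normal(size=(7, 7, 7)))
        assert patch_sqdist(v, (3, 3, 3), (3, 3, 3), 1) == 0.0

    def test_flat_field_gives_zero(self):
        v = Volume(np.full((7, 7, 7), 4.2))
        assert patch_sqdist(v, (2, 3, 2), (4, 3, 4), 1) == 0.0

    def test_single_spike_two_mismatches(self):
        # spike of 2 seen once in each patch -> two terms of 2^2
        data = np.zeros((7, 7, 7))
        data[3, 3, 3] = 2.0
        assert patch_sqdist(Volume(data), (3, 3, 3), (3, 3, 4), 1) == 8.0

    def test_symmetry(self, rng):
        v = Volume(rng.normal(size=(9, 9, 9)))
        for _ in range(10):
            i = tuple(rng.integers(2, 7, size=3))
            j = tuple(rng.integers(2, 7, size=3))
            assert patch_sqdist(v, i, j, 2) == patch_sqdist(v, j, i, 2)

    def test_out_of_bounds_box_rejected(self):
        v = Volume(np.zeros((5, 5, 5)))
        with pytest.raises(BoxOutOfBoundsError):
            patch_sqdist(v, (0, 2, 2), (2, 2, 2), 1)


class TestDenoiseVoxel:
    def test_constant_volume_returns_constant(self):
        v = Volume(np.full((9, 9, 9), 3.5))
        p = NLMParams(search_edge=3, sim_edge=3, h=1.0)
        assert denoise_voxel(v, (4, 4, 4), p) == 3.5

    def test_search_edge_one_is_identity(self, rng):
        v = Volume(rng.normal(size=(5, 5, 5)))
        p = NLMParams(search_edge=1, sim_edge=1, h=1.0)
        assert denoise_voxel(v, (2, 2, 2), p) == v.data[2, 2, 2]

    def test_matches_naive_oracle_at_center(self):
        vol = random_volume((9, 9, 9), seed=42)
        p = NLMParams(search_edge=5, sim_edge=3, h=float(np.sqrt(50.0)))
        padded = pad_volume(vol, PadSpec.for_filter(p.search_radius, p.sim_radius))
        got = denoise_voxel(padded, (4 + p.pad_margin,) * 3, p)
        want = nlm_naive(vol, p).data[4, 4, 4]
        assert got == pytest.approx(want, rel=1e-12)


class TestDenoiseVolume:
    def test_flat_volume_is_fixed_point_bit_exact(self):
        v = Volume(np.full((8, 8, 8), 7.0))
        p = NLMParams(search_edge=5, sim_edge=3, h=2.0)
        out = denoise_volume(v, p)
        assert np.array_equal(out.data, v.data)

    def test_output_within_global_intensity_bounds(self):
        v = random_volume((10, 10, 10), seed=3)
        p = NLMParams(search_edge=5, sim_edge=3, h=1.0)
        out = denoise_volume(v, p)
        assert out.data.min() >= v.data.min() - 1e-12
        assert out.data.max() <= v.data.max() + 1e-12

    def test_matches_oracle_on_seeded_volume(self):
        v = random_volume((12, 12, 12), seed=11)
        p = NLMParams(search_edge=5, sim_edge=3, h=3.0)
        assert max_rel_dev(denoise_volume(v, p), nlm_naive(v, p)) <= 1e-10

    def test_input_not_modified(self):
        v = random_volume((8, 8, 8), seed=5)
        before = v.data.copy()
        denoise_volume(v, NLMParams(search_edge=3, sim_edge=3, h=1.0))
        assert np.array_equal(v.data, before)

    def test_column_and_voxel_traversals_agree_bit_exactly(self):
        v = random_volume((9, 8, 11), seed=9)
        p = NLMParams(search_edge=5, sim_edge=3, h=2.0)
        a = denoise_volume(v, p, traversal="voxel")
        b = denoise_volume(v, p, traversal="column")
        assert np.array_equal(a.data, b.data)

    def test_preserves_storage_dtype(self):
        v = Volume(np.random.default_rng(0).normal(size=(6, 6, 6)).astype(np.float32))
        out = denoise_volume(v, NLMParams(search_edge=3, sim_edge=1, h=1.0))
        assert out.dtype == np.float32

    def test_h_monotone_smoothing_on_noisy_flat_phantom(self):
        noisy = Volume(100.0 + random_volume((12, 12, 12), seed=21).data * 5.0)
        variances = []
        for h in [1.0, 5.0, 25.0, 125.0, 625.0]:
            out = denoise_volume(noisy, NLMParams(search_edge=5, sim_edge=3, h=h))
            variances.append(float(np.var(out.data)))
        assert all(b <= a + 1e-12 for a, b in zip(variances, variances[1:]))

    def test_small_h_limit_returns_input(self):
        v = random_volume((8, 8, 8), seed=2)
        out = denoise_volume(v, NLMParams(search_edge=5, sim_edge=3, h=1e-3))
        assert max_rel_dev(out, v) < 1e-9

    def test_exclude_self_still_averages_neighbours(self):
        v = random_volume((8, 8, 8), seed=4)
        p = NLMParams(search_edge=3, sim_edge=1, h=10.0, include_self=False)
        out = denoise_volume(v, p)
        assert np.isfinite(out.data).all()
        assert not np.array_equal(out.data, v.data)

    def test_runtime_tracks_window_cardinality(self):
        # operation count ~ |V| * |B| * n_voxels: (5^3,3^3) vs (3^3,3^3)
        # should cost ~125/27 = 4.6x; assert within a loose factor-2 band
        v = random_volume((24, 24, 24), seed=1)
        big = NLMParams(search_edge=5, sim_edge=3, h=1.0)
        small = NLMParams(search_edge=3, sim_edge=3, h=1.0)

        def best_of(params, n=3):
            times = []
            for _ in range(n):
                t0 = time.perf_counter()
                denoise_volume(v, params)
                times.append(time.perf_counter() - t0)
            return min(times)

        denoise_volume(v, small)  # warm caches
        ratio = best_of(big) / best_of(small)
        expected = (5**3 * 3**3) / (3**3 * 3**3)
        assert expected / 2 < ratio < expected * 2
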