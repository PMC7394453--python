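import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from b0synth.preprocess import (
    NormalizationParams,
    default_working_grid,
    denormalize_b0,
    denormalize_t1,
    from_working_grid,
    make_sampling_mask,
    match_gain,
    normalize_b0,
    normalize_b0_pair,
    normalize_t1,
    smooth_to_match,
    smoothness_energy,
    to_working_grid,
)


class TestMatchGain:
    def test_pure_gain_removed(self, volume_factory, rng):
        base = rng.random((16, 16, 16)) + 0.5
        b0_d = volume_factory(base)
        b0_u = volume_factory(2.0 * base)
        mask = volume_factory(np.ones_like(base))
        out = match_gain(b0_u, b0_d, mask)
        np.testing.assert_allclose(out.data, b0_d.data, rtol=1e-6)

    def test_matched_medians_identity(self, volume_factory, rng):
        base = rng.random((16, 16, 16)) + 0.5
        vol = volume_factory(base)
        mask = volume_factory(np.ones_like(base))
        out = match_gain(vol, vol.copy(), mask)
        np.testing.assert_allclose(out.data, vol.data, rtol=1e-6)

    def test_scale_factor_from_medians(self, volume_factory):
        # medians 80 (undistorted) and 100 (distorted) -> scale 1.25
        b0_u = volume_factory(np.full((16, 16, 16), 80.0))
        b0_d = volume_factory(np.full((16, 16, 16), 100.0))
        mask = volume_factory(np.ones((16, 16, 16)))
        out = match_gain(b0_u, b0_d, mask)
        np.testing.assert_allclose(out.data / b0_u.data, 1.25)

    def test_zero_median_rejected(self, volume_factory):
        zeros = volume_factory(np.zeros((16, 16, 16)))
        ones = volume_factory(np.ones((16, 16, 16)))
        mask = volume_factory(np.ones((16, 16, 16)))
        with pytest.raises(ValueError, match="degenerate"):
            match_gain(zeros, ones, mask)


class TestT1Normalization:
    @pytest.mark.parametrize(
        "value,expected", [(0.0, -1.0), (75.0, 0.0), (150.0, 1.0), (200.0, 1.0)]
    )
    def test_fixed_range_map(self, volume_factory, value, expected):
        vol = volume_factory(np.full((8, 8, 8), value))
        assert normalize_t1(vol).data[0, 0, 0] == pytest.approx(expected)

    def test_round_trip_in_range(self, volume_factory, rng):
        vol = volume_factory(rng.uniform(0, 150, (8, 8, 8)))
        back = denormalize_t1(normalize_t1(vol))
        np.testing.assert_allclose(back.data, vol.data, atol=1e-4)


class TestB0Normalization:
    def test_p99_maps_to_one_and_zero_to_minus_one(self, volume_factory, rng):
        b0_d = volume_factory(rng.uniform(0, 1000, (16, 16, 16)))
        d_n, _, params = normalize_b0_pair(b0_d)
        p99_vol = volume_factory(np.full((8, 8, 8), params.b0_p99))
        assert normalize_b0(p99_vol, params).data[0, 0, 0] == pytest.approx(1.0)
        zero_vol = volume_factory(np.zeros((8, 8, 8)))
        assert normalize_b0(zero_vol, params).data[0, 0, 0] == pytest.approx(-1.0)

    def test_pileup_not_clipped(self, volume_factory, rng):
        b0_d = volume_factory(rng.uniform(0, 100, (16, 16, 16)))
        _, _, params = normalize_b0_pair(b0_d)
        hot = volume_factory(np.full((8, 8, 8), 1.5 * params.b0_p99))
        assert normalize_b0(hot, params).data[0, 0, 0] == pytest.approx(2.0)

    def test_same_scale_shared_with_pair(self, volume_factory, rng):
        b0_d = volume_factory(rng.uniform(0, 500, (16, 16, 16)))
        b0_u = volume_factory(rng.uniform(0, 500, (16, 16, 16)))
        d_n, u_n, params = normalize_b0_pair(b0_d, b0_u)
        np.testing.assert_allclose(
            u_n.data, 2.0 * b0_u.data / params.b0_p99 - 1.0, rtol=1e-5
        )

    def test_constant_zero_rejected(self, volume_factory):
        with pytest.raises(ValueError, match="percentile"):
            normalize_b0_pair(volume_factory(np.zeros((16, 16, 16))))

    def test_round_trip_exact(self, volume_factory, rng):
        b0_d = volume_factory(rng.uniform(0, 900, (16, 16, 16)))
        d_n, _, params = normalize_b0_pair(b0_d)
        back = denormalize_b0(d_n, params)
        np.testing.assert_allclose(back.data, b0_d.data, atol=1e-3)

    def test_params_validation(self):
        with pytest.raises(ValueError):
            NormalizationParams(b0_p99=0.0)


class TestWorkingGrid:
    def test_identity_resample(self, volume_factory, rng):
        vol = volume_factory(rng.random((16, 16, 16)))
        out, tfm = to_working_grid(vol, vol.shape, vol.affine)
        np.testing.assert_allclose(out.data, vol.data, atol=1e-6)
        assert tfm.validity.all()

    def test_round_trip_on_band_limited_volume(self, volume_factory):
        rng = np.random.default_rng(0)
        smooth = gaussian_filter(rng.random((32, 32, 32)), 3.0)
        vol = volume_factory(smooth, voxel=2.0)
        shape, affine = default_working_grid(vol, voxel_mm=2.5)
        work, tfm = to_working_grid(vol, shape, affine)
        back = from_working_grid(work, tfm)
        valid_src, _ = to_working_grid(
            vol.like(np.ones(vol.shape)), shape, affine
        )
        interior = from_working_grid(valid_src, tfm).data > 0.99
        err = np.abs(back.data - vol.data)[interior]
        assert err.max() < 0.02 * np.ptp(smooth)

    def test_validity_excludes_out_of_fov(self, volume_factory, rng):
        vol = volume_factory(rng.random((16, 16, 16)))
        shifted = vol.affine.copy()
        shifted[0, 3] += 8 * 2.5  # target half a FOV away
        _, tfm = to_working_grid(vol, vol.shape, shifted)
        assert tfm.validity.any() and not tfm.validity.all()

    def test_forward_inverse_consistency(self, volume_factory, rng):
        vol = volume_factory(rng.random((16, 16, 16)))
        shape, affine = default_working_grid(vol)
        _, tfm = to_working_grid(vol, shape, affine)
        np.testing.assert_allclose(
            tfm.forward @ tfm.inverse, np.eye(4), atol=1e-10
        )


class TestSamplingMask:
    def test_all_valid_gives_all_ones(self):
        m = make_sampling_mask(np.ones((8, 8, 8)), np.ones((8, 8, 8)))
        assert m.all()

    def test_intersection_and_idempotence(self, rng):
        a = (rng.random((8, 8, 8)) > 0.3).astype(np.float32)
        b = (rng.random((8, 8, 8)) > 0.3).astype(np.float32)
        m = make_sampling_mask(a, b)
        np.testing.assert_array_equal(m, (a > 0) & (b > 0))
        np.testing.assert_array_equal(make_sampling_mask(m, m), m)

    def test_empty_intersection_rejected(self):
        a = np.zeros((8, 8, 8))
        a[0] = 1
        b = np.zeros((8, 8, 8))
        b[4] = 1
        with pytest.raises(ValueError, match="empty"):
            make_sampling_mask(a, b)


class TestSmoothnessMatching:
    def test_identical_reference_returns_sigma_zero(self, volume_factory, rng):
        vol = volume_factory(rng.random((24, 24, 24)))
        out, sigma = smooth_to_match(vol, vol.copy())
        assert sigma == 0.0
        np.testing.assert_array_equal(out.data, vol.data)

    def test_recovers_known_sigma(self, volume_factory, rng):
        sharp = rng.random((32, 32, 32))
        ref = volume_factory(gaussian_filter(sharp, 0.8))
        out, sigma = smooth_to_match(volume_factory(sharp), ref)
        assert sigma == pytest.approx(0.8, abs=0.15)

    def test_output_statistic_matches_reference(self, volume_factory, rng):
        sharp = rng.random((32, 32, 32))
        ref = volume_factory(gaussian_filter(sharp, 0.6))
        out, _ = smooth_to_match(volume_factory(sharp), ref)
        assert smoothness_energy(out.data) == pytest.approx(
            smoothness_energy(ref.data), rel=0.05
        )
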