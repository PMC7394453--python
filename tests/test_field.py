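import numpy as np
import pytest

from b0synth.core_io import PhaseEncodingSpec
from b0synth.evaluate import masked_mse
from b0synth.field import (
    FieldEstimationConfig,
    correct_subject,
    estimate_field,
    unwarp,
)
from b0synth.phantom import (
    DisplacementField,
    PhantomParams,
    apply_distortion,
    field_to_displacement,
    simulate_subject,
)

FAST_CFG = FieldEstimationConfig(max_iterations=15, cg_iterations=30)


class TestEstimateField:
    def test_null_field_when_images_agree(self, subject_32):
        b0_d = subject_32.b0_u
        pe = PhaseEncodingSpec(1, 1, 0.05)
        d, _ = estimate_field(b0_d, subject_32.b0_u, pe, FAST_CFG)
        assert np.abs(d.shift[subject_32.mask.data > 0]).max() < 0.05

    def test_recovers_constant_shift(self, subject_32):
        pe = PhaseEncodingSpec(1, 1, 0.05)
        const = DisplacementField(np.full(subject_32.b0_u.shape, 1.2), pe)
        b0_d = apply_distortion(subject_32.b0_u, const)
        d, _ = estimate_field(b0_d, subject_32.b0_u, pe, FAST_CFG)
        interior = subject_32.labels >= 1
        # erode to the mask interior: boundary voxels see no signal support
        from scipy.ndimage import binary_erosion

        interior = binary_erosion(interior, iterations=3)
        err = d.shift[interior] - 1.2
        assert np.abs(np.median(d.shift[interior]) - 1.2) < 0.1
        assert np.sqrt(np.mean(err**2)) < 0.25

    def test_smooth_field_rmse_under_quarter_voxel(self, subject_32):
        b0_d, pe = subject_32.b0_d_blips[0]
        d, _ = estimate_field(b0_d, subject_32.b0_u, pe)
        d_true = field_to_displacement(subject_32.truth_field, pe)
        m = subject_32.mask.data > 0
        rmse = np.sqrt(np.mean((d.shift[m] - d_true.shift[m]) ** 2))
        assert rmse < 0.25

    def test_cost_traces_non_increasing(self, subject_32):
        b0_d, pe = subject_32.b0_d_blips[0]
        _, traces = estimate_field(b0_d, subject_32.b0_u, pe, FAST_CFG)
        for trace in traces:
            assert all(np.diff(trace) <= 1e-9)

    def test_roughness_non_increasing_in_lambda(self, subject_two_blip):
        from b0synth.field import _grad_quadform

        s = subject_two_blip
        b0_d, pe = s.b0_d_blips[0]
        rough = []
        for lam in (0.01, 0.1, 1.0, 10.0):
            cfg = FieldEstimationConfig(
                smoothness_lambda=lam, max_iterations=10, cg_iterations=20
            )
            d, _ = estimate_field(b0_d, s.b0_u, pe, cfg)
            rough.append(_grad_quadform(d.shift.astype(np.float64)))
        assert all(b <= a * 1.05 for a, b in zip(rough, rough[1:]))

    def test_polarity_consistency(self, subject_two_blip):
        s = subject_two_blip
        (b1, pe1), (b2, pe2) = s.b0_d_blips
        d1, _ = estimate_field(b1, s.b0_u, pe1, FAST_CFG)
        d2, _ = estimate_field(b2, s.b0_u, pe2, FAST_CFG)
        m = s.mask.data > 0
        assert np.sqrt(np.mean((d1.shift[m] + d2.shift[m]) ** 2)) < 0.3

    def test_zero_readout_reference_required(self, subject_32):
        pe = PhaseEncodingSpec(1, 1, 0.0)
        with pytest.raises(ValueError, match="readout"):
            estimate_field(subject_32.b0_u, subject_32.b0_u, pe, FAST_CFG)


class TestUnwarp:
    def test_zero_displacement_identity(self, subject_32):
        pe = PhaseEncodingSpec(1, 1, 0.05)
        d = DisplacementField(np.zeros(subject_32.b0_u.shape), pe)
        out = unwarp(subject_32.b0_u, d)
        np.testing.assert_allclose(out.data, subject_32.b0_u.data, atol=1e-4)

    def test_inverts_simulated_distortion(self, subject_32):
        # on a band-limited volume the pullback undoes the splatting warp;
        # sharp tissue edges would add an irreducible interpolation floor
        from scipy.ndimage import gaussian_filter

        smooth_b0 = subject_32.b0_u.like(
            gaussian_filter(subject_32.b0_u.data, 1.5)
        )
        pe = subject_32.b0_d_blips[0][1]
        d_true = field_to_displacement(subject_32.truth_field, pe)
        warped = apply_distortion(smooth_b0, d_true)
        out = unwarp(warped, d_true)
        m = subject_32.mask.data > 0
        rmse = np.sqrt(np.mean((out.data[m] - smooth_b0.data[m]) ** 2))
        assert rmse < 0.03 * np.ptp(smooth_b0.data)

    def test_line_sums_close_to_truth_after_unwarp(self, subject_32):
        b0_d, pe = subject_32.b0_d_blips[0]
        d_true = field_to_displacement(subject_32.truth_field, pe)
        out = unwarp(b0_d, d_true)
        sums_u = subject_32.b0_u.data.sum(axis=pe.axis)
        sums_c = out.data.sum(axis=pe.axis)
        busy = sums_u > 0.2 * sums_u.max()
        assert np.abs(sums_c - sums_u)[busy].max() < 0.02 * sums_u[busy].max() * 2


class TestCorrectSubject:
    def test_zero_field_everything_agrees(self):
        params = PhantomParams(grid=(16, 16, 16), field_amplitude_hz=0.0, seed=2)
        s = simulate_subject(params, n_blips=1)
        b0_d, pe = s.b0_d_blips[0]
        res = correct_subject(b0_d, s.b0_u, pe, FAST_CFG)
        m = s.mask.data > 0
        scale = np.ptp(s.b0_u.data)
        assert np.sqrt(masked_mse(res.corrected, s.b0_u, m)) < 0.05 * scale

    def test_oracle_synthesis_halves_error(self):
        # at the working-grid scale (48^3) correction with the truth b0 as
        # reference must at least halve the masked error to truth
        params = PhantomParams(grid=(48, 48, 48), seed=11, n_hotspots=0)
        s = simulate_subject(params, pe_axis=1, readout=0.05, n_blips=1)
        b0_d, pe = s.b0_d_blips[0]
        res = correct_subject(b0_d, s.b0_u, pe)
        m = s.mask.data > 0
        mse_unc = masked_mse(b0_d, s.b0_u, m)
        mse_cor = masked_mse(res.corrected, s.b0_u, m)
        assert mse_cor < 0.5 * mse_unc

    def test_acqparams_artifact(self, subject_32, tmp_path):
        b0_d, pe = subject_32.b0_d_blips[0]
        path = tmp_path / "acqparams.txt"
        res = correct_subject(
            b0_d, subject_32.b0_u, pe, FAST_CFG, acqparams_path=path
        )
        rows = res.acqparams.rows
        assert len(rows) == 2
        assert rows[0][1] > 0 and rows[1][1] == 0.0
        assert rows[0][0][pe.axis] == pe.polarity
        lines = path.read_text().splitlines()
        assert lines[1] == "0 1 0 0"

    def test_degraded_reference_is_worse_than_oracle(self, subject_32):
        from scipy.ndimage import gaussian_filter

        b0_d, pe = subject_32.b0_d_blips[0]
        m = subject_32.mask.data > 0
        oracle = correct_subject(b0_d, subject_32.b0_u, pe, FAST_CFG)
        blurred = subject_32.b0_u.like(
            gaussian_filter(subject_32.b0_u.data, 3.0)
        )
        degraded = correct_subject(b0_d, blurred, pe, FAST_CFG)
        assert masked_mse(oracle.corrected, subject_32.b0_u, m) < masked_mse(
            degraded.corrected, subject_32.b0_u, m
        )
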