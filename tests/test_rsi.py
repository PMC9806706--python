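"""Normalization and four-compartment fitting."""

import numpy as np
import pytest
from scipy.optimize import nnls as scipy_nnls

from rsiscope.model import DIFFUSION_COEFFS, design_matrix, forward_signal
from rsiscope.rsi import (
    DwiSeries,
    build_design_matrix,
    compute_rsirs,
    fit_compartments,
    nnls_many,
    normalize_by_median_b0,
)

B = (0.0, 500.0, 1000.0, 2000.0)


def make_series(signal, normalized=False):
    return DwiSeries(
        signal=signal, b_values=B, voxel_size_mm=(2.5, 2.5, 6.0), normalized=normalized
    )


class TestDesignMatrix:
    def test_b0_row_is_ones(self):
        A = build_design_matrix(B)
        assert np.allclose(A[0], 1.0)

    def test_decay_entries(self):
        A = build_design_matrix(B)
        assert A[2, 1] == pytest.approx(np.exp(-1.8), abs=1e-12)  # b=1000, D=1.8e-3
        assert A[1, 0] == pytest.approx(np.exp(-0.05), abs=1e-12)

    def test_flow_column_zero_off_b0(self):
        A = build_design_matrix(B)
        assert np.all(A[1:, 3] == 0.0)
        assert A[0, 3] == 1.0

    def test_full_rank(self):
        assert np.linalg.matrix_rank(build_design_matrix(B)) == 4


class TestNormalize:
    def test_uniform_b0_becomes_one(self):
        sig = np.zeros((4, 4, 2, 4))
        sig[..., 0] = 400.0
        sig[..., 1:] = 100.0
        mask = np.zeros((4, 4, 2), dtype=bool)
        mask[1:3, 1:3, :] = True
        out = normalize_by_median_b0(make_series(sig), mask)
        assert np.allclose(out.signal[..., 0], 1.0)
        assert out.normalized

    def test_idempotent_at_fixed_point(self):
        rng = np.random.default_rng(0)
        sig = rng.uniform(0.5, 1.5, (4, 4, 2, 4))
        mask = np.ones((4, 4, 2), dtype=bool)
        once = normalize_by_median_b0(make_series(sig), mask)
        twice = normalize_by_median_b0(once, mask)
        assert np.allclose(once.signal, twice.signal, atol=1e-12)

    def test_median_of_three_voxel_mask(self):
        sig = np.zeros((3, 1, 1, 4))
        sig[:, 0, 0, 0] = [2.0, 4.0, 6.0]
        mask = np.ones((3, 1, 1), dtype=bool)
        out = normalize_by_median_b0(make_series(sig), mask)
        assert np.allclose(out.signal[:, 0, 0, 0], [0.5, 1.0, 1.5])

    def test_empty_mask_rejected(self):
        sig = np.ones((3, 3, 3, 4))
        with pytest.raises(ValueError, match="empty"):
            normalize_by_median_b0(make_series(sig), np.zeros((3, 3, 3), bool))

    def test_nonpositive_median_rejected(self):
        sig = np.zeros((3, 3, 3, 4))
        with pytest.raises(ValueError, match="positive"):
            normalize_by_median_b0(make_series(sig), np.ones((3, 3, 3), bool))


class TestFit:
    def voxel_series(self, coeff_rows):
        """Pack a list of 4-vectors into a (n,1,1,4) noiseless series."""
        C = np.asarray(coeff_rows, dtype=float)
        S = forward_signal(C, B)
        return make_series(S.reshape(len(C), 1, 1, 4), normalized=True)

    @pytest.mark.parametrize(
        "true_c",
        [(1.0, 0.0, 0.0, 0.0), (0.0, 0.0, 0.0, 0.0), (0.3, 0.5, 0.15, 0.05)],
    )
    def test_forward_inverse_identity(self, true_c):
        series = self.voxel_series([true_c])
        maps = fit_compartments(series, np.ones((1, 1, 1), bool))
        assert np.allclose(maps.c[0, 0, 0], true_c, atol=1e-8)
        assert maps.residual_rms[0, 0, 0] == pytest.approx(0.0, abs=1e-8)

    def test_pure_restricted_signal_values(self):
        # fractions (1,0,0,0) produce exp(-b*1e-4) at each b
        series = self.voxel_series([(1.0, 0.0, 0.0, 0.0)])
        expect = [1.0, 0.951229, 0.904837, 0.818731]
        assert np.allclose(series.signal[0, 0, 0], expect, atol=1e-6)

    def test_unnormalized_input_rejected(self):
        series = make_series(np.ones((2, 2, 2, 4)))
        with pytest.raises(ValueError, match="normalized"):
            fit_compartments(series, np.ones((2, 2, 2), bool))

    def test_out_of_mask_is_nan(self):
        series = self.voxel_series([(0.3, 0.5, 0.15, 0.05), (0.2, 0.2, 0.2, 0.2)])
        mask = np.array([True, False]).reshape(2, 1, 1)
        maps = fit_compartments(series, mask)
        assert np.all(np.isnan(maps.c[1, 0, 0]))
        assert np.all(np.isfinite(maps.c[0, 0, 0]))

    def test_matches_scipy_nnls_oracle(self):
        """Support-enumeration solver equals scipy's NNLS on random noisy voxels."""
        rng = np.random.default_rng(42)
        A = design_matrix(B)
        n = 150
        C_true = rng.uniform(0, 0.6, (n, 4))
        S = C_true @ A.T + rng.normal(0, 0.1, (n, 4))
        ours, rss = nnls_many(A, S)
        for i in range(n):
            ref, ref_norm = scipy_nnls(A, S[i])
            assert np.allclose(ours[i], ref, atol=1e-6)
            assert rss[i] == pytest.approx(ref_norm**2, abs=1e-9)

    def test_nonnegativity(self):
        rng = np.random.default_rng(7)
        A = design_matrix(B)
        S = rng.normal(0.2, 0.3, (500, 4))  # includes negative signals
        coeffs, _ = nnls_many(A, S)
        assert np.all(coeffs >= 0)

    def test_scaling_covariance(self):
        """Multiplying raw signals by a constant leaves normalized fits unchanged."""
        rng = np.random.default_rng(3)
        C = rng.uniform(0, 0.5, (3, 2, 2, 4))
        S = forward_signal(C.reshape(-1, 4), B).reshape(3, 2, 2, 4)
        S += rng.normal(0, 0.02, S.shape)
        S = np.abs(S)
        mask = np.ones((3, 2, 2), bool)
        fits = []
        for scale in (1.0, 773.2):
            series = normalize_by_median_b0(make_series(S * scale), mask)
            fits.append(fit_compartments(series, mask).c)
        assert np.allclose(fits[0], fits[1], atol=1e-9)

    def test_unconstrained_flag(self):
        """The unconstrained fit interpolates the 4-point signal exactly."""
        rng = np.random.default_rng(11)
        S = np.abs(rng.normal(0.5, 0.3, (4, 1, 1, 4)))
        series = make_series(S, normalized=True)
        maps = fit_compartments(series, np.ones((4, 1, 1), bool), nonnegative=False)
        A = design_matrix(B)
        recon = maps.c[:, 0, 0] @ A.T
        assert np.allclose(recon, S[:, 0, 0], atol=1e-8)


class TestRsirs:
    def test_is_first_compartment(self):
        rng = np.random.default_rng(5)
        C = rng.uniform(0, 0.5, (3, 3, 2, 4))
        S = forward_signal(C.reshape(-1, 4), B).reshape(3, 3, 2, 4)
        series = make_series(S, normalized=True)
        maps = fit_compartments(series, np.ones((3, 3, 2), bool))
        rs = compute_rsirs(maps)
        assert np.allclose(rs.value, maps.c[..., 0], equal_nan=True)
        assert np.allclose(rs.value, C[..., 0], atol=1e-8)

    def test_recovery_under_rician_noise(self, protocol):
        """Tumor-population C1 is recovered accurately at b=0 SNR 20.

        Voxels are drawn across grade groups and per-patient intensities as in
        the simulator; direction-averaged Rician noise at sigma = 0.05.
        """
        from rsiscope.cohort import CohortConfig, _direction_averaged_volume

        cfg = CohortConfig()
        rng = np.random.default_rng(99)
        n = 1000
        base = np.array(cfg.archetypes["tumor"].fractions)
        scale = rng.choice([cfg.grade_c1_scale[g] for g in range(1, 6)], n)
        intensity = np.clip(rng.normal(1.0, cfg.patient_intensity_sd, n), 0.6, 1.4)
        c1 = base[0] * scale * intensity
        C = np.tile(base, (n, 1))
        C[:, 0] = c1
        C[:, 1] = base[1] + base[0] - c1
        C += rng.normal(0, cfg.archetypes["tumor"].fraction_dispersion, C.shape)
        C = np.clip(C, 0, None)
        clean = forward_signal(C, protocol.b_values).reshape(n, 1, 1, 4)
        noisy = _direction_averaged_volume(clean, protocol, cfg.noise_sigma, rng)
        series = make_series(noisy.reshape(n, 1, 1, 4), normalized=True)
        maps = fit_compartments(series, np.ones((n, 1, 1), bool))
        c1_hat = maps.c[:, 0, 0, 0]
        mae = np.abs(c1_hat - C[:, 0]).mean()
        assert mae < 0.05
        from scipy.stats import spearmanr

        rho = spearmanr(c1_hat, C[:, 0]).statistic
        assert rho > 0.9
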