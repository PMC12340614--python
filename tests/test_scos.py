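"""Speckle-contrast pipeline: windowed contrast, noise decomposition, inversion."""

import warnings

import numpy as np
import pytest

from speckleflow import (
    FlowParams,
    InvalidParameterError,
    OpticalMedium,
    SemiInfiniteGeometry,
    dark_calibration,
    effective_beta_spatial,
    fit_kappa2_bfi,
    gain_sensitivity_sweep,
    kappa_squared_theory,
    noise_corrections,
    process_scos,
    simulate_scos_frames,
    spatial_variance,
    windowed_contrast,
)
from speckleflow.exceptions import InsufficientDataError
from speckleflow.scos import CameraCalibration
from speckleflow.synthetic import FrameStack

MEDIUM = OpticalMedium(mua=0.1, musp=6.0)
GEOMETRY = SemiInfiniteGeometry.for_medium(MEDIUM, rho=2.5)


def _flat_calibration(shape=(14, 14), gain=9.64, offset=0.0, variance=0.0):
    return CameraCalibration(
        gain=gain,
        dark_offset_map=np.full(shape, float(offset)),
        dark_variance_map=np.full(shape, float(variance)),
        n_avg=10,
    )


def _dark_stack(n=20, shape=(28, 28), offset=100.0, read_sigma=2.0, seed=0):
    return simulate_scos_frames(MEDIUM, GEOMETRY, 0.0, 0.0, n, seed, shape=shape,
                                read_sigma=read_sigma, dark_offset=offset)


class TestDarkCalibration:
    def test_noiseless_dark_frames_recover_offset_exactly(self):
        frames = np.full((12, 14, 14), 100, dtype=np.uint16)
        cal = dark_calibration(frames, gain=9.64)
        assert cal.dark_offset == pytest.approx(100.0)
        assert cal.dark_variance == pytest.approx(0.0)

    def test_read_noise_variance_recovered(self):
        cal = dark_calibration(_dark_stack(n=600, shape=(14, 14)), gain=9.64)
        # quantized Gaussian read noise sigma=2: variance ~ 4 + 1/12
        assert cal.dark_variance == pytest.approx(4.0 + 1.0 / 12.0, rel=0.10)

    def test_empty_or_short_stack_rejected(self):
        with pytest.raises(InsufficientDataError):
            dark_calibration(np.zeros((0, 14, 14)), gain=9.64)
        with pytest.raises(InsufficientDataError):
            dark_calibration(np.zeros((5, 14, 14)), gain=9.64)

    def test_lit_pixels_trigger_warning(self):
        frames = np.random.default_rng(0).normal(100, 2, size=(20, 14, 14))
        frames[:, 3, 3] = 5000.0
        with pytest.warns(UserWarning, match="lit"):
            dark_calibration(frames, gain=9.64)


class TestWindowedContrast:
    def test_constant_frame_has_zero_contrast(self):
        kappa, mu, valid = windowed_contrast(np.full((14, 14), 50.0), _flat_calibration())
        np.testing.assert_allclose(kappa, 0.0)
        np.testing.assert_allclose(mu, 50.0)
        assert valid.all()

    def test_hand_computed_window(self):
        # one 7x7 window holding 1..49: mean 25, unbiased variance 204.1667
        frame = np.arange(1, 50, dtype=float).reshape(7, 7)
        kappa, mu, _ = windowed_contrast(frame, _flat_calibration(shape=(7, 7)))
        assert mu[0, 0] == pytest.approx(25.0)
        assert kappa[0, 0] == pytest.approx(204.16666666666666 / 625.0, rel=1e-12)

    def test_checkerboard_two_point_distribution(self):
        # 7x7 checkerboard of a=2 (25 cells) and b=4 (24 cells), frozen by
        # direct arithmetic with the unbiased variance convention
        frame = np.empty((7, 7))
        frame[::2, ::2] = frame[1::2, 1::2] = 2.0
        frame[::2, 1::2] = frame[1::2, ::2] = 4.0
        kappa, _, _ = windowed_contrast(frame, _flat_calibration(shape=(7, 7)))
        assert kappa[0, 0] == pytest.approx(0.11493713642334395, rel=1e-12)

    def test_edge_windows_discarded_and_dark_offset_applied(self):
        frame = np.full((16, 18), 60.0)
        kappa, mu, valid = windowed_contrast(frame, _flat_calibration(shape=(16, 18), offset=10.0))
        assert kappa.shape == (2, 2)
        np.testing.assert_allclose(mu, 50.0)

    def test_nonpositive_mean_window_invalid(self):
        frame = np.full((7, 7), 5.0)
        kappa, mu, valid = windowed_contrast(frame, _flat_calibration(shape=(7, 7), offset=10.0))
        assert not valid[0, 0]
        assert np.isnan(kappa[0, 0])


class TestNoiseCorrections:
    def test_shot_and_quantization_terms_by_direct_substitution(self):
        kappa = np.array([[0.5]])
        mu = np.array([[100.0]])
        rec = noise_corrections(kappa, mu, _flat_calibration(shape=(7, 7)), 0.0)
        assert rec.kappa_shot_sq[0, 0] == pytest.approx(9.64 / 100.0)
        mu10 = noise_corrections(kappa, np.array([[10.0]]), _flat_calibration(shape=(7, 7)), 0.0)
        assert mu10.kappa_quant_sq[0, 0] == pytest.approx(1.0 / 1200.0)

    def test_decomposition_identity_holds_exactly(self):
        rng = np.random.default_rng(1)
        kappa = rng.uniform(0.01, 0.5, (4, 4))
        mu = rng.uniform(50, 500, (4, 4))
        rec = noise_corrections(kappa, mu, _flat_calibration(shape=(28, 28), variance=4.0),
                                sigma_spatial_sq=rng.uniform(0, 2, (4, 4)))
        total = (rec.kappa_f_sq + rec.kappa_read_sq + rec.kappa_shot_sq
                 + rec.kappa_quant_sq + rec.kappa_spatial_sq)
        np.testing.assert_allclose(total, rec.kappa_meas_sq, rtol=1e-14)

    def test_negative_fundamental_contrast_flagged_not_clipped(self):
        kappa = np.array([[0.01]])
        mu = np.array([[100.0]])
        rec = noise_corrections(kappa, mu, _flat_calibration(shape=(7, 7)), 0.0)
        assert rec.kappa_f_sq[0, 0] < 0
        assert not rec.valid[0, 0]

    def test_noise_only_frames_give_null_fundamental_contrast(self):
        # speckle-free illumination: corrected kappa_f^2 consistent with zero
        dark = _dark_stack(n=100, seed=11)
        lit = simulate_scos_frames(MEDIUM, GEOMETRY, 1e-8, 2e5, 100, seed=12,
                                   shape=(28, 28), uniform=True, read_sigma=2.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = process_scos(lit, dark, MEDIUM, GEOMETRY, n_avg=100)
        kf = out["kappa_f_sq"]
        stderr = np.std(kf) / np.sqrt(kf.size)
        assert abs(np.mean(kf)) < 3.0 * max(stderr, 1e-6)


class TestSpatialVariance:
    def test_static_vignette_recovered_exactly(self):
        # noise-free frames: with a negligible gain the shot-correction term
        # g * mu / n vanishes and the window variance is returned exactly
        vignette = np.tile(np.linspace(90, 110, 14), (14, 1))
        frames = np.repeat(vignette[None], 12, axis=0)
        cal = _flat_calibration(shape=(14, 14), gain=1e-9)
        sigma_sq = spatial_variance(frames, cal)
        expected = vignette[:7, :7].var(ddof=1)
        assert sigma_sq[0, 0] == pytest.approx(expected, rel=1e-6)

    def test_pure_shot_noise_averages_to_zero(self):
        rng = np.random.default_rng(3)
        g = 9.64
        frames = g * rng.poisson(200.0, size=(400, 14, 14)).astype(float)
        cal = _flat_calibration(shape=(14, 14), gain=g)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sigma_sq = spatial_variance(frames, cal)
        assert np.abs(sigma_sq).max() < 0.15 * g * g * 200.0 / 400 * 10

    def test_single_frame_rejected(self):
        with pytest.raises(InsufficientDataError):
            spatial_variance(np.zeros((1, 14, 14)), _flat_calibration(shape=(14, 14)))


class TestKappaInversion:
    def test_round_trip_from_theory(self):
        beta = 0.3
        truth = np.array([3e-9, 1e-8, 5e-8])
        k2 = np.array([
            kappa_squared_theory(MEDIUM, GEOMETRY, FlowParams.from_bfi(b), beta, 1e-3)
            for b in truth
        ])
        bfi, valid = fit_kappa2_bfi(k2, 1e-3, MEDIUM, GEOMETRY, beta_assumed=beta)
        assert valid.all()
        np.testing.assert_allclose(bfi, truth, rtol=1e-3)

    def test_recovered_bfi_strictly_decreasing_in_contrast(self):
        k2 = np.linspace(0.02, 0.15, 8)
        bfi, valid = fit_kappa2_bfi(k2, 1e-3, MEDIUM, GEOMETRY, beta_assumed=0.3)
        assert valid.all()
        assert np.all(np.diff(bfi) < 0)

    def test_unphysical_contrast_flagged_invalid(self):
        bfi, valid = fit_kappa2_bfi(np.array([-0.01, 0.0, 0.35]), 1e-3, MEDIUM, GEOMETRY,
                                    beta_assumed=0.3)
        assert not valid.any()
        assert np.isnan(bfi).all()

    def test_beta_sensitivity_mostly_cancels_in_relative_flow(self):
        # halving the assumed beta shifts absolute BFi but rBFi moves < 5%
        truths = np.array([1e-8, 2.5e-8])
        beta_true = 0.3
        k2 = np.array([
            kappa_squared_theory(MEDIUM, GEOMETRY, FlowParams.from_bfi(b), beta_true, 1e-3)
            for b in truths
        ])
        bfi_a, _ = fit_kappa2_bfi(k2, 1e-3, MEDIUM, GEOMETRY, beta_assumed=0.3)
        bfi_b, _ = fit_kappa2_bfi(k2, 1e-3, MEDIUM, GEOMETRY, beta_assumed=0.15)
        assert not np.allclose(bfi_a, bfi_b)
        rel_a = bfi_a[1] / bfi_a[0]
        rel_b = bfi_b[1] / bfi_b[0]
        assert abs(rel_b / rel_a - 1.0) < 0.05


class TestEndToEndRecovery:
    def test_absolute_recovery_with_known_spatial_beta(self):
        truth = 1e-8
        stack = simulate_scos_frames(MEDIUM, GEOMETRY, truth, 2e5, 40, seed=21,
                                     shape=(70, 70), substeps=512)
        dark = _dark_stack(n=40, shape=(70, 70), seed=22)
        beta_eff = effective_beta_spatial(2.3, 7)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = process_scos(stack, dark, MEDIUM, GEOMETRY, beta_assumed=beta_eff, n_avg=40)
        recovered = np.nanmedian(out["bfi"][out["valid"]])
        assert recovered == pytest.approx(truth, rel=0.10)

    def test_gain_sweep_directions(self):
        # two-level flow emulating baseline + hyperemia
        bfi = np.concatenate([np.full(12, 1e-8), np.full(12, 2.5e-8)])
        stack = simulate_scos_frames(MEDIUM, GEOMETRY, bfi, 2e5, 24, seed=31,
                                     shape=(42, 42), substeps=256)
        dark = _dark_stack(n=20, shape=(42, 42), seed=32)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rows = gain_sensitivity_sweep(
                stack, dark, MEDIUM, GEOMETRY,
                gains=np.array([9.64 * 0.9, 9.64, 9.64 * 1.1]),
                baseline=slice(0, 12), beta_assumed=effective_beta_spatial(2.3, 7),
                n_avg=24,
            )
        low, true, high = rows
        # overestimated gain -> over-subtracted shot noise -> smaller kappa_f
        # -> inflated flow; underestimated gain reverses both effects
        assert high["bfi_baseline"] > true["bfi_baseline"] > low["bfi_baseline"]
        assert low["min_kappa_f_sq"] > true["min_kappa_f_sq"] > high["min_kappa_f_sq"]
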