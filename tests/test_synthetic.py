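"""Detector-level generators: field statistics, photon counts, interferograms, frames, flow programs."""

import numpy as np
import pytest

from speckleflow import (
    FlowParams,
    InvalidParameterError,
    OpticalMedium,
    SemiInfiniteGeometry,
    cde_target_g1,
    effective_beta_spatial,
    exponential_g1,
    make_flow_program,
    sample_correlated_field,
    simulate_dcs_counts,
    simulate_idws_record,
    simulate_scos_frames,
    stokes_einstein_db,
)
from speckleflow.synthetic import speckle_ratio_to_sigma

MEDIUM = OpticalMedium(mua=0.1, musp=6.0)
GEOMETRY = SemiInfiniteGeometry.for_medium(MEDIUM, rho=2.5)


class TestCorrelatedField:
    def test_exponential_target_autocorrelation(self):
        tau_c = 10e-6
        n, dt = 200_000, 1e-6
        field = sample_correlated_field(exponential_g1(tau_c, n * dt), n, dt, 1, seed=3)
        z = field.field[0].astype(np.complex128)
        lag = int(tau_c / dt)
        emp = np.vdot(z[:-lag], z[lag:]) / (z.size - lag)
        g1_emp = abs(emp) / np.mean(np.abs(z) ** 2)
        assert g1_emp == pytest.approx(np.exp(-1.0), abs=0.02)

    def test_complex_gaussian_intensity_moment(self):
        field = sample_correlated_field(exponential_g1(10e-6, 0.1), 100_000, 1e-6, 2, seed=5)
        intensity = field.intensity()
        ratio = (intensity**2).mean() / intensity.mean() ** 2
        assert ratio == pytest.approx(2.0, abs=0.05)

    def test_zero_mean_circularity(self):
        tau_c, dt = 10e-6, 1e-6
        field = sample_correlated_field(exponential_g1(tau_c, 0.05), 50_000, dt, 4, seed=7)
        z = field.field
        rms = np.sqrt(np.mean(np.abs(z) ** 2))
        # the effective sample count is reduced by the temporal correlation
        n_eff = z.size / (2.0 * tau_c / dt)
        assert abs(z.mean()) / rms <= 3.0 / np.sqrt(n_eff)

    def test_fixed_seed_reproducibility(self):
        a = sample_correlated_field(exponential_g1(5e-6, 0.01), 10_000, 1e-6, 3, seed=42)
        b = sample_correlated_field(exponential_g1(5e-6, 0.01), 10_000, 1e-6, 3, seed=42)
        assert np.array_equal(a.field, b.field)

    def test_distinct_seeds_are_uncorrelated(self):
        a = sample_correlated_field(exponential_g1(5e-6, 0.02), 20_000, 1e-6, 1, seed=1)
        b = sample_correlated_field(exponential_g1(5e-6, 0.02), 20_000, 1e-6, 1, seed=2)
        za, zb = a.field[0], b.field[0]
        cross = abs(np.vdot(za, zb)) / (np.linalg.norm(za) * np.linalg.norm(zb))
        assert cross < 0.05

    def test_grid_coverage_precondition(self):
        with pytest.raises(InvalidParameterError):
            sample_correlated_field(exponential_g1(5e-6, 0.001), 10_000, 1e-6, 1, seed=0)


class TestDcsCounts:
    def test_constant_field_gives_poisson_dispersion(self):
        from speckleflow.synthetic import SpeckleFieldSeries

        field = SpeckleFieldSeries(field=np.ones((1, 200_000), dtype=np.complex64), dt=1e-6)
        counts = simulate_dcs_counts(field, mean_rate=2e5, seed=0)
        x = counts.counts[0].astype(float)
        dispersion = x.var() / x.mean()
        assert dispersion == pytest.approx(1.0, abs=0.05)
        assert x.mean() == pytest.approx(2e5 * 1e-6, rel=0.05)

    def test_zero_intensity_gives_zero_counts(self):
        from speckleflow.synthetic import SpeckleFieldSeries

        field = SpeckleFieldSeries(field=np.zeros((2, 1000), dtype=np.complex64), dt=1e-6)
        counts = simulate_dcs_counts(field, mean_rate=1e5, seed=0)
        assert counts.counts.sum() == 0

    def test_spad_regime_warning(self):
        from speckleflow.synthetic import SpeckleFieldSeries

        field = SpeckleFieldSeries(field=np.ones((1, 100), dtype=np.complex64), dt=1e-2)
        with pytest.warns(UserWarning, match="SPAD"):
            simulate_dcs_counts(field, mean_rate=1e6, seed=0)

    def test_counts_are_nonnegative_integers(self):
        field = sample_correlated_field(exponential_g1(10e-6, 0.01), 10_000, 1e-6, 4, seed=9)
        counts = simulate_dcs_counts(field, mean_rate=3e5, seed=10)
        assert counts.counts.dtype.kind == "i"
        assert counts.counts.min() >= 0


class TestIdwsRecord:
    def _fields(self, n_px=64, n_t=30_000, seed=0):
        target = cde_target_g1(MEDIUM, GEOMETRY, FlowParams.from_bfi(1e-8),
                               tau_max=n_t * 3e-6)
        return sample_correlated_field(target, n_t, 3e-6, n_px, seed=seed)

    def test_mean_tracks_reference_level(self):
        record = simulate_idws_record(self._fields(), reference_level=100.0, seed=1)
        assert record.counts.mean() == pytest.approx(100.0, abs=1.0)

    def test_zero_sample_field_leaves_noise_only(self):
        from speckleflow.synthetic import SpeckleFieldSeries

        fields = SpeckleFieldSeries(field=np.zeros((8, 20_000), dtype=np.complex64), dt=3e-6)
        record = simulate_idws_record(fields, reference_level=100.0, seed=2)
        x = record.counts.astype(float)
        fluct = x - x.mean(axis=1, keepdims=True)
        lagged = np.mean(fluct[:, :-5] * fluct[:, 5:])
        assert abs(lagged) < 0.05 * fluct.var()

    def test_spatial_autocorrelation_half_width(self):
        record = simulate_idws_record(self._fields(n_px=128), reference_level=100.0,
                                      spatial_hwhm=1.5, read_sigma=0.0, seed=3)
        x = record.counts.astype(float)
        fluct = x - x.mean(axis=1, keepdims=True)
        # column-wise spatial autocorrelation of the fluctuation
        corr = np.array([
            np.mean(fluct[:-d or None if d else None] * fluct[d:]) if d else np.mean(fluct**2)
            for d in range(6)
        ])
        corr /= corr[0]
        # half-max crossing by linear interpolation
        below = np.nonzero(corr < 0.5)[0][0]
        hwhm = below - 1 + (corr[below - 1] - 0.5) / (corr[below - 1] - corr[below])
        assert hwhm == pytest.approx(1.5, abs=0.3)

    def test_heterodyne_regime_warning(self):
        with pytest.warns(UserWarning, match="heterodyne"):
            simulate_idws_record(self._fields(n_px=4, n_t=2000), reference_level=10.0,
                                 sample_level=5.0, seed=4)

    def test_counts_clipped_to_bit_depth(self):
        record = simulate_idws_record(self._fields(n_px=4, n_t=2000), reference_level=200.0,
                                      sample_level=20.0, seed=5, bit_depth=8)
        assert record.counts.max() <= 255


class TestScosFrames:
    def test_mean_counts_linear_in_flux(self):
        kw = dict(shape=(32, 32), t_exp=1e-3, substeps=64, read_sigma=0.0,
                  dark_offset=50.0, n_frames=4)
        a = simulate_scos_frames(MEDIUM, GEOMETRY, 1e-8, 1e5, seed=0, **kw)
        b = simulate_scos_frames(MEDIUM, GEOMETRY, 1e-8, 2e5, seed=0, **kw)
        lit_a = a.frames.mean() - 50.0
        lit_b = b.frames.mean() - 50.0
        assert lit_b / lit_a == pytest.approx(2.0, rel=0.02)

    def test_static_speckle_contrast_independent_of_exposure(self):
        kw = dict(shape=(64, 64), substeps=16, read_sigma=0.0, dark_offset=0.0,
                  n_frames=2, shot_noise=False, quantize=False)
        a = simulate_scos_frames(MEDIUM, GEOMETRY, 0.0, 1e5, seed=6, t_exp=1e-3, **kw)
        b = simulate_scos_frames(MEDIUM, GEOMETRY, 0.0, 1e5, seed=6, t_exp=2e-3, **kw)
        ka = a.frames[0].std() / a.frames[0].mean()
        kb = b.frames[0].std() / b.frames[0].mean()
        assert ka == pytest.approx(kb, rel=1e-6)

    def test_uniform_illumination_has_no_speckle(self):
        stack = simulate_scos_frames(MEDIUM, GEOMETRY, 1e-8, 5e5, seed=7, n_frames=2,
                                     shape=(64, 64), substeps=32, uniform=True,
                                     read_sigma=0.0, dark_offset=0.0)
        frame = stack.frames[0].astype(float)
        # residual contrast should be pure shot noise: var ~= gain * mean
        assert frame.var() / (stack.gain * frame.mean()) == pytest.approx(1.0, rel=0.1)

    def test_dark_frames_contain_only_offset_and_read_noise(self):
        stack = simulate_scos_frames(MEDIUM, GEOMETRY, 0.0, 0.0, seed=8, n_frames=5,
                                     shape=(16, 16), read_sigma=2.0, dark_offset=100.0)
        assert stack.frames.mean() == pytest.approx(100.0, abs=1.0)
        assert stack.frames.std() == pytest.approx(np.sqrt(4.0 + 1.0 / 12.0), rel=0.2)

    def test_fixed_seed_reproducibility(self):
        kw = dict(shape=(16, 16), n_frames=3, substeps=32)
        a = simulate_scos_frames(MEDIUM, GEOMETRY, 1e-8, 2e5, seed=9, **kw)
        b = simulate_scos_frames(MEDIUM, GEOMETRY, 1e-8, 2e5, seed=9, **kw)
        assert np.array_equal(a.frames, b.frames)

    def test_speckle_pixel_ratio_sets_blur(self):
        assert speckle_ratio_to_sigma(2.3) == pytest.approx(
            2.3 / (2 * np.sqrt(2 * np.log(2))), rel=1e-12
        )
        assert 0.9 < effective_beta_spatial(2.3, 7) < 0.95
        assert effective_beta_spatial(0.1, 7) == pytest.approx(1.0, abs=1e-6)


class TestExposureIntegration:
    def test_mode_weights_preserve_contrast_moments(self):
        from speckleflow.synthetic import _temporal_modes
        from speckleflow import kappa_squared_theory

        mk = (MEDIUM.mua, MEDIUM.musp, MEDIUM.n_in, MEDIUM.n_out, MEDIUM.wavelength)
        gk = (GEOMETRY.rho, GEOMETRY.z0, GEOMETRY.zb, GEOMETRY.reff)
        weights, pedestal = _temporal_modes(mk, gk, 1e-8, 1e-3, 512)
        assert weights.sum() + pedestal == pytest.approx(1.0, rel=1e-9)
        # sum of squared weights is the temporal contrast of the exposure
        k2 = kappa_squared_theory(MEDIUM, GEOMETRY, FlowParams.from_bfi(1e-8), 1.0, 1e-3)
        assert (weights**2).sum() == pytest.approx(k2, rel=5e-3)

    def test_substep_discretization_converges(self):
        from speckleflow.synthetic import _temporal_modes

        mk = (MEDIUM.mua, MEDIUM.musp, MEDIUM.n_in, MEDIUM.n_out, MEDIUM.wavelength)
        gk = (GEOMETRY.rho, GEOMETRY.z0, GEOMETRY.zb, GEOMETRY.reff)
        coarse, _ = _temporal_modes(mk, gk, 1e-8, 1e-3, 256)
        fine, _ = _temporal_modes(mk, gk, 1e-8, 1e-3, 512)
        assert (coarse**2).sum() == pytest.approx((fine**2).sum(), rel=5e-3)


class TestFlowPrograms:
    def test_cuff_pure_sinusoid_pi_exact_by_construction(self):
        program = make_flow_program("cuff", pi=0.4, pure_sinusoid=True,
                                    baseline_s=20.0, occlusion_s=10.0, recovery_s=10.0)
        base = program.bfi[program.segment_mask("baseline")]
        assert (base.max() - base.min()) / base.mean() == pytest.approx(0.4, rel=1e-9)

    def test_occlusion_suppresses_flow(self):
        program = make_flow_program("cuff", baseline_s=20.0, occlusion_s=30.0, recovery_s=20.0)
        occl = program.bfi[program.segment_mask("occlusion")]
        base = program.bfi[program.segment_mask("baseline")]
        assert occl.mean() < base.mean()
        assert np.all(program.bfi > 0)

    def test_recovery_attains_configured_hyperemic_peak(self):
        program = make_flow_program("cuff", hyperemia_peak_rbfi=2.5, pi=0.0,
                                    baseline_s=10.0, occlusion_s=10.0, recovery_s=60.0)
        base = program.bfi[program.segment_mask("baseline")].mean()
        assert program.bfi.max() / base == pytest.approx(2.5, rel=1e-6)

    def test_hyperemia_below_baseline_rejected(self):
        with pytest.raises(InvalidParameterError):
            make_flow_program("cuff", hyperemia_peak_rbfi=0.9)

    def test_phantom_ramp_endpoints_match_stokes_einstein(self):
        program = make_flow_program("phantom_ramp", duration_s=60.0, fs=2.0)
        assert program.bfi[0] == pytest.approx(stokes_einstein_db(7.0, 97.5e-9, unit="C"), rel=1e-9)
        assert program.bfi[-1] == pytest.approx(stokes_einstein_db(22.0, 97.5e-9, unit="C"), rel=1e-9)
        assert np.all(np.diff(program.bfi) > 0)
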