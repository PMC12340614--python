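"""Cross-modality comparison layer: rBFi, beats, PI, Bland-Altman, paired tests."""

import numpy as np
import pytest

from speckleflow import (
    FlowTimeSeries,
    InvalidParameterError,
    average_waveform,
    bland_altman_nonparametric,
    block_average_downsample,
    detect_beats,
    make_flow_program,
    paired_group_tests,
    per_beat_pulsatility,
    pulsatility_index,
    relative_bfi,
)
from speckleflow.exceptions import InsufficientDataError


def _series(values, fs=20.0, **kw):
    values = np.asarray(values, dtype=float)
    return FlowTimeSeries(time=np.arange(values.size) / fs, values=values, **kw)


def _pulse_train(fs=120.0, f=1.0, duration=60.0, pi=0.4, noise=0.0, seed=0):
    t = np.arange(int(duration * fs)) / fs
    base = 1.0 + 0.5 * pi * np.sin(2 * np.pi * f * t)
    if noise:
        base = base + np.random.default_rng(seed).normal(0, noise, t.size)
    return FlowTimeSeries(time=t, values=base)


class TestRelativeBfi:
    def test_constant_series_becomes_ones(self):
        rel = relative_bfi(_series(np.full(100, 3e-8)), (0.0, 2.0))
        np.testing.assert_allclose(rel.values, 1.0)
        assert rel.relative

    def test_scaling_during_recovery(self):
        values = np.concatenate([np.full(40, 1e-8), np.full(40, 2e-8)])
        rel = relative_bfi(_series(values), (0.0, 2.0))
        np.testing.assert_allclose(rel.values[40:], 2.0)

    def test_baseline_mean_is_exactly_one(self):
        rng = np.random.default_rng(5)
        rel = relative_bfi(_series(rng.uniform(1e-8, 3e-8, 200)), (0.0, 5.0))
        assert rel.values[:100].mean() == pytest.approx(1.0, rel=1e-12)

    def test_empty_baseline_rejected(self):
        with pytest.raises(InvalidParameterError):
            relative_bfi(_series(np.ones(50)), (100.0, 101.0))


class TestBeatDetection:
    def test_clean_pulse_train_peak_count_and_timing(self):
        series = _pulse_train(f=1.0, duration=60.0)
        peaks = detect_beats(series)
        assert abs(peaks.size - 60) <= 1
        # peaks at t = 0.25 + k (sinusoid maxima), within one sample
        expected = 0.25 + np.arange(peaks.size)
        offset = np.round(peaks - expected)
        np.testing.assert_allclose(peaks - offset, expected, atol=1.0 / 120.0 + 1e-9)

    def test_noisy_pulse_train_mostly_recovered(self):
        # SNR 10 on a broad sinusoidal crest: peaks remain within 5% of a
        # cycle of the true systolic times, adequate for beat segmentation
        series = _pulse_train(f=1.0, duration=60.0, noise=0.06, seed=7)
        peaks = detect_beats(series)
        assert abs(peaks.size - 60) <= 2
        expected = 0.25 + np.arange(60)
        hits = sum(np.min(np.abs(expected - p)) <= 0.05 for p in peaks)
        assert hits >= 0.95 * peaks.size

    def test_constant_series_has_no_cardiac_peak(self):
        with pytest.raises(InsufficientDataError):
            detect_beats(_series(np.ones(1200), fs=120.0))

    def test_undersampled_series_rejected(self):
        series = _pulse_train(fs=3.0, f=1.0, duration=30.0)
        with pytest.raises(InvalidParameterError):
            detect_beats(series)


class TestWaveformAveraging:
    def test_identical_beats_have_zero_iqr(self):
        series = _pulse_train(f=1.0, duration=20.0)
        peaks = detect_beats(series)
        wf = average_waveform(series, peaks)
        np.testing.assert_allclose(wf.iqr_high - wf.iqr_low, 0.0, atol=1e-9)
        assert wf.n_beats >= 15

    def test_slow_drift_removed_by_per_beat_normalization(self):
        series = _pulse_train(f=1.0, duration=30.0)
        drift = FlowTimeSeries(time=series.time,
                               values=series.values * (1.0 + 0.002 * series.time))
        peaks = detect_beats(series)
        wf_ref = average_waveform(series, peaks)
        wf_drift = average_waveform(drift, peaks)
        np.testing.assert_allclose(wf_drift.waveform, wf_ref.waveform, atol=5e-3)

    def test_respiration_modulation_iqr_shrinks_with_normalization(self):
        t = np.arange(int(60 * 120)) / 120.0
        resp = 1.0 + 0.15 * np.sin(2 * np.pi * 0.25 * t)
        series = FlowTimeSeries(time=t, values=_pulse_train(duration=60.0).values * resp)
        peaks = detect_beats(series)
        wf_norm = average_waveform(series, peaks, normalize_beats=True)
        wf_raw = average_waveform(series, peaks, normalize_beats=False)
        iqr_norm = np.mean(wf_norm.iqr_high - wf_norm.iqr_low)
        iqr_raw = np.mean(wf_raw.iqr_high - wf_raw.iqr_low)
        assert iqr_norm < iqr_raw

    def test_fewer_than_three_beats_rejected(self):
        series = _pulse_train(duration=2.5)
        with pytest.raises(InsufficientDataError):
            average_waveform(series, np.array([0.25, 1.25]))


class TestPulsatilityIndex:
    def test_constant_waveform_is_zero(self):
        assert pulsatility_index(np.ones(64)) == 0.0

    def test_sinusoid_closed_form(self):
        t = np.linspace(0.0, 1.0, 2001)[:-1]
        w = 1.0 + 0.2 * np.sin(2 * np.pi * t)
        assert pulsatility_index(w) == pytest.approx(0.4, rel=1e-6)

    def test_scale_invariance_and_amplitude_monotonicity(self):
        t = np.linspace(0.0, 1.0, 500)
        w = 1.0 + 0.2 * np.sin(2 * np.pi * t)
        assert pulsatility_index(5.0 * w) == pytest.approx(pulsatility_index(w), rel=1e-12)
        stronger = 1.0 + 0.3 * np.sin(2 * np.pi * t)
        assert pulsatility_index(stronger) > pulsatility_index(w)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(InvalidParameterError):
            pulsatility_index(np.zeros(10) - 1.0)

    def test_block_averaging_sharp_pulses_reduces_pi(self):
        # sharp systolic upstrokes lose amplitude at 6x slower sampling
        program = make_flow_program("cuff", baseline_s=60.0, occlusion_s=1.0,
                                    recovery_s=2.0, fs=120.0, pi=0.4, cardiac_freq=1.0)
        base = program.segment_mask("baseline")
        series = FlowTimeSeries(time=program.time[base], values=program.bfi[base])
        peaks = detect_beats(series)
        pi_fast, _ = per_beat_pulsatility(series, peaks)
        slow = block_average_downsample(series, factor=6)
        pi_slow, _ = per_beat_pulsatility(slow, peaks)
        assert pi_slow < pi_fast

    def test_outlier_beats_removed_by_mad_rule(self):
        series = _pulse_train(f=1.0, duration=40.0)
        values = series.values.copy()
        # one beat with a tripled oscillation (a whole-beat scale factor would
        # be removed by the per-beat mean normalization)
        values[1200:1320] = 1.0 + 3.0 * (values[1200:1320] - 1.0)
        corrupted = FlowTimeSeries(time=series.time, values=values)
        peaks = detect_beats(series)
        pi_mean, kept = per_beat_pulsatility(corrupted, peaks)
        assert kept.size < peaks.size - 1
        assert pi_mean == pytest.approx(0.4, abs=0.05)


class TestBlockAverage:
    def test_six_sample_block_mean(self):
        out = block_average_downsample(np.array([1.0, 2, 3, 4, 5, 6]), factor=6)
        np.testing.assert_allclose(out, [3.5])

    def test_constant_series_unchanged(self):
        out = block_average_downsample(np.full(24, 2.5), factor=6)
        np.testing.assert_allclose(out, 2.5)

    def test_alternating_series_cancels(self):
        out = block_average_downsample(np.resize([1.0, -1.0], 10), factor=2)
        np.testing.assert_allclose(out, 0.0)

    def test_trailing_partial_block_dropped(self):
        out = block_average_downsample(np.arange(10.0), factor=3)
        assert out.size == 3

    def test_invalid_factor_rejected(self):
        with pytest.raises(InvalidParameterError):
            block_average_downsample(np.arange(10.0), factor=0)


class TestBlandAltman:
    def test_perfect_agreement(self):
        r = np.linspace(1.0, 2.0, 50)
        res = bland_altman_nonparametric(r, r)
        assert res.bias == res.loa_low == res.loa_high == res.rpc == 0.0

    def test_pure_five_percent_offset(self):
        r = np.linspace(1.0, 2.0, 50)
        res = bland_altman_nonparametric(1.05 * r, r)
        assert res.bias == pytest.approx(5.0, rel=1e-9)
        assert res.rpc == pytest.approx(0.0, abs=1e-9)

    def test_gaussian_differences_match_quantile_oracle(self):
        # d ~ N(0, 3%): 2.5/97.5 percentiles at +/- 1.96 * 3 = 5.88%
        rng = np.random.default_rng(9)
        r = np.full(10_000, 10.0)
        m = r * (1.0 + rng.normal(0.0, 0.03, r.size))
        res = bland_altman_nonparametric(m, r)
        assert res.loa_low == pytest.approx(-5.88, abs=0.3)
        assert res.loa_high == pytest.approx(5.88, abs=0.3)
        assert res.rpc == pytest.approx(5.88, abs=0.3)

    def test_zero_references_dropped_with_count(self):
        r = np.concatenate([np.zeros(3), np.ones(20)])
        m = np.ones(23)
        res = bland_altman_nonparametric(m, r)
        assert res.n == 20 and res.n_dropped == 3

    def test_common_rescaling_invariance(self):
        rng = np.random.default_rng(11)
        r = rng.uniform(1, 2, 40)
        m = r * (1 + rng.normal(0, 0.05, 40))
        a = bland_altman_nonparametric(m, r)
        b = bland_altman_nonparametric(7.0 * m, 7.0 * r)
        assert a.bias == pytest.approx(b.bias)
        assert a.rpc == pytest.approx(b.rpc)


class TestPairedGroupTests:
    def test_identical_modalities_show_no_effect(self):
        vals = np.array([1.0, 1.2, 1.4, 1.6, 1.8])
        out = paired_group_tests({"dcs": vals, "idws": vals, "scos": vals})
        assert out["friedman_p"] > 0.5
        assert np.allclose(out["pearson_r"], 1.0)
        assert all(p == 1.0 for p in out["wilcoxon_p"].values())

    def test_constant_shift_detected_by_wilcoxon_sign_bound(self):
        rng = np.random.default_rng(13)
        base = rng.uniform(1, 2, 8)
        out = paired_group_tests({"a": base, "b": base + 0.5})
        # sign-consistency bound for n paired runs: p <= 2 * (1/2)^n
        assert out["wilcoxon_p"][("a", "b")] <= 2 * 0.5**8 + 1e-12

    def test_noisier_modality_flagged_in_pi_comparison(self):
        # PI estimates inflated by channel noise on one modality only
        rng = np.random.default_rng(15)
        n_runs = 10
        quiet = 0.40 + rng.normal(0.0, 0.01, (2, n_runs))
        noisy = 0.48 + rng.normal(0.0, 0.03, n_runs)
        out = paired_group_tests({"dcs": noisy, "idws": quiet[0], "scos": quiet[1]})
        assert out["friedman_p"] < 0.05
        assert out["wilcoxon_p"][("dcs", "idws")] < 0.05
        assert out["wilcoxon_p"][("dcs", "scos")] < 0.05
        assert out["wilcoxon_p"][("idws", "scos")] > 0.05

    def test_fewer_than_three_runs_rejected(self):
        with pytest.raises(InsufficientDataError):
            paired_group_tests({"a": np.ones(2), "b": np.ones(2)})
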