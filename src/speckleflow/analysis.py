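"""Cross-modality flow comparison: rBFi, pulsatility, agreement statistics.

Operates on sampled blood-flow-index time series regardless of which
detection modality produced them: baseline normalization to relative flow
(rBFi), systolic-peak detection from the highest-rate series, per-beat
waveform averaging on a common cardiac phase grid, the pulsatility index
PI = (max - min) / mean, block-average downsampling, nonparametric
Bland-Altman agreement (median bias, 2.5/97.5 percentile limits of
agreement, reproducibility coefficient), and paired group statistics
(Friedman, pairwise Wilcoxon signed-rank, Pearson correlation and linear
fits).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

from .exceptions import InsufficientDataError, InvalidParameterError

#: scaled-MAD consistency constant for a normal distribution
MAD_SCALE = 1.4826


@dataclass
class FlowTimeSeries:
    """A sampled BFi (or rBFi) trace for one modality."""

    time: np.ndarray
    values: np.ndarray
    modality: str = ""
    relative: bool = False
    segment: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.values.shape:
            raise InvalidParameterError("time and values must be matching 1-d arrays")
        if self.time.size >= 2:
            dt = np.diff(self.time)
            if np.any(dt <= 0):
                raise InvalidParameterError("time must be strictly increasing")
            if np.any(np.abs(dt - dt.mean()) > dt.mean() + 1e-9):
                raise InvalidParameterError("sampling must be uniform within one period")

    @property
    def fs(self) -> float:
        if self.time.size < 2:
            raise InvalidParameterError("need >= 2 samples for a sampling rate")
        return 1.0 / float(np.mean(np.diff(self.time)))


@dataclass
class PulsatileWaveform:
    """Phase-gridded average cardiac waveform (per-beat mean normalized)."""

    phase: np.ndarray
    waveform: np.ndarray
    iqr_low: np.ndarray
    iqr_high: np.ndarray
    n_beats: int
    pi: float = field(init=False)

    def __post_init__(self) -> None:
        self.pi = pulsatility_index(self.waveform)


@dataclass
class BlandAltmanResult:
    """Nonparametric agreement between a measurement and a reference."""

    bias: float
    loa_low: float
    loa_high: float
    rpc: float
    n: int
    n_dropped: int = 0


def relative_bfi(
    series: FlowTimeSeries, baseline: tuple[float, float] | np.ndarray
) -> FlowTimeSeries:
    """Normalize a series by its mean over the baseline window.

    ``baseline`` is either a (t_start, t_stop) span or a boolean mask. The
    output has baseline mean exactly 1.
    """
    if isinstance(baseline, tuple):
        mask = (series.time >= baseline[0]) & (series.time < baseline[1])
    else:
        mask = np.asarray(baseline, dtype=bool)
    base = series.values[mask]
    base = base[np.isfinite(base)]
    if base.size == 0:
        raise InvalidParameterError("baseline window contains no valid samples")
    mean = float(base.mean())
    if mean <= 0:
        raise InvalidParameterError("baseline mean must be positive")
    return FlowTimeSeries(
        time=series.time,
        values=series.values / mean,
        modality=series.modality,
        relative=True,
        segment=series.segment,
    )


def estimate_cardiac_frequency(
    series: FlowTimeSeries, band: tuple[float, float] = (0.5, 3.0)
) -> float:
    """Dominant spectral frequency in the cardiac band.

    Raises if the series carries no oscillatory power in the band (e.g. a
    constant trace).
    """
    x = series.values - np.nanmean(series.values)
    x = np.nan_to_num(x)
    scale = float(np.nanmax(np.abs(series.values))) if series.values.size else 0.0
    if scale == 0.0 or np.std(x) <= 1e-12 * scale:
        raise InsufficientDataError("series is constant: no cardiac component")
    freqs, power = signal.periodogram(x, fs=series.fs)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if not in_band.any():
        raise InsufficientDataError("no spectral estimate inside the cardiac band")
    p_band = power[in_band]
    peak = float(freqs[in_band][np.argmax(p_band)])
    if p_band.max() <= 5.0 * np.median(power[freqs > 0]):
        raise InsufficientDataError("no dominant spectral peak in the cardiac band")
    return peak


def detect_beats(series: FlowTimeSeries, band: tuple[float, float] = (0.5, 3.0)) -> np.ndarray:
    """Systolic peak times from the highest-rate modality.

    The cardiac frequency f is estimated from the dominant spectral peak in
    the band; local maxima separated by at least 0.5 / f are returned as
    peak times, to be shared across modalities.
    """
    f = estimate_cardiac_frequency(series, band=band)
    if series.fs < 4.0 * f:
        raise InvalidParameterError("sampling rate must be >= 4x the cardiac frequency")
    values = np.nan_to_num(series.values, nan=float(np.nanmedian(series.values)))
    # zero-phase smoothing over ~1/4 cycle so measurement noise cannot pull
    # the detected maximum off the systolic crest
    width = max(1, int(round(0.25 / f * series.fs)))
    if width > 1:
        window = np.hanning(width + 2)[1:-1]
        values = np.convolve(values, window / window.sum(), mode="same")
    distance = max(1, int(round(0.5 / f * series.fs)))
    peaks, _ = signal.find_peaks(values, distance=distance)
    times = series.time[peaks]
    # drop smoothing-edge artifacts within a quarter cycle of the record ends
    margin = 0.25 / f
    keep = (times >= series.time[0] + margin) & (times <= series.time[-1] - margin)
    return times[keep]


def _beat_slices(time: np.ndarray, peak_times: np.ndarray) -> list[np.ndarray]:
    out = []
    for t0, t1 in zip(peak_times[:-1], peak_times[1:]):
        idx = np.nonzero((time >= t0) & (time < t1))[0]
        if idx.size >= 3:
            out.append(idx)
    return out


def average_waveform(
    series: FlowTimeSeries,
    peak_times: np.ndarray,
    n_phase: int = 64,
    normalize_beats: bool = True,
) -> PulsatileWaveform:
    """Median cardiac waveform on a common phase grid.

    Each beat (peak-to-peak span) is linearly resampled onto ``n_phase``
    points and — with ``normalize_beats`` — divided by its own mean to
    strip slow multiplicative drifts (respiration); the pointwise median
    and interquartile band across beats are returned.
    """
    beats = _beat_slices(series.time, np.asarray(peak_times, dtype=float))
    if len(beats) < 3:
        raise InsufficientDataError("need at least 3 complete beats")
    phase = np.linspace(0.0, 1.0, n_phase)
    resampled = []
    for idx in beats:
        t = series.time[idx]
        v = series.values[idx]
        if not np.all(np.isfinite(v)):
            continue
        local = (t - t[0]) / (t[-1] - t[0])
        w = np.interp(phase, local, v)
        if normalize_beats:
            m = w.mean()
            if m <= 0:
                continue
            w = w / m
        resampled.append(w)
    if len(resampled) < 3:
        raise InsufficientDataError("fewer than 3 usable beats after filtering")
    arr = np.asarray(resampled)
    return PulsatileWaveform(
        phase=phase,
        waveform=np.median(arr, axis=0),
        iqr_low=np.percentile(arr, 25, axis=0),
        iqr_high=np.percentile(arr, 75, axis=0),
        n_beats=arr.shape[0],
    )


def pulsatility_index(waveform: np.ndarray | PulsatileWaveform) -> float:
    """PI = (max - min) / mean of a waveform; requires a positive mean."""
    w = waveform.waveform if isinstance(waveform, PulsatileWaveform) else np.asarray(waveform, dtype=float)
    if w.size == 0:
        raise InvalidParameterError("empty waveform")
    mean = float(w.mean())
    if mean <= 0:
        raise InvalidParameterError("waveform mean must be positive")
    return float((w.max() - w.min()) / mean)


def mad_outlier_mask(values: np.ndarray, n_mad: float = 3.0) -> np.ndarray:
    """Keep-mask by the median +/- n_mad * scaled-MAD rule."""
    v = np.asarray(values, dtype=float)
    med = np.median(v)
    mad = MAD_SCALE * np.median(np.abs(v - med))
    if mad == 0:
        # degenerate spread: anything off the median is an outlier
        return np.abs(v - med) <= 1e-9 * max(abs(med), 1e-300)
    return np.abs(v - med) <= n_mad * mad


def per_beat_pulsatility(
    series: FlowTimeSeries,
    peak_times: np.ndarray,
    n_phase: int = 64,
    n_mad: float = 3.0,
) -> tuple[float, np.ndarray]:
    """Mean PI over beats after scaled-MAD outlier removal.

    Each beat is resampled and mean-normalized as in
    :func:`average_waveform`; the per-beat PI list is filtered by the
    median +/- ``n_mad`` scaled-MAD rule before averaging. Returns
    ``(mean_pi, per_beat_pis_kept)``.
    """
    beats = _beat_slices(series.time, np.asarray(peak_times, dtype=float))
    if len(beats) < 3:
        raise InsufficientDataError("need at least 3 complete beats")
    phase = np.linspace(0.0, 1.0, n_phase)
    pis = []
    for idx in beats:
        t, v = series.time[idx], series.values[idx]
        if not np.all(np.isfinite(v)) or v.mean() <= 0:
            continue
        local = (t - t[0]) / (t[-1] - t[0])
        w = np.interp(phase, local, v)
        w = w / w.mean()
        pis.append(pulsatility_index(w))
    if len(pis) < 3:
        raise InsufficientDataError("fewer than 3 usable beats")
    pis = np.asarray(pis)
    kept = pis[mad_outlier_mask(pis, n_mad=n_mad)]
    return float(kept.mean()), kept


def block_average_downsample(
    series: FlowTimeSeries | np.ndarray, factor: int = 6
) -> FlowTimeSeries | np.ndarray:
    """Non-overlapping block means; the trailing partial block is dropped."""
    if factor < 1:
        raise InvalidParameterError("factor must be >= 1")
    if isinstance(series, FlowTimeSeries):
        n = series.values.size // factor
        if n < 1:
            raise InvalidParameterError("series shorter than one block")
        vals = series.values[: n * factor].reshape(n, factor).mean(axis=1)
        t = series.time[: n * factor].reshape(n, factor).mean(axis=1)
        return FlowTimeSeries(
            time=t, values=vals, modality=series.modality, relative=series.relative
        )
    x = np.asarray(series, dtype=float)
    n = x.size // factor
    if n < 1:
        raise InvalidParameterError("series shorter than one block")
    return x[: n * factor].reshape(n, factor).mean(axis=1)


def bland_altman_nonparametric(
    measured: np.ndarray, reference: np.ndarray
) -> BlandAltmanResult:
    """Nonparametric Bland-Altman agreement in percent of the reference.

    Differences d = 100 (m - r) / r; bias = median(d); limits of agreement
    are the 2.5th and 97.5th percentiles of d; the reproducibility
    coefficient is half the 95% inter-percentile range. Pairs with a zero
    reference are dropped and counted.
    """
    m = np.asarray(measured, dtype=float)
    r = np.asarray(reference, dtype=float)
    if m.shape != r.shape:
        raise InvalidParameterError("measured and reference must be paired")
    finite = np.isfinite(m) & np.isfinite(r)
    nonzero = finite & (r != 0)
    n_dropped = int(finite.sum() - nonzero.sum())
    m, r = m[nonzero], r[nonzero]
    if m.size < 10:
        raise InsufficientDataError("need at least 10 valid pairs")
    d = 100.0 * (m - r) / r
    lo, hi = np.percentile(d, [2.5, 97.5])
    return BlandAltmanResult(
        bias=float(np.median(d)),
        loa_low=float(lo),
        loa_high=float(hi),
        rpc=float((hi - lo) / 2.0),
        n=int(m.size),
        n_dropped=n_dropped,
    )


def paired_group_tests(values_by_modality: dict[str, np.ndarray]) -> dict:
    """Friedman + pairwise Wilcoxon + Pearson correlation over paired runs.

    ``values_by_modality`` maps each modality name to one value per run
    (same run order everywhere). Returns the Friedman p-value, pairwise
    Wilcoxon signed-rank p-values, the Pearson correlation matrix and
    pairwise linear-fit slopes/intercepts. Requires >= 3 paired runs.
    """
    names = list(values_by_modality)
    arrays = [np.asarray(values_by_modality[k], dtype=float) for k in names]
    n_runs = arrays[0].size
    if any(a.size != n_runs for a in arrays):
        raise InvalidParameterError("all modalities must supply one value per run")
    if n_runs < 3:
        raise InsufficientDataError("need >= 3 paired runs")
    keep = np.all(np.isfinite(arrays), axis=0)
    n_excluded = int(n_runs - keep.sum())
    arrays = [a[keep] for a in arrays]
    if arrays[0].size < 3:
        raise InsufficientDataError("fewer than 3 complete paired runs")

    if len(names) >= 3:
        _, friedman_p = stats.friedmanchisquare(*arrays)
        if not np.isfinite(friedman_p):
            friedman_p = 1.0  # fully tied ranks: no detectable effect
    else:
        friedman_p = float("nan")

    wilcoxon_p: dict[tuple[str, str], float] = {}
    pearson_r = np.eye(len(names))
    slopes: dict[tuple[str, str], tuple[float, float]] = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = arrays[i], arrays[j]
            if np.allclose(a, b):
                p = 1.0
            else:
                _, p = stats.wilcoxon(a, b)
            wilcoxon_p[(names[i], names[j])] = float(p)
            if np.std(a) > 0 and np.std(b) > 0:
                r, _ = stats.pearsonr(a, b)
            else:
                r = 1.0 if np.allclose(a, b) else float("nan")
            pearson_r[i, j] = pearson_r[j, i] = r
            fit = stats.linregress(b, a)
            slopes[(names[i], names[j])] = (float(fit.slope), float(fit.intercept))
    return {
        "modalities": names,
        "friedman_p": float(friedman_p),
        "wilcoxon_p": wilcoxon_p,
        "pearson_r": pearson_r,
        "linear_fits": slopes,
        "n_runs": int(arrays[0].size),
        "n_excluded": n_excluded,
    }
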