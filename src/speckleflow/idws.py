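"""Interferometric diffusing-wave spectroscopy processing chain.

The heterodyne line-scan record is reduced to a blood flow index by

1. a 0.1 s centered rolling-mean subtraction isolating the interference
   term delta_I(x, t),
2. a spatial Gaussian filter (peak value 1, sigma = 0.9669 px) across the
   pixel axis to combine neighboring pixels sampling the same speckle,
3. per-pixel, per-0.05 s-segment autocorrelation via the Wiener-Khinchin
   theorem (zero-padded FFT, so the estimator equals the direct lag sum),
4. pixel summation and subtraction of an identically processed
   reference-only record (sample arm blocked),
5. a two-parameter (A, BFi) least-squares fit of the *squared* corrected
   autocorrelation against (A g1(tau; BFi))^2, summed up to the first lag
   where the normalized measured correlation goes negative.

The unknown coupling prefactor (2 beta_iDWS <I_R> and any detector gain)
is absorbed into the amplitude A, so fits are invariant to overall scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve1d
from scipy.optimize import least_squares

from .exceptions import InvalidParameterError, NumericalError
from .forward import (
    CorrelationCurve,
    FlowParams,
    OpticalMedium,
    SemiInfiniteGeometry,
    _g1_values,
)
from .synthetic import LineScanRecord

LOG_BFI_BOUNDS = (-12.0, -4.0)

FIT_MODES = ("g1sq_all", "g1_all", "g1_over_1e")


@dataclass
class IdwsFitResult:
    """Result of one squared-G2 cost-function fit."""

    bfi: float
    amplitude: float
    fit_range_end: int
    residual: float
    converged: bool = True


def rolling_mean_subtract(
    record: LineScanRecord | np.ndarray,
    dt: float | None = None,
    window: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Subtract a centered rolling mean from each pixel's time trace.

    The window shrinks at the record edges; the first and last half-window
    of samples are flagged invalid in the returned time mask and should be
    excluded from downstream segments. Returns ``(delta_i, valid_time)``.
    """
    if isinstance(record, LineScanRecord):
        data = record.counts
        dt = record.dt
    else:
        data = np.asarray(record)
        if dt is None:
            raise InvalidParameterError("dt is required for array input")
    squeeze = data.ndim == 1
    data = np.atleast_2d(data)
    n = data.shape[-1]
    half = int(round(window / dt / 2.0))
    if 2 * half + 1 > n:
        raise InvalidParameterError("record shorter than the rolling-mean window")
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    counts = (hi - lo).astype(np.float64)
    out = np.empty(data.shape, dtype=np.float32)
    # chunk over pixels: the float64 cumulative sums of long records are large
    chunk = max(1, int(2e7) // n)
    for a in range(0, data.shape[0], chunk):
        d = data[a:a + chunk].astype(np.float64)
        csum = np.concatenate([np.zeros((d.shape[0], 1)), np.cumsum(d, axis=-1)], axis=-1)
        out[a:a + chunk] = d - (csum[:, hi] - csum[:, lo]) / counts
    valid = (idx >= half) & (idx < n - half)
    if squeeze:
        out = out[0]
    return out, valid


def spatial_filter(delta_i: np.ndarray, sigma: float = 0.9669) -> np.ndarray:
    """Convolve across the pixel axis with an unnormalized Gaussian kernel.

    The kernel has peak value 1 (it is *not* area-normalized, matching the
    coherent-summation convention), truncated at 4 sigma, with reflective
    edge handling. A single-pixel input is returned scaled by the kernel
    peak, i.e. unchanged.
    """
    delta_i = np.asarray(delta_i)
    if delta_i.dtype.kind != "f":
        delta_i = delta_i.astype(np.float64)
    if delta_i.ndim != 2:
        raise InvalidParameterError("expected a (n_pixels, n_time) array")
    if delta_i.shape[0] < 2 or sigma <= 0:
        return delta_i.copy()
    radius = max(1, int(math.ceil(4.0 * sigma)))
    x = np.arange(-radius, radius + 1, dtype=float)
    kernel = np.exp(-(x**2) / (2.0 * sigma**2)).astype(delta_i.dtype)
    # the kernel runs across pixels (axis 0): chunk over time to bound memory
    out = np.empty_like(delta_i)
    step = max(1, int(2e7) // max(1, delta_i.shape[0]))
    for t0 in range(0, delta_i.shape[1], step):
        sl = slice(t0, t0 + step)
        convolve1d(delta_i[:, sl], kernel, axis=0, mode="reflect", output=out[:, sl])
    return out


def gaussian_kernel_self_correlation(sigma: float, lags: np.ndarray) -> np.ndarray:
    """Normalized self-correlation of the spatial kernel (oracle helper)."""
    radius = max(1, int(math.ceil(4.0 * sigma)))
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-(x**2) / (2.0 * sigma**2))
    full = np.correlate(k, k, mode="full")
    center = full.size // 2
    return full[center + lags] / full[center]


def wk_autocorrelation(
    segment: np.ndarray,
    n_lags: int = 4000,
) -> tuple[np.ndarray, bool]:
    """Per-pixel autocorrelation lag sums via the Wiener-Khinchin theorem.

    ``segment`` is (n_pixels, n_samples). The transform is zero-padded to
    at least twice the segment length, so circular wrap-around is
    eliminated and G2(x, k) equals the direct sum over t of
    delta_I(x, t) delta_I(x, t + k) exactly (to float rounding). If the
    segment holds fewer samples than ``n_lags`` the output is truncated and
    flagged (second return value False).
    """
    segment = np.atleast_2d(np.asarray(segment, dtype=np.float64))
    n = segment.shape[-1]
    full_lags = n_lags <= n
    kept = min(n_lags, n)
    nfft = 1 << int(math.ceil(math.log2(2 * n)))
    spec = np.fft.rfft(segment, nfft, axis=-1)
    corr = np.fft.irfft(spec * np.conj(spec), nfft, axis=-1)[..., :kept]
    return corr, full_lags


def autocorrelation_direct(x: np.ndarray, n_lags: int) -> np.ndarray:
    """O(N L) direct lag-sum oracle: sum_t x[t] x[t+k]."""
    x = np.asarray(x, dtype=np.float64)
    return np.array([np.dot(x[: x.size - k], x[k:]) for k in range(min(n_lags, x.size))])


def sum_and_reference_correct(
    g2_pixels: np.ndarray | CorrelationCurve,
    reference_g2: np.ndarray | CorrelationCurve,
    dt: float = 3e-6,
) -> CorrelationCurve:
    """Pixel-summed sample G2 minus the pixel-summed reference G2.

    Both inputs must be on the same lag grid (same segment length and
    native spacing); per-pixel arrays are summed over the pixel axis first.
    """

    def reduce(obj):
        if isinstance(obj, CorrelationCurve):
            return obj.values, obj.tau
        arr = np.asarray(obj, dtype=np.float64)
        vals = arr.sum(axis=0) if arr.ndim == 2 else arr
        return vals, np.arange(vals.size) * dt

    meas, tau_m = reduce(g2_pixels)
    ref, tau_r = reduce(reference_g2)
    if meas.shape != ref.shape or not np.allclose(tau_m, tau_r):
        raise InvalidParameterError("measurement and reference lag grids differ")
    return CorrelationCurve(tau=tau_m, values=meas - ref, kind="G2_idws")


def _first_negative_index(normalized: np.ndarray, start: int) -> int:
    neg = np.nonzero(normalized[start:] < 0)[0]
    return int(start + neg[0]) if neg.size else normalized.size


def fit_g2sq_bfi(
    corrected: CorrelationCurve,
    medium: OpticalMedium,
    geometry: SemiInfiniteGeometry,
    fit_mode: str = "g1sq_all",
    first_lag: int = 1,
) -> IdwsFitResult:
    """Two-parameter (A, BFi) fit of the corrected interferometric G2.

    The fit range runs from ``first_lag`` (default 1: the zero-lag point
    carries the shot/read-noise variance spike) up to the first lag at
    which the measured correlation, normalized by its value at
    ``first_lag``, goes negative — the theoretical semi-infinite g1 is
    strictly positive, so the range rule necessarily refers to the measured
    curve. ``fit_mode``:

    * ``g1sq_all``  — minimize sum (G2^2 - (A g1)^2)^2 over that range
      (the squared-correlation cost; default),
    * ``g1_all``    — minimize sum (G2 - A g1)^2 over the same range,
    * ``g1_over_1e``— like ``g1_all`` but keeping only lags where the
      normalized correlation exceeds 1/e.
    """
    if fit_mode not in FIT_MODES:
        raise InvalidParameterError(f"fit_mode must be one of {FIT_MODES}")
    values = corrected.values
    if values.size <= first_lag or values[first_lag] <= 0:
        raise NumericalError("corrected G2 has no positive initial lag")
    normalized = values / values[first_lag]
    end = _first_negative_index(normalized, first_lag)
    if end - first_lag < 2:
        raise NumericalError("fewer than two positive lags: cannot fit")
    sel = slice(first_lag, end)
    tau, meas, norm = corrected.tau[sel], values[sel], normalized[sel]
    if fit_mode == "g1_over_1e":
        keep = norm >= 1.0 / math.e
        if keep.sum() < 2:
            raise NumericalError("fewer than two lags above 1/e: cannot fit")
        tau, meas = tau[keep], meas[keep]

    def model_g1(log_bfi):
        return _g1_values(medium, geometry, FlowParams.from_bfi(10.0 ** log_bfi), tau)

    squared = fit_mode == "g1sq_all"

    def residuals(p):
        amp, log_bfi = p
        g1 = model_g1(log_bfi)
        if squared:
            return meas**2 - (amp * g1) ** 2
        return meas - amp * g1

    a0 = float(meas[0])
    grid = np.linspace(*LOG_BFI_BOUNDS, 48)
    costs = [np.sum(residuals([a0, lb]) ** 2) for lb in grid]
    lb0 = float(grid[int(np.argmin(costs))])
    sol = least_squares(
        residuals,
        x0=[a0, lb0],
        bounds=([0.0, LOG_BFI_BOUNDS[0]], [np.inf, LOG_BFI_BOUNDS[1]]),
    )
    if not sol.success:
        raise NumericalError(f"iDWS fit did not converge: {sol.message}")
    return IdwsFitResult(
        bfi=10.0 ** float(sol.x[1]),
        amplitude=float(sol.x[0]),
        fit_range_end=end,
        residual=float(np.sum(sol.fun**2)),
        converged=bool(sol.success),
    )


def segment_g2(
    record: LineScanRecord,
    segment_s: float = 0.05,
    n_lags: int = 4000,
    spatial_sigma: float = 0.9669,
    rolling_window: float = 0.1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pixel-summed G2 per non-overlapping 0.05 s segment.

    Returns ``(t_segments, g2_sums, tau)`` with ``g2_sums`` of shape
    (n_segments, n_lags). Segments overlapping the invalid rolling-mean
    edges are dropped.
    """
    delta, valid_t = rolling_mean_subtract(record, window=rolling_window)
    delta = spatial_filter(delta, sigma=spatial_sigma)
    seg_len = int(round(segment_s / record.dt))
    if seg_len < 2:
        raise InvalidParameterError("segment shorter than two samples")
    n_seg = delta.shape[-1] // seg_len
    out, times = [], []
    for s in range(n_seg):
        sl = slice(s * seg_len, (s + 1) * seg_len)
        if not valid_t[sl].all():
            continue
        corr, _ = wk_autocorrelation(delta[:, sl], n_lags=n_lags)
        out.append(corr.sum(axis=0))
        times.append(s * segment_s)
    if not out:
        raise InvalidParameterError("no complete segments inside the valid region")
    kept = min(n_lags, seg_len)
    tau = np.arange(kept) * record.dt
    return np.asarray(times), np.asarray(out), tau


def process_idws(
    record: LineScanRecord,
    reference: LineScanRecord,
    medium: OpticalMedium,
    geometry: SemiInfiniteGeometry,
    fit_mode: str = "g1sq_all",
    segment_s: float = 0.05,
    n_lags: int = 4000,
    full: bool = False,
):
    """Full iDWS chain at 20 Hz: returns ``(t, bfi, amplitude, valid)``.

    The reference record (sample arm blocked) is processed identically;
    its segment-averaged pixel-summed G2 is subtracted from every sample
    segment before fitting. With ``full=True`` a DataFrame with the
    documented columns (time_s, bfi_cm2s, amplitude, fit_range_end,
    residual, valid_flag) is returned instead.
    """
    t, g2_segments, tau = segment_g2(record, segment_s=segment_s, n_lags=n_lags)
    _, ref_segments, tau_ref = segment_g2(reference, segment_s=segment_s, n_lags=n_lags)
    if tau_ref.shape != tau.shape or not np.allclose(tau_ref, tau):
        raise InvalidParameterError("reference was not processed on the same lag grid")
    ref_mean = ref_segments.mean(axis=0)
    bfi = np.full(t.size, np.nan)
    amp = np.full(t.size, np.nan)
    range_end = np.zeros(t.size, dtype=int)
    residual = np.full(t.size, np.nan)
    ok = np.zeros(t.size, dtype=bool)
    for i in range(t.size):
        corrected = CorrelationCurve(tau=tau, values=g2_segments[i] - ref_mean, kind="G2_idws")
        try:
            res = fit_g2sq_bfi(corrected, medium, geometry, fit_mode=fit_mode)
        except NumericalError:
            continue
        bfi[i], amp[i], ok[i] = res.bfi, res.amplitude, res.converged
        range_end[i], residual[i] = res.fit_range_end, res.residual
    if full:
        import pandas as pd

        return pd.DataFrame({
            "time_s": t, "bfi_cm2s": bfi, "amplitude": amp,
            "fit_range_end": range_end, "residual": residual,
            "valid_flag": ok.astype(int),
        })
    return t, bfi, amp, ok
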