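"""Software intensity autocorrelator and semi-infinite CDE fit (DCS).

The correlator evaluates g2(tau) = <I(t) I(t+tau)> / <I>^2 per 0.05 s
integration window and per photon-counting channel on a quasi-logarithmic
("multi-tau style") lag grid. Every lag is estimated by a direct lag
product at the native bin width (computed with one FFT per window), so the
estimate at any lag equals the naive direct-sum estimator exactly up to
floating-point rounding — there is no cascaded rebinning.

Fitting recovers the blood flow index BFi = alpha*Db by nonlinear least
squares of the measured g2 against 1 + beta |g1(tau; BFi)|^2 with the
semi-infinite CDE g1. The coherence parameter beta is calibrated once per
session from the time-averaged curve and then frozen (a per-window joint
(beta, BFi) fit is available as an option).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .exceptions import CalibrationError, InvalidParameterError, NumericalError
from .forward import (
    CorrelationCurve,
    FlowParams,
    OpticalMedium,
    SemiInfiniteGeometry,
    _g1_values,
)
from .synthetic import PhotonCountSeries

#: log10(BFi) fit bounds, cm^2/s
LOG_BFI_BOUNDS = (-12.0, -4.0)


@dataclass
class DcsFitResult:
    """Result of one g2-to-BFi fit."""

    bfi: float
    beta: float
    residual: float
    window_index: int = 0
    converged: bool = True
    at_bound: bool = False


def multitau_lag_bins(n_bins: int, lags_per_octave: int = 16, max_lag: int | None = None) -> np.ndarray:
    """Quasi-logarithmic integer lag grid: dense first octave, then doubling steps.

    The first ``lags_per_octave`` lags are consecutive multiples of the bin
    width; each subsequent octave keeps ``lags_per_octave // 2`` lags with a
    doubled step.
    """
    if max_lag is None:
        max_lag = n_bins // 4
    lags = list(range(1, lags_per_octave + 1))
    step = 2
    current = lags[-1]
    while current + step <= max_lag:
        for _ in range(lags_per_octave // 2):
            current += step
            if current > max_lag:
                break
            lags.append(current)
        step *= 2
    return np.asarray(lags, dtype=int)


def autocorrelate_direct(x: np.ndarray, lags: np.ndarray) -> np.ndarray:
    """Direct lag-sum estimator: mean of x[t] x[t+k] over valid pairs."""
    x = np.asarray(x, dtype=float)
    return np.array([np.dot(x[: x.size - k], x[k:]) / (x.size - k) for k in lags])


def _lag_products_fft(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Sum_t x[t] x[t+k] for k = 0..max_lag via zero-padded FFT."""
    n = x.size
    nfft = 1 << int(math.ceil(math.log2(2 * n)))
    spec = np.fft.rfft(x, nfft)
    corr = np.fft.irfft(spec * np.conj(spec), nfft)[: max_lag + 1]
    return corr


def g2_estimate(x: np.ndarray, lags: np.ndarray, dt: float) -> CorrelationCurve:
    """Normalized intensity autocorrelation of one count series.

    g2(k dt) = [sum_t x_t x_{t+k} / (N - k)] / mean(x)^2, evaluated for all
    requested integer lags with a single FFT.
    """
    x = np.asarray(x, dtype=float)
    mean = x.mean()
    if mean <= 0:
        raise InvalidParameterError("count series has no counts")
    sums = _lag_products_fft(x, int(lags.max()))
    g2 = sums[lags] / (x.size - lags) / mean**2
    return CorrelationCurve(tau=lags * dt, values=g2, kind="g2")


@dataclass
class G2Windows:
    """Per-window, per-channel g2 estimates on a shared lag grid."""

    tau: np.ndarray
    g2: np.ndarray      # (n_windows, n_channels, n_lags)
    valid: np.ndarray   # (n_windows, n_channels) bool
    t: np.ndarray       # window start times, s

    @property
    def n_windows(self) -> int:
        return self.g2.shape[0]

    def window_curves(self, w: int) -> list[CorrelationCurve | None]:
        return [
            CorrelationCurve(tau=self.tau, values=self.g2[w, c], kind="g2")
            if self.valid[w, c]
            else None
            for c in range(self.g2.shape[1])
        ]


def software_autocorrelator(
    counts: PhotonCountSeries,
    integration: float = 0.05,
    lags: np.ndarray | None = None,
    lags_per_octave: int = 16,
) -> G2Windows:
    """Windowed multi-lag g2 estimates at 1/integration output rate.

    Windows whose total count is zero are flagged invalid and never fitted.
    """
    window_bins = int(round(integration / counts.dt))
    if window_bins < 100:
        raise InvalidParameterError("integration window must span at least 100 bins")
    n_windows = counts.n_bins // window_bins
    if n_windows < 1:
        raise InvalidParameterError("record shorter than one integration window")
    if lags is None:
        lags = multitau_lag_bins(window_bins, lags_per_octave)
    lags = np.asarray(lags, dtype=int)
    n_ch = counts.n_channels
    g2 = np.full((n_windows, n_ch, lags.size), np.nan)
    valid = np.zeros((n_windows, n_ch), dtype=bool)
    for w in range(n_windows):
        sl = slice(w * window_bins, (w + 1) * window_bins)
        for c in range(n_ch):
            x = counts.counts[c, sl].astype(float)
            if x.sum() <= 0:
                continue
            sums = _lag_products_fft(x, int(lags.max()))
            g2[w, c] = sums[lags] / (window_bins - lags) / x.mean() ** 2
            valid[w, c] = True
    t = np.arange(n_windows) * integration
    return G2Windows(tau=lags * counts.dt, g2=g2, valid=valid, t=t)


def average_channels(curves: list[CorrelationCurve | None]) -> tuple[CorrelationCurve, int]:
    """Unweighted pointwise mean of the valid per-channel g2 curves.

    Returns the averaged curve and the number of channels used; raises if
    all channels are invalid.
    """
    valid = [c for c in curves if c is not None]
    if not valid:
        raise InvalidParameterError("all channels invalid in this window")
    tau = valid[0].tau
    for c in valid[1:]:
        if c.tau.shape != tau.shape or not np.allclose(c.tau, tau):
            raise InvalidParameterError("channel curves must share the lag grid")
    mean = np.mean([c.values for c in valid], axis=0)
    return CorrelationCurve(tau=tau, values=mean, kind="g2"), len(valid)


def average_windows(windows: G2Windows, window_slice: slice | None = None) -> CorrelationCurve:
    """Mean g2 across channels and a range of windows (default: all)."""
    sl = window_slice if window_slice is not None else slice(None)
    g2 = windows.g2[sl]
    ok = windows.valid[sl]
    if not ok.any():
        raise InvalidParameterError("no valid windows to average")
    mean = np.nanmean(np.where(ok[..., None], g2, np.nan), axis=(0, 1))
    return CorrelationCurve(tau=windows.tau, values=mean, kind="g2")


def _fit_lag_mask(values: np.ndarray) -> np.ndarray:
    """Lags kept for fitting: contrast above 3x the late-lag noise floor.

    The noise floor is the standard deviation of (g2 - 1) over the last
    quarter of the lag grid; for noise-free curves (floor 0) all lags are
    kept.
    """
    contrast = values - 1.0
    tail = contrast[-max(2, values.size // 4):]
    floor = float(np.std(tail))
    if floor == 0.0:
        return np.ones(values.size, dtype=bool)
    above = contrast > 3.0 * floor
    if not above.any():
        return np.ones(values.size, dtype=bool)
    last = int(np.max(np.nonzero(above)[0]))
    mask = np.zeros(values.size, dtype=bool)
    mask[: last + 1] = True
    return mask


def _g2_model(tau: np.ndarray, log_bfi: float, beta: float,
              medium: OpticalMedium, geometry: SemiInfiniteGeometry) -> np.ndarray:
    flow = FlowParams.from_bfi(10.0 ** log_bfi)
    return 1.0 + beta * _g1_values(medium, geometry, flow, tau) ** 2


def _grid_scan_log_bfi(tau, values, beta, medium, geometry, n=48) -> float:
    grid = np.linspace(*LOG_BFI_BOUNDS, n)
    costs = [
        np.sum((values - _g2_model(tau, lb, beta, medium, geometry)) ** 2) for lb in grid
    ]
    return float(grid[int(np.argmin(costs))])


def calibrate_beta(
    curve_or_windows: CorrelationCurve | G2Windows,
    medium: OpticalMedium,
    geometry: SemiInfiniteGeometry,
    calibration_span: float = 60.0,
) -> float:
    """Joint (beta, BFi) fit of the session-averaged g2; returns beta.

    For a :class:`G2Windows` input the curves from the first
    ``calibration_span`` seconds are averaged first. A flat curve (no decay
    above the noise floor) raises :class:`CalibrationError`.
    """
    if isinstance(curve_or_windows, G2Windows):
        n = max(1, int(np.searchsorted(curve_or_windows.t, calibration_span)))
        curve = average_windows(curve_or_windows, slice(0, n))
    else:
        curve = curve_or_windows
    contrast = curve.values - 1.0
    tail_std = float(np.std(contrast[-max(2, contrast.size // 4):]))
    if contrast[: max(1, contrast.size // 8)].mean() <= 3.0 * tail_std and tail_std == 0.0:
        raise CalibrationError("g2 curve shows no decay: cannot calibrate beta")
    if contrast.max() <= max(3.0 * tail_std, 1e-12):
        raise CalibrationError("g2 curve shows no decay above the noise floor")
    mask = _fit_lag_mask(curve.values)
    tau, values = curve.tau[mask], curve.values[mask]
    beta0 = float(np.clip(contrast[mask][0], 1e-3, 1.0))
    lb0 = _grid_scan_log_bfi(tau, values, beta0, medium, geometry)

    def residuals(p):
        lb, beta = p
        return values - _g2_model(tau, lb, beta, medium, geometry)

    sol = least_squares(
        residuals,
        x0=[lb0, beta0],
        bounds=([LOG_BFI_BOUNDS[0], 1e-4], [LOG_BFI_BOUNDS[1], 1.0]),
    )
    if not sol.success:
        raise CalibrationError(f"beta calibration did not converge: {sol.message}")
    return float(sol.x[1])


def fit_g2_bfi(
    g2: CorrelationCurve,
    medium: OpticalMedium,
    geometry: SemiInfiniteGeometry,
    beta: float | None = None,
    joint_beta: bool = False,
    window_index: int = 0,
) -> DcsFitResult:
    """Nonlinear least-squares fit of one g2 curve for BFi.

    With ``joint_beta=False`` (the default) the calibrated ``beta`` is
    frozen and BFi is the single free parameter; ``joint_beta=True`` fits
    (beta, BFi) jointly per window. BFi is bounded in [1e-12, 1e-4] cm^2/s
    and initialized from a coarse log-grid scan.
    """
    if not joint_beta and (beta is None or not 0.0 < beta <= 1.0):
        raise InvalidParameterError("a calibrated beta in (0, 1] is required")
    mask = _fit_lag_mask(g2.values)
    tau, values = g2.tau[mask], g2.values[mask]
    beta0 = beta if beta is not None else float(np.clip(values[0] - 1.0, 1e-3, 1.0))
    lb0 = _grid_scan_log_bfi(tau, values, beta0, medium, geometry)
    if joint_beta:
        def residuals(p):
            return values - _g2_model(tau, p[0], p[1], medium, geometry)
        x0, lo, hi = [lb0, beta0], [LOG_BFI_BOUNDS[0], 1e-4], [LOG_BFI_BOUNDS[1], 1.0]
    else:
        def residuals(p):
            return values - _g2_model(tau, p[0], beta0, medium, geometry)
        x0, lo, hi = [lb0], [LOG_BFI_BOUNDS[0]], [LOG_BFI_BOUNDS[1]]
    sol = least_squares(residuals, x0=x0, bounds=(lo, hi))
    if not sol.success:
        raise NumericalError(f"BFi fit did not converge: {sol.message}")
    log_bfi = float(sol.x[0])
    at_bound = bool(
        np.isclose(log_bfi, LOG_BFI_BOUNDS[0]) or np.isclose(log_bfi, LOG_BFI_BOUNDS[1])
    )
    return DcsFitResult(
        bfi=10.0 ** log_bfi,
        beta=float(sol.x[1]) if joint_beta else float(beta0),
        residual=float(np.sum(sol.fun**2)),
        window_index=window_index,
        converged=bool(sol.success),
        at_bound=at_bound,
    )


def process_dcs(
    counts: PhotonCountSeries,
    medium: OpticalMedium,
    geometry: SemiInfiniteGeometry,
    integration: float = 0.05,
    beta: float | None = None,
    calibration_span: float = 60.0,
    joint_beta: bool = False,
    full: bool = False,
) -> tuple:
    """Full DCS chain: correlate, average channels, calibrate beta, fit.

    Returns ``(t, bfi, valid, beta)`` with one fit per integration window;
    with ``full=True`` the first element is instead a DataFrame holding the
    documented output table (time_s, bfi_cm2s, beta, residual, valid_flag).
    """
    windows = software_autocorrelator(counts, integration=integration)
    if beta is None and not joint_beta:
        beta = calibrate_beta(windows, medium, geometry, calibration_span)
    bfi = np.full(windows.n_windows, np.nan)
    residual = np.full(windows.n_windows, np.nan)
    ok = np.zeros(windows.n_windows, dtype=bool)
    for w in range(windows.n_windows):
        if not windows.valid[w].any():
            continue
        curve, _ = average_channels(windows.window_curves(w))
        try:
            res = fit_g2_bfi(
                curve, medium, geometry, beta=beta, joint_beta=joint_beta, window_index=w
            )
        except NumericalError:
            continue
        bfi[w] = res.bfi
        residual[w] = res.residual
        ok[w] = res.converged and not res.at_bound
    beta_out = float(beta) if beta is not None else float("nan")
    if full:
        import pandas as pd

        table = pd.DataFrame({
            "time_s": windows.t, "bfi_cm2s": bfi,
            "beta": np.full(windows.n_windows, beta_out),
            "residual": residual, "valid_flag": ok.astype(int),
        })
        return table, beta_out
    return windows.t, bfi, ok, beta_out
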