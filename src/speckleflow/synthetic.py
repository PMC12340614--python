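"""Seeded detector-level speckle simulators.

Each generator produces the raw record of one acquisition modality from a
prescribed field autocorrelation g1(tau):

* :func:`sample_correlated_field` — stationary circular complex Gaussian
  speckle amplitudes whose temporal autocovariance follows a target g1
  (spectral synthesis: filter white complex noise with the square root of
  the discrete spectrum of the symmetrized covariance).
* :func:`simulate_dcs_counts` — Poisson photodetection of single-speckle
  intensities, one speckle per photon-counting channel.
* :func:`simulate_idws_record` — heterodyne line-scan interferograms: a
  strong constant reference plus the interference beat 2 sqrt(IR) Re(E_S),
  with shot noise, read noise and integer quantization.
* :func:`simulate_scos_frames` — exposure-integrated speckle frames with a
  configured speckle-to-pixel size ratio, camera gain, read noise, dark
  offset and quantization.
* :func:`make_flow_program` — ground-truth BFi(t) programs: the forearm
  cuff-occlusion protocol with cardiac pulsatility, and the temperature-
  ramped Brownian microsphere phantom.

Statistics are imposed, not emergent: there is no physical optics
propagation here. All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import fft
from scipy.fft import next_fast_len
from scipy.linalg import eigh, toeplitz
from scipy.ndimage import gaussian_filter1d

from .exceptions import InvalidParameterError
from .forward import (
    CorrelationCurve,
    FlowParams,
    OpticalMedium,
    SemiInfiniteGeometry,
    _g1_values,
    stokes_einstein_db,
)

#: default line-scan sample interval, s
IDWS_DT = 3e-6

#: default microsphere radius (195 nm diameter spheres), m
PHANTOM_SPHERE_RADIUS_M = 97.5e-9


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SpeckleFieldSeries:
    """Complex speckle amplitudes, one row per independent speckle."""

    field: np.ndarray  # (n_speckles, n_time) complex
    dt: float
    target_g1: CorrelationCurve | None = None

    @property
    def n_speckles(self) -> int:
        return self.field.shape[0]

    @property
    def n_time(self) -> int:
        return self.field.shape[1]

    def intensity(self) -> np.ndarray:
        return np.abs(self.field) ** 2


@dataclass
class PhotonCountSeries:
    """Per-channel photon counts in uniform time bins."""

    counts: np.ndarray  # (n_channels, n_bins) integer
    dt: float

    @property
    def n_channels(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    @property
    def duration(self) -> float:
        return self.n_bins * self.dt


@dataclass
class LineScanRecord:
    """Simulated line-scan camera record (pixels x time, integer counts)."""

    counts: np.ndarray  # (n_pixels, n_time)
    dt: float
    reference_level: float
    spatial_hwhm: float

    @property
    def n_pixels(self) -> int:
        return self.counts.shape[0]

    @property
    def n_time(self) -> int:
        return self.counts.shape[1]

    @property
    def duration(self) -> float:
        return self.n_time * self.dt


@dataclass
class FrameStack:
    """Simulated CMOS speckle frames (n_frames x H x W, integer counts)."""

    frames: np.ndarray
    t_exp: float
    frame_rate: float
    gain: float
    read_sigma: float
    dark_offset: float
    speckle_pixel_ratio: float

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate


@dataclass
class FlowProgram:
    """Ground-truth BFi(t) with segment labels."""

    time: np.ndarray
    bfi: np.ndarray
    segment: np.ndarray  # array of {baseline, occlusion, recovery, ramp}
    cardiac_freq: float | None = None
    pi: float | None = None
    temperature_k: np.ndarray | None = None

    @property
    def fs(self) -> float:
        return 1.0 / float(self.time[1] - self.time[0])

    def segment_mask(self, label: str) -> np.ndarray:
        return self.segment == label

    def bfi_at(self, t: np.ndarray | float) -> np.ndarray | float:
        return np.interp(t, self.time, self.bfi)


# ---------------------------------------------------------------------------
# correlated complex Gaussian fields
# ---------------------------------------------------------------------------

def sample_correlated_field(
    target_g1: CorrelationCurve,
    n_time: int,
    dt: float,
    n_speckles: int,
    seed: int | np.random.Generator,
    dtype: np.dtype = np.complex64,
) -> SpeckleFieldSeries:
    """Stationary circular complex Gaussian speckles with a target g1.

    The symmetrized covariance sequence is embedded in a circulant of length
    2*n_time; its discrete spectrum (clipped at zero where the embedding is
    not nonnegative definite) filters white complex Gaussian noise. Clipped
    spectral mass above 5% of the total raises a warning, above 20% an
    error (the target is not realizable on this grid).
    """
    if n_time < 2 or n_speckles < 1:
        raise InvalidParameterError("need n_time >= 2 and n_speckles >= 1")
    if target_g1.tau[-1] < (n_time - 1) * dt:
        raise InvalidParameterError(
            "target_g1 grid must cover delays up to (n_time - 1) * dt"
        )
    if np.any(np.abs(target_g1.values) > 1.0 + 1e-9):
        raise InvalidParameterError("target g1 must be bounded by 1 in magnitude")
    # circulant embedding padded to a fast FFT length; beyond the target grid
    # the covariance is extended with its final value (typically ~0)
    m = next_fast_len(2 * n_time)
    half = m // 2
    lags = np.arange(half + 1) * dt
    cov = np.interp(lags, target_g1.tau, target_g1.values,
                    right=float(target_g1.values[-1]))
    idx = np.minimum(np.arange(m), m - np.arange(m))
    circ = cov[idx]
    spectrum = fft.fft(circ).real
    clipped = -spectrum[spectrum < 0].sum()
    total = np.abs(spectrum).sum()
    frac = clipped / total if total > 0 else 0.0
    if frac > 0.20:
        raise InvalidParameterError(
            f"clipped spectral mass {frac:.1%} > 20%: target g1 not realizable"
        )
    if frac > 0.05:
        warnings.warn(f"clipped spectral mass {frac:.1%} of total", stacklevel=2)
    spectrum = np.clip(spectrum, 0.0, None)
    # renormalize to unit variance after clipping (variance = mean of spectrum)
    spectrum *= m / spectrum.sum()
    amplitude = np.sqrt(spectrum * m).astype(np.float32)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = np.empty((n_speckles, n_time), dtype=dtype)
    chunk = max(1, int(2e7) // m)  # bound transient memory
    scale = np.float32(math.sqrt(0.5))
    for lo in range(0, n_speckles, chunk):
        hi = min(lo + chunk, n_speckles)
        white = np.empty((hi - lo, m), dtype=np.complex64)
        white.real = rng.standard_normal((hi - lo, m), dtype=np.float32)
        white.imag = rng.standard_normal((hi - lo, m), dtype=np.float32)
        white *= scale * amplitude
        series = fft.ifft(white, axis=1, overwrite_x=True)[:, :n_time]
        out[lo:hi] = series.astype(dtype)
    return SpeckleFieldSeries(field=out, dt=dt, target_g1=target_g1)


def _log_tau_grid(tau_max: float, n: int) -> np.ndarray:
    """Delay grid dense near zero: 0 plus log-spaced nodes up to tau_max."""
    return np.concatenate([[0.0], np.logspace(math.log10(tau_max * 1e-8), math.log10(tau_max), n - 1)])


def exponential_g1(tau_c: float, tau_max: float, n: int = 4096) -> CorrelationCurve:
    """Convenience single-exponential target curve exp(-tau/tau_c)."""
    tau = _log_tau_grid(tau_max, n)
    return CorrelationCurve(tau=tau, values=np.exp(-tau / tau_c), kind="g1")


def cde_target_g1(
    medium: OpticalMedium,
    geometry: SemiInfiniteGeometry,
    flow: FlowParams,
    tau_max: float,
    n: int = 4096,
) -> CorrelationCurve:
    """Semi-infinite CDE g1 sampled densely near zero for field synthesis."""
    tau = _log_tau_grid(tau_max, n)
    return CorrelationCurve(tau=tau, values=_g1_values(medium, geometry, flow, tau), kind="g1")


# ---------------------------------------------------------------------------
# DCS: Poisson photodetection
# ---------------------------------------------------------------------------

def simulate_dcs_counts(
    field: SpeckleFieldSeries,
    mean_rate: float,
    seed: int | np.random.Generator,
) -> PhotonCountSeries:
    """Poisson photon counts per channel, one field speckle per channel.

    counts[k] ~ Poisson(mean_rate * dt * I(t_k) / <I>) independently per
    channel given the field. A mean count above 1e3 per bin triggers a
    warning (outside the single-photon-detector regime).
    """
    if mean_rate <= 0:
        raise InvalidParameterError("mean_rate must be positive")
    if mean_rate * field.dt > 1e3:
        warnings.warn("mean_rate * dt > 1e3 counts/bin: SPAD regime violated", stacklevel=2)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    intensity = field.intensity().astype(np.float64)
    mean_i = intensity.mean(axis=1, keepdims=True)
    mean_i[mean_i == 0] = 1.0
    lam = mean_rate * field.dt * intensity / mean_i
    counts = rng.poisson(lam).astype(np.int32)
    return PhotonCountSeries(counts=counts, dt=field.dt)


# ---------------------------------------------------------------------------
# iDWS: heterodyne line-scan interferograms
# ---------------------------------------------------------------------------

def _blur_complex_rows(field: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian-blur a complex field across axis 0, restoring unit variance."""
    if sigma <= 0 or field.shape[0] < 2:
        return field
    blurred = (
        gaussian_filter1d(field.real, sigma, axis=0, mode="wrap")
        + 1j * gaussian_filter1d(field.imag, sigma, axis=0, mode="wrap")
    )
    rms = np.sqrt(np.mean(np.abs(blurred) ** 2))
    return blurred / rms if rms > 0 else blurred


def hwhm_to_field_sigma(hwhm: float) -> float:
    """Kernel sigma giving a fluctuation autocorrelation of the stated HWHM.

    White complex noise blurred with a Gaussian kernel of s.d. sigma_k has a
    field autocorrelation exp(-dx^2 / (4 sigma_k^2)), whose half width at
    half maximum is 2 sigma_k sqrt(ln 2).
    """
    return hwhm / (2.0 * math.sqrt(math.log(2.0)))


def simulate_idws_record(
    fields: SpeckleFieldSeries,
    reference_level: float = 100.0,
    sample_level: float = 2.0,
    spatial_hwhm: float = 1.5,
    read_sigma: float = 1.0,
    seed: int | np.random.Generator = 0,
    bit_depth: int = 8,
    shot_noise: bool = True,
) -> LineScanRecord:
    """Heterodyne interferogram: reference + 2 sqrt(IR) Re(E_S) + noise.

    ``fields`` supplies one pre-blur speckle per camera pixel; pixels are
    then correlated by a Gaussian blur of the complex field so the spatial
    autocorrelation of the fluctuation has the configured half width
    (default 1.5 px). Counts are integer-quantized and clipped to the given
    bit depth.
    """
    if reference_level <= 0 or sample_level < 0:
        raise InvalidParameterError("reference_level must be positive")
    if reference_level < 10.0 * sample_level:
        warnings.warn(
            "reference_level below 10x sample intensity: heterodyne "
            "approximation degraded",
            stacklevel=2,
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    e_s = _blur_complex_rows(fields.field.astype(np.complex64), hwhm_to_field_sigma(spatial_hwhm))
    signal = reference_level + 2.0 * math.sqrt(reference_level * sample_level) * e_s.real
    np.clip(signal, 0.0, None, out=signal)
    if shot_noise:
        counts = rng.poisson(signal.astype(np.float64)).astype(np.float32)
    else:
        counts = signal.astype(np.float32)
    if read_sigma > 0:
        counts += rng.normal(0.0, read_sigma, size=counts.shape).astype(np.float32)
    counts = np.clip(np.floor(counts + 0.5), 0, 2**bit_depth - 1).astype(np.uint16)
    return LineScanRecord(
        counts=counts,
        dt=fields.dt,
        reference_level=reference_level,
        spatial_hwhm=spatial_hwhm,
    )


# ---------------------------------------------------------------------------
# SCOS: exposure-integrated speckle frames
# ---------------------------------------------------------------------------

@lru_cache(maxsize=64)
def _temporal_modes(
    medium_key: tuple,
    geometry_key: tuple,
    bfi: float,
    t_exp: float,
    substeps: int,
    keep_fraction: float = 0.95,
) -> np.ndarray:
    """Eigen-decomposition of the within-exposure field covariance.

    The exposure integral of the intensity is represented by ``substeps``
    point samples of the field; the Toeplitz covariance C[m,m'] =
    g1(|m-m'| T/M) is diagonalized once and the integrated intensity
    becomes a weighted sum of squared moduli of independent complex
    Gaussian modes. The leading eigenvalues covering ``keep_fraction`` of
    the mass are kept as stochastic modes; the long tail of tiny
    eigenvalues (whose fluctuations are negligible) enters as a
    deterministic pedestal, and the kept weights are rescaled so the mean
    *and* variance of the integrated intensity — hence the theoretical
    speckle contrast — are preserved exactly. Returns ``(weights,
    pedestal)``.
    """
    medium = OpticalMedium(*medium_key)
    geometry = SemiInfiniteGeometry(*geometry_key)
    flow = FlowParams.from_bfi(bfi)
    delta = t_exp / substeps
    lags = np.arange(substeps) * delta
    cov = _g1_values(medium, geometry, flow, lags)
    evals = eigh(toeplitz(cov), eigvals_only=True)[::-1]
    evals = np.clip(evals, 0.0, None)
    weights = evals / substeps  # sums to ~1
    total_sq = float((weights**2).sum())
    csum = np.cumsum(weights)
    n_keep = min(int(np.searchsorted(csum, keep_fraction) + 1), weights.size)
    kept = weights[:n_keep]
    # scale kept modes to carry the full variance; the rest is a constant
    scale = math.sqrt(total_sq / float((kept**2).sum()))
    kept = kept * scale
    pedestal = float(max(0.0, 1.0 - kept.sum()))
    return np.ascontiguousarray(kept), pedestal


def speckle_ratio_to_sigma(speckle_pixel_ratio: float) -> float:
    """Gaussian blur sigma for a given speckle-to-pixel size ratio.

    The speckle size is taken as the FWHM of the spatial intensity
    autocovariance; blurring white complex noise with a kernel of s.d.
    sigma gives an intensity autocovariance exp(-dx^2/(2 sigma^2)) with
    FWHM = 2 sqrt(2 ln 2) sigma.
    """
    return speckle_pixel_ratio / (2.0 * math.sqrt(2.0 * math.log(2.0)))


def _spatial_transfer(shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Unit-variance-preserving Gaussian transfer function on the FFT grid."""
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    g = np.exp(-2.0 * math.pi**2 * sigma**2 * (fy**2 + fx**2))
    g /= math.sqrt(np.mean(g**2))
    return g


def _speckle_exposure_image(
    rng: np.random.Generator,
    shape: tuple[int, int],
    weights: np.ndarray,
    transfer: np.ndarray | None,
    pedestal: float = 0.0,
) -> np.ndarray:
    """Mean-1 exposure-integrated intensity image from temporal eigenmodes."""
    n_modes = weights.size
    z = np.empty((n_modes, *shape), dtype=np.complex64)
    z.real = rng.standard_normal((n_modes, *shape), dtype=np.float32)
    z.imag = rng.standard_normal((n_modes, *shape), dtype=np.float32)
    z *= np.float32(math.sqrt(0.5))
    if transfer is not None:
        z = fft.ifft2(fft.fft2(z, axes=(1, 2), overwrite_x=True) * transfer.astype(np.complex64),
                      axes=(1, 2), overwrite_x=True)
    return pedestal + np.tensordot(weights, np.abs(z).astype(np.float64) ** 2, axes=(0, 0))


def simulate_scos_frames(
    medium: OpticalMedium,
    geometry: SemiInfiniteGeometry,
    bfi: float | np.ndarray,
    flux: float,
    n_frames: int,
    seed: int | np.random.Generator,
    shape: tuple[int, int] = (128, 128),
    t_exp: float = 1e-3,
    substeps: int = 512,
    speckle_pixel_ratio: float = 2.3,
    gain: float = 9.64,
    read_sigma: float = 2.0,
    dark_offset: float = 100.0,
    frame_rate: float = 120.0,
    bit_depth: int = 16,
    shot_noise: bool = True,
    quantize: bool = True,
    uniform: bool = False,
) -> FrameStack:
    """Exposure-integrated speckle frames with the full camera noise model.

    Pixel values are quantize(gain * Poisson(flux * t_exp * J) + read noise
    + dark offset) where J is the exposure-averaged, spatially blurred
    speckle intensity with unit mean. ``bfi`` may be a scalar or a
    per-frame array (the flow is held constant within each exposure, and
    frames are statistically independent — the frame period is much longer
    than the speckle decorrelation time at the default settings).
    ``flux`` is in photoelectrons per pixel per second. ``uniform=True``
    replaces the speckle by flat illumination (noise-only null frames);
    ``flux=0`` yields dark frames.
    """
    if n_frames < 1:
        raise InvalidParameterError("n_frames must be >= 1")
    if substeps < 2:
        raise InvalidParameterError("substeps must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bfi_arr = np.broadcast_to(np.asarray(bfi, dtype=float), (n_frames,))
    sigma = speckle_ratio_to_sigma(speckle_pixel_ratio)
    transfer = _spatial_transfer(shape, sigma) if sigma > 0 else None
    medium_key = (medium.mua, medium.musp, medium.n_in, medium.n_out, medium.wavelength)
    geometry_key = (geometry.rho, geometry.z0, geometry.zb, geometry.reff)

    max_count = 2**bit_depth - 1
    if quantize:
        dtype = np.uint16 if bit_depth <= 16 else np.uint32
    else:
        dtype = np.float32  # analog debug mode: no integer truncation
    frames = np.empty((n_frames, *shape), dtype=dtype)
    saturated = 0
    for i in range(n_frames):
        if flux <= 0:
            j = None
        elif uniform:
            j = np.ones(shape)
        else:
            weights, pedestal = _temporal_modes(
                medium_key, geometry_key, float(bfi_arr[i]), t_exp, substeps
            )
            j = _speckle_exposure_image(rng, shape, weights, transfer, pedestal)
        if j is None:
            pixel = np.zeros(shape)
        else:
            lam = flux * t_exp * j
            pixel = rng.poisson(lam).astype(np.float64) if shot_noise else lam
        pixel = gain * pixel + dark_offset
        if read_sigma > 0:
            pixel = pixel + rng.normal(0.0, read_sigma, size=shape)
        if quantize:
            pixel = np.floor(pixel + 0.5)
        saturated += int(np.count_nonzero(pixel > max_count))
        frames[i] = np.clip(pixel, 0, max_count)
    if saturated > 0.01 * frames.size:
        warnings.warn(
            f"saturation fraction {saturated / frames.size:.2%} exceeds 1%", stacklevel=2
        )
    return FrameStack(
        frames=frames,
        t_exp=t_exp,
        frame_rate=frame_rate,
        gain=gain,
        read_sigma=read_sigma,
        dark_offset=dark_offset,
        speckle_pixel_ratio=speckle_pixel_ratio,
    )


def effective_beta_spatial(
    speckle_pixel_ratio: float = 2.3, window: int = 7
) -> float:
    """Expected small-exposure squared contrast of the simulated frames.

    Point-sampled speckle with Gaussian intensity correlation
    rho(d) = exp(-d^2 / (2 sigma^2)) reduces the expected unbiased sample
    variance within an N-pixel window by 1 - sum_{i != j} rho_ij / (N(N-1)).
    This factor plays the role of the SCOS coherence parameter beta for the
    synthetic camera and makes absolute BFi recovery well-posed on
    simulated data.
    """
    sigma = speckle_ratio_to_sigma(speckle_pixel_ratio)
    idx = np.arange(window)
    xs, ys = np.meshgrid(idx, idx)
    pts = np.stack([xs.ravel(), ys.ravel()], axis=1).astype(float)
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=-1)
    rho = np.exp(-d2 / (2.0 * sigma**2)) if sigma > 0 else np.eye(window**2)
    n = window**2
    off_diagonal = rho.sum() - n
    return float(1.0 - off_diagonal / (n * (n - 1)))


# ---------------------------------------------------------------------------
# ground-truth flow programs
# ---------------------------------------------------------------------------

#: relative harmonic amplitudes and phases of the default cardiac waveform
CARDIAC_HARMONICS = ((1.0, 0.0), (0.35, -1.2), (0.15, -2.4))


def _cardiac_shape(t: np.ndarray, freq: float) -> np.ndarray:
    """Zero-ish-mean multi-harmonic cardiac shape (fundamental + 2 overtones)."""
    u = np.zeros_like(t)
    for k, (amp, phase) in enumerate(CARDIAC_HARMONICS, start=1):
        u += amp * np.cos(2.0 * math.pi * k * freq * t + phase)
    return u


def make_flow_program(
    protocol: str,
    *,
    fs: float = 20.0,
    # cuff protocol
    baseline_bfi: float = 1e-8,
    occlusion_floor: float = 1e-9,
    hyperemia_peak_rbfi: float = 2.5,
    cardiac_freq: float = 1.2,
    pi: float = 0.4,
    pure_sinusoid: bool = False,
    respiration_amp: float = 0.0,
    respiration_freq: float = 0.25,
    baseline_s: float = 60.0,
    occlusion_s: float = 120.0,
    recovery_s: float = 120.0,
    occlusion_tau: float = 5.0,
    hyperemia_rise: float = 2.0,
    hyperemia_decay: float = 20.0,
    # phantom ramp protocol
    t_start_c: float = 7.0,
    t_end_c: float = 22.0,
    duration_s: float = 3600.0,
    radius_m: float = PHANTOM_SPHERE_RADIUS_M,
) -> FlowProgram:
    """Ground-truth flow program for the cuff or phantom-ramp protocol.

    ``cuff``: baseline with cardiac pulsatility of the configured
    pulsatility index (exact on the sampled baseline by construction),
    exponential decay to the occlusion floor without cardiac modulation,
    then a hyperemic overshoot relaxing back to baseline. ``phantom_ramp``:
    a linear temperature ramp with BFi(t) given by the Stokes-Einstein /
    Vogel model (alpha = 1).
    """
    if protocol == "phantom_ramp":
        n = max(2, int(round(duration_s * fs)))
        time = np.arange(n) / fs
        temp_c = t_start_c + (t_end_c - t_start_c) * time / time[-1]
        bfi = stokes_einstein_db(temp_c, radius_m, unit="C")
        return FlowProgram(
            time=time,
            bfi=np.asarray(bfi, dtype=float),
            segment=np.full(n, "ramp"),
            temperature_k=temp_c + 273.15,
        )
    if protocol != "cuff":
        raise InvalidParameterError(f"unknown protocol {protocol!r}")

    if baseline_bfi <= 0 or occlusion_floor <= 0 or pi < 0:
        raise InvalidParameterError("flow levels must be positive and PI nonnegative")
    if hyperemia_peak_rbfi <= 1.0:
        raise InvalidParameterError("hyperemia peak rBFi must exceed the baseline (1.0)")

    n = int(round((baseline_s + occlusion_s + recovery_s) * fs))
    time = np.arange(n) / fs
    segment = np.full(n, "baseline", dtype=object)
    occl = (time >= baseline_s) & (time < baseline_s + occlusion_s)
    reco = time >= baseline_s + occlusion_s
    segment[occl] = "occlusion"
    segment[reco] = "recovery"
    segment = segment.astype(str)

    envelope = np.full(n, baseline_bfi)
    t_occ = time[occl] - baseline_s
    envelope[occl] = occlusion_floor + (baseline_bfi - occlusion_floor) * np.exp(
        -t_occ / occlusion_tau
    )
    t_rec = time[reco] - (baseline_s + occlusion_s)
    overshoot = (hyperemia_peak_rbfi - 1.0) * (
        np.exp(-t_rec / hyperemia_decay) * (1.0 - np.exp(-t_rec / hyperemia_rise))
    )
    # rescale so the sampled recovery actually attains the configured peak
    if overshoot.max() > 0:
        overshoot *= (hyperemia_peak_rbfi - 1.0) / overshoot.max()
    envelope[reco] = baseline_bfi * (1.0 + overshoot)

    modulation = np.ones(n)
    if pi > 0:
        if pure_sinusoid:
            u = np.sin(2.0 * math.pi * cardiac_freq * time)
        else:
            u = _cardiac_shape(time, cardiac_freq)
        u_base = u[segment == "baseline"]
        u = u - u_base.mean()
        ptp = u[segment == "baseline"].max() - u[segment == "baseline"].min()
        modulation = 1.0 + pi * u / ptp
        modulation[occl] = 1.0
    if respiration_amp > 0:
        resp = 1.0 + respiration_amp * np.sin(2.0 * math.pi * respiration_freq * time)
        resp[occl] = 1.0
        modulation = modulation * resp

    bfi = envelope * modulation
    return FlowProgram(
        time=time,
        bfi=bfi,
        segment=segment,
        cardiac_freq=cardiac_freq,
        pi=pi,
    )
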