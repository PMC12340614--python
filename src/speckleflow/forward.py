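"""Closed-form theory for diffuse-speckle flowmetry.

This module implements the homogeneous semi-infinite solution of the
correlation diffusion equation (CDE) for the normalized electric-field
autocorrelation g1(tau), the Siegert relation linking g1 to the intensity
autocorrelation g2, the exposure-time integral that maps g1 onto squared
speckle contrast, and the Stokes-Einstein/Vogel model giving the Brownian
diffusion coefficient of aqueous microspheres as a function of temperature.

Unit conventions: lengths in cm, times in s, diffusion coefficients in
cm^2/s, wavelengths supplied in nm (converted internally), temperatures in
kelvin unless a function exposes an explicit ``unit`` flag.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import simpson

from .exceptions import InsufficientDataError, InvalidParameterError, NumericalError

#: speed of light in vacuum, cm/s
C_LIGHT_CM_S = 2.99792458e10

#: Boltzmann constant, J/K
K_BOLTZMANN = 1.380649e-23

#: pole of the Vogel viscosity equation for water, K
VOGEL_POLE_K = 137.546

VALID_CURVE_KINDS = ("g1", "g2", "G2_idws")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OpticalMedium:
    """Static optical properties of the probed medium.

    Parameters
    ----------
    mua : absorption coefficient, 1/cm
    musp : reduced scattering coefficient, 1/cm
    n_in : refractive index of the medium
    n_out : refractive index of the external medium (air = 1.0)
    wavelength : vacuum wavelength, nm
    """

    mua: float
    musp: float
    n_in: float = 1.33
    n_out: float = 1.0
    wavelength: float = 785.0

    def __post_init__(self) -> None:
        if self.mua <= 0 or self.musp <= 0 or self.wavelength <= 0:
            raise InvalidParameterError("mua, musp and wavelength must be positive")
        if self.n_in < 1 or self.n_out < 1:
            raise InvalidParameterError("refractive indices must be >= 1")

    @property
    def k0(self) -> float:
        """Wave number in the medium, 1/cm."""
        return 2.0 * math.pi * self.n_in / (self.wavelength * 1e-7)

    @property
    def v(self) -> float:
        """Speed of light in the medium, cm/s."""
        return C_LIGHT_CM_S / self.n_in

    @property
    def diffusion_coefficient(self) -> float:
        """Photon diffusion coefficient D = v / [3 (mua + musp)], cm^2/s."""
        return self.v / (3.0 * (self.mua + self.musp))


@dataclass(frozen=True)
class SemiInfiniteGeometry:
    """Extrapolated-boundary source/detector geometry on a half space.

    All lengths in cm. ``r1``/``r2`` are the distances from the detector to
    the isotropic source and its negative image above the extrapolated
    boundary.
    """

    rho: float
    z0: float
    zb: float
    reff: float
    r1: float = field(init=False)
    r2: float = field(init=False)

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.z0 <= 0 or self.zb <= 0:
            raise InvalidParameterError("rho, z0 and zb must be positive")
        if not 0.0 <= self.reff < 1.0:
            raise InvalidParameterError("Reff must lie in [0, 1)")
        object.__setattr__(self, "r1", math.hypot(self.rho, self.z0))
        object.__setattr__(self, "r2", math.hypot(self.rho, self.z0 + 2.0 * self.zb))

    @classmethod
    def for_medium(
        cls, medium: OpticalMedium, rho: float, reff: float | None = None
    ) -> "SemiInfiniteGeometry":
        """Build the geometry implied by a medium at separation ``rho``.

        ``reff`` may be overridden; by default it is computed from the
        medium's index mismatch.
        """
        if reff is None:
            reff = effective_reflection_coefficient(medium.n_in, medium.n_out)
        z0 = 1.0 / medium.musp
        zb = 2.0 * (1.0 + reff) / (3.0 * medium.musp * (1.0 - reff))
        return cls(rho=rho, z0=z0, zb=zb, reff=reff)


@dataclass(frozen=True)
class FlowParams:
    """Dynamic-scatterer model entering the CDE decay.

    ``alpha`` is the moving-scatterer fraction, ``db`` the effective Brownian
    diffusion coefficient (cm^2/s); the blood flow index is BFi = alpha * db.
    Moving scatterers follow <dr^2(tau)> = 6 * db * tau.
    """

    alpha: float = 1.0
    db: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise InvalidParameterError("alpha must lie in [0, 1]")
        if self.db < 0:
            raise InvalidParameterError("db must be nonnegative")

    @property
    def bfi(self) -> float:
        return self.alpha * self.db

    def msd(self, tau: np.ndarray | float) -> np.ndarray | float:
        """Mean-square displacement of the moving scatterers, cm^2."""
        return 6.0 * self.db * np.asarray(tau, dtype=float)

    @classmethod
    def from_bfi(cls, bfi: float) -> "FlowParams":
        """Flow parameters with alpha = 1 carrying the whole index in db."""
        return cls(alpha=1.0, db=bfi)


@dataclass
class CorrelationCurve:
    """An autocorrelation record on a delay grid.

    ``kind`` is one of ``g1`` (field), ``g2`` (normalized intensity) or
    ``G2_idws`` (unnormalized interferometric intensity autocorrelation,
    detector-count^2 units). ``beta`` optionally carries the coherence
    parameter relevant to the record.
    """

    tau: np.ndarray
    values: np.ndarray
    kind: str
    beta: float | None = None

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in VALID_CURVE_KINDS:
            raise InvalidParameterError(f"unknown curve kind {self.kind!r}")
        if self.tau.ndim != 1 or self.tau.shape != self.values.shape:
            raise InvalidParameterError("tau and values must be matching 1-d arrays")
        if self.tau.size and (self.tau[0] < 0 or np.any(np.diff(self.tau) <= 0)):
            raise InvalidParameterError("tau must be nonnegative and strictly increasing")
        if self.beta is not None and not 0.0 < self.beta <= 1.0:
            raise InvalidParameterError("beta must lie in (0, 1]")

    def to_csv(self, path: str | Path, params: dict | None = None) -> None:
        """Write a two-column CSV (tau_s, value) with a JSON parameter sidecar."""
        path = Path(path)
        header = "tau_s,value"
        np.savetxt(
            path,
            np.column_stack([self.tau, self.values]),
            delimiter=",",
            header=header,
            comments="",
        )
        sidecar = {"kind": self.kind, "beta": self.beta}
        if params:
            sidecar.update(params)
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "CorrelationCurve":
        path = Path(path)
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        sidecar_path = path.with_suffix(path.suffix + ".json")
        kind, beta = "g2", None
        if sidecar_path.exists():
            meta = json.loads(sidecar_path.read_text())
            kind = meta.get("kind", kind)
            beta = meta.get("beta")
        return cls(tau=data[:, 0], values=data[:, 1], kind=kind, beta=beta)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def effective_reflection_coefficient(n_in: float, n_out: float = 1.0) -> float:
    """Effective Fresnel reflection coefficient of the boundary.

    Uses the standard diffuse-optics polynomial approximation in the index
    ratio n = n_in / n_out:

        Reff(n) = -1.440 / n^2 + 0.710 / n + 0.668 + 0.0636 n

    valid for n >= 1 (the matched boundary gives Reff ~ 0).
    """
    if n_in <= 0 or n_out <= 0:
        raise InvalidParameterError("refractive indices must be positive")
    n = n_in / n_out
    reff = -1.440 / n**2 + 0.710 / n + 0.668 + 0.0636 * n
    return float(min(max(reff, 0.0), 1.0 - 1e-12))


def cde_decay_parameter(
    medium: OpticalMedium, flow: FlowParams, tau: np.ndarray | float
) -> np.ndarray:
    """Decay parameter K(tau) of the semi-infinite CDE solution, 1/cm.

    K(tau) = sqrt( 3 mua (mua + musp) + 6 (mua + musp) musp k0^2 alpha Db tau )
    """
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise InvalidParameterError("delay times must be nonnegative")
    mt = medium.mua + medium.musp
    static = 3.0 * medium.mua * mt
    dynamic = 6.0 * mt * medium.musp * medium.k0**2 * flow.bfi * tau
    return np.sqrt(static + dynamic)


def _g1_values(
    medium: OpticalMedium,
    geometry: SemiInfiniteGeometry,
    flow: FlowParams,
    tau: np.ndarray,
) -> np.ndarray:
    k = cde_decay_parameter(medium, flow, tau)
    k0 = cde_decay_parameter(medium, flow, 0.0)

    def unnormalized(kk: np.ndarray) -> np.ndarray:
        return (
            np.exp(-kk * geometry.r1) / geometry.r1
            - np.exp(-kk * geometry.r2) / geometry.r2
        )

    return unnormalized(k) / unnormalized(k0)


def g1_semi_infinite(
    medium: OpticalMedium,
    geometry: SemiInfiniteGeometry,
    flow: FlowParams,
    tau: np.ndarray | Sequence[float],
) -> CorrelationCurve:
    """Normalized field autocorrelation g1(tau) = G1(tau)/G1(0).

    G1 is the semi-infinite CDE solution (isotropic source at depth z0 with
    a negative image above the extrapolated boundary). g1 equals 1 at tau=0,
    decreases strictly in tau for a moving medium, and stays at 1 for a
    static medium (alpha*Db = 0).
    """
    tau = np.atleast_1d(np.asarray(tau, dtype=float))
    if np.any(tau < 0):
        raise InvalidParameterError("delay times must be nonnegative")
    return CorrelationCurve(tau=tau, values=_g1_values(medium, geometry, flow, tau), kind="g1")


def siegert_g2(g1: CorrelationCurve, beta: float) -> CorrelationCurve:
    """Siegert relation g2(tau) = 1 + beta |g1(tau)|^2."""
    if not 0.0 < beta <= 1.0:
        raise InvalidParameterError("beta must lie in (0, 1]")
    if g1.kind != "g1":
        raise InvalidParameterError("siegert_g2 expects a g1 curve")
    return CorrelationCurve(tau=g1.tau, values=1.0 + beta * np.abs(g1.values) ** 2,
                            kind="g2", beta=beta)


def siegert_invert(g2: CorrelationCurve, beta: float | None = None) -> CorrelationCurve:
    """Invert the Siegert relation: |g1| = sqrt(max(g2 - 1, 0) / beta)."""
    beta = beta if beta is not None else g2.beta
    if beta is None or not 0.0 < beta <= 1.0:
        raise InvalidParameterError("a beta in (0, 1] is required for inversion")
    if g2.kind != "g2":
        raise InvalidParameterError("siegert_invert expects a g2 curve")
    vals = np.sqrt(np.clip(g2.values - 1.0, 0.0, None) / beta)
    return CorrelationCurve(tau=g2.tau, values=vals, kind="g1", beta=beta)


def _kappa_tau_grid(t_exp: float, n_nodes: int) -> np.ndarray:
    return np.concatenate(
        [[0.0], np.logspace(math.log10(t_exp * 1e-9), math.log10(t_exp), n_nodes - 1)]
    )


def kappa_squared_from_g1(
    g1_sq: Callable[[np.ndarray], np.ndarray],
    beta: float,
    t_exp: float,
    n_nodes: int = 2048,
    check_convergence: bool = True,
    rtol: float = 1e-8,
) -> float:
    """Exposure-integrated squared speckle contrast for a given |g1|^2.

    kappa^2 = (2 beta / T) * int_0^T |g1(tau)|^2 (1 - tau/T) dtau

    evaluated by composite Simpson quadrature on ``n_nodes`` log-spaced nodes
    plus tau = 0 (|g1|^2 decays fastest near zero).  When
    ``check_convergence`` is set, the value is re-evaluated on a 2x finer
    grid and a relative disagreement above ``rtol`` raises
    :class:`NumericalError`.
    """
    if t_exp <= 0:
        raise InvalidParameterError("exposure time must be positive")

    def integral(n: int) -> float:
        tau = _kappa_tau_grid(t_exp, n)
        y = np.asarray(g1_sq(tau), dtype=float) * (1.0 - tau / t_exp)
        return float(simpson(y, x=tau))

    value = 2.0 * beta / t_exp * integral(n_nodes)
    if check_convergence:
        refined = 2.0 * beta / t_exp * integral(2 * n_nodes)
        denom = max(abs(refined), 1e-300)
        if abs(value - refined) / denom > rtol:
            raise NumericalError(
                "kappa^2 quadrature did not converge: "
                f"{value!r} (n={n_nodes}) vs {refined!r} (n={2 * n_nodes})"
            )
    return value


def kappa_squared_theory(
    medium: OpticalMedium,
    geometry: SemiInfiniteGeometry,
    flow: FlowParams,
    beta: float,
    t_exp: float,
    n_nodes: int = 2048,
    check_convergence: bool = False,
) -> float:
    """Squared speckle contrast predicted by the semi-infinite CDE solution.

    Monotone nonincreasing in both the exposure time and alpha*Db; tends to
    ``beta`` as the exposure time goes to zero.
    """
    if not 0.0 < beta <= 1.0:
        raise InvalidParameterError("beta must lie in (0, 1]")
    g1_sq = lambda tau: _g1_values(medium, geometry, flow, tau) ** 2
    return kappa_squared_from_g1(
        g1_sq, beta, t_exp, n_nodes=n_nodes, check_convergence=check_convergence
    )


def vogel_viscosity(temperature: float | np.ndarray, unit: str = "K") -> float | np.ndarray:
    """Viscosity of water from Vogel's equation, Pa*s.

    eta(T) = 1e-3 * exp(-3.7188 + 578.919 / (T - 137.546)), T in kelvin.
    """
    t_kelvin = _to_kelvin(temperature, unit)
    if np.any(np.asarray(t_kelvin) <= VOGEL_POLE_K):
        raise InvalidParameterError(
            f"temperature must exceed the Vogel pole at {VOGEL_POLE_K} K"
        )
    eta = 1e-3 * np.exp(-3.7188 + 578.919 / (-VOGEL_POLE_K + t_kelvin))
    return float(eta) if np.isscalar(temperature) else eta


def stokes_einstein_db(
    temperature: float | np.ndarray, radius: float, unit: str = "K"
) -> float | np.ndarray:
    """Theoretical Brownian diffusion coefficient of a sphere in water, cm^2/s.

    Db = kB T / (6 pi a eta(T)) with the radius ``a`` in meters and the
    viscosity from Vogel's equation; the SI result (m^2/s) is converted to
    cm^2/s. Strictly increasing in temperature over the liquid-water range.
    """
    if radius <= 0:
        raise InvalidParameterError("radius must be positive")
    t_kelvin = _to_kelvin(temperature, unit)
    eta = vogel_viscosity(t_kelvin)
    db = K_BOLTZMANN * np.asarray(t_kelvin, dtype=float) / (6.0 * math.pi * radius * eta) * 1e4
    return float(db) if np.isscalar(temperature) else db


def _to_kelvin(temperature, unit: str):
    if unit not in ("K", "C"):
        raise InvalidParameterError("temperature unit must be 'K' or 'C'")
    t = np.asarray(temperature, dtype=float)
    t = t + 273.15 if unit == "C" else t
    return float(t) if t.ndim == 0 else t


def extrapolate_optical_properties(
    musp_amplitude: float,
    scatter_power: float,
    mua_samples: Sequence[tuple[float, float]],
    target_wavelength: float,
) -> tuple[float, float]:
    """Extrapolate (mua, musp) to a target wavelength.

    The reduced scattering follows the power law musp(lambda) =
    A (lambda / 500 nm)^(-b); the absorption is an ordinary linear fit over
    wavelength through the supplied (lambda_nm, mua) samples, evaluated at
    the target wavelength. Returns ``(mua, musp)`` at ``target_wavelength``.
    """
    if musp_amplitude <= 0:
        raise InvalidParameterError("scattering amplitude A must be positive")
    samples = np.asarray(mua_samples, dtype=float)
    if samples.ndim != 2 or samples.shape[0] < 2:
        raise InsufficientDataError("at least two mua samples are needed for the linear model")
    musp = musp_amplitude * (target_wavelength / 500.0) ** (-scatter_power)
    slope, intercept = np.polyfit(samples[:, 0], samples[:, 1], 1)
    mua = slope * target_wavelength + intercept
    return float(mua), float(musp)
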