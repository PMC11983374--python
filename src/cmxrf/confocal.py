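"""Confocal transformation: MXRF spectrum -> CMXRF depth profile.

The probing volume formed by the two polycapillary optics is modelled as
a Gaussian of energy-dependent axial width sigma(E); the second optic
imposes a band-pass transmission T(E).  For a homogeneous thick sample
with surface at x0, the expected confocal intensity at scan position x_n
factorizes per energy channel:

    Phi(E, x_n) = Phi_0(E) * T(E) * R(x_n - x0; mu_bar(E), sigma(E))

where mu_bar(E) is the effective linear attenuation (ingoing at a fixed
effective excitation energy, outgoing at E) and R is the closed form of
the Gaussian-probe x exponential-absorption depth integral:

    R(d) = 1/2 * exp(mu^2 sigma^2 / 2 - mu d)
               * erfc((mu sigma^2 - d) / (sqrt(2) sigma))
         = integral_0^inf exp(-mu t) N(t; d, sigma^2) dt.

Six setup parameters (T_A, T_B, T_M, sigma_max, sigma_exp, sigma_off)
describe one calibration of the instrument; randomizing them per profile
emulates alignment and source drift so that a downstream model needs no
explicit setup calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
from scipy.special import erfcx

from . import physics
from .forward import MXRFSpectrum, SENSITIVITY_BAND
from .samples import Composition

__all__ = [
    "CU_KA_KEV",
    "SetupCalibration",
    "CalibrationRanges",
    "DepthProfile",
    "default_depth_grid",
    "optic_transmission",
    "probe_sigma",
    "depth_fwhm",
    "depth_response",
    "effective_linear_mu",
    "transform",
    "spectral_centroid",
    "randomize_calibration",
    "add_poisson_noise",
]

FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))

#: reference fluorescence energy at which the nominal calibration is
#: stated (Cu K-alpha)
CU_KA_KEV = physics.line_energy(29, "K-L3")

N_DEPTH_STEPS = 40
DEPTH_STEP_UM = 5.0


def default_depth_grid() -> np.ndarray:
    """40 scan positions, 5 um apart, origin at the first position."""
    return np.arange(N_DEPTH_STEPS) * DEPTH_STEP_UM


@dataclass(frozen=True)
class SetupCalibration:
    """The six setup parameters plus fixed geometry.

    Defaults are chosen so that the depth resolution at Cu K-alpha is
    30 um FWHM and the transmission is band-pass shaped over the 3-20
    keV sensitivity range.
    """

    T_A: float = 6.0  # keV, low-energy roll-off
    T_B: float = 25.0  # keV, high-energy roll-off
    T_M: float = 0.8  # peak transmission in (0, 1]
    sigma_max: float = 42.0  # um, amplitude of the power-law width term
    sigma_exp: float = 0.7  # dimensionless decay exponent
    sigma_off: float = 3.0  # um, asymptotic width floor
    theta_e: float = 50.0  # deg, excitation angle
    theta_d: float = 50.0  # deg, detection angle
    effective_excitation_energy: float = 17.0  # keV, ingoing-path energy

    def validate(self) -> None:
        if not (0 < self.T_M <= 1):
            raise ValueError("T_M must lie in (0, 1]")
        if self.T_A < 0 or self.T_B <= 0:
            raise ValueError("transmission roll-off parameters invalid")
        if self.sigma_off <= 0 or self.sigma_max < 0:
            raise ValueError("probe-width parameters invalid")
        if self.sigma_max > 0 and self.sigma_exp <= 0:
            raise ValueError("sigma(E) must decrease with energy")
        for a in (self.theta_e, self.theta_d):
            if not (0 < a < 90):
                raise ValueError("angles must lie in (0, 90) degrees")


@dataclass(frozen=True)
class CalibrationRanges:
    """Uniform randomization bounds per setup parameter."""

    bounds: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if lo > hi:
                raise ValueError(f"range for {name} has low > high")

    @classmethod
    def relative(
        cls, nominal: SetupCalibration | None = None, spread: float = 0.2
    ) -> "CalibrationRanges":
        """+-spread (default 20%) around the nominal six parameters."""
        nominal = nominal or SetupCalibration()
        names = ("T_A", "T_B", "T_M", "sigma_max", "sigma_exp", "sigma_off")
        b = {}
        for n in names:
            v = getattr(nominal, n)
            lo, hi = v * (1 - spread), v * (1 + spread)
            if n == "T_M":
                hi = min(hi, 1.0)
            b[n] = (lo, hi)
        return cls(b)


@dataclass
class DepthProfile:
    """One CMXRF depth profile: intensity over (scan position, energy)."""

    depth_grid: np.ndarray  # um, strictly increasing, uniform
    energy_grid: np.ndarray  # keV
    intensity: np.ndarray  # (n_steps, n_channels), expected counts
    x0: float  # um, surface position on the depth axis
    calibration: SetupCalibration
    label: str = ""

    def __post_init__(self) -> None:
        self.depth_grid = np.asarray(self.depth_grid, dtype=float)
        self.energy_grid = np.asarray(self.energy_grid, dtype=float)
        self.intensity = np.asarray(self.intensity)
        if self.intensity.shape != (len(self.depth_grid), len(self.energy_grid)):
            raise ValueError("intensity must be (n_steps, n_channels)")
        steps = np.diff(self.depth_grid)
        if np.any(steps <= 0) or (steps.size and not np.allclose(steps, steps[0])):
            raise ValueError("depth grid must be strictly increasing and uniform")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be non-negative")


def optic_transmission(energy, cal: SetupCalibration) -> np.ndarray | float:
    """Band-pass transmission of the detection optic,
    T(E) = T_M * exp(-T_A/E) * exp(-E/T_B); maximal at sqrt(T_A*T_B)."""
    e = np.asarray(energy, dtype=float)
    out = cal.T_M * np.exp(-cal.T_A / e) * np.exp(-e / cal.T_B)
    return float(out) if np.isscalar(energy) else out


def probe_sigma(energy, cal: SetupCalibration) -> np.ndarray | float:
    """Axial probing-volume width sigma(E) = sigma_off + sigma_max * E^-sigma_exp,
    strictly decreasing with energy (smaller probe at higher E)."""
    e = np.asarray(energy, dtype=float)
    out = cal.sigma_off + cal.sigma_max * e ** (-cal.sigma_exp)
    return float(out) if np.isscalar(energy) else out


def depth_fwhm(energy, cal: SetupCalibration | None = None) -> np.ndarray | float:
    """Depth resolution (FWHM) of the probing volume at ``energy``."""
    cal = cal or SetupCalibration()
    return FWHM_FACTOR * probe_sigma(energy, cal)


def depth_response(d, mu_lin, sigma) -> np.ndarray | float:
    """Gaussian-probe x exponential-absorption depth response.

    Parameters: probe-center depth below the surface d (um), effective
    linear attenuation mu_lin (1/um), probe width sigma (um).  Evaluated
    through erfcx for overflow-free results at large mu*sigma:

        R = 1/2 * erfcx(u) * exp(-d^2 / (2 sigma^2)),
        u = (mu sigma^2 - d) / (sqrt(2) sigma),

    which is exactly 1/2 exp(mu^2 s^2/2 - mu d) erfc(u).  For deeply
    buried probes (u << 0, erfcx overflows) the asymptotic full-burial
    form exp(mu^2 s^2/2 - mu d) is used; its exponent is then negative.
    """
    d = np.asarray(d, dtype=float)
    mu = np.asarray(mu_lin, dtype=float)
    s = np.asarray(sigma, dtype=float)
    if np.any(s <= 0):
        raise ValueError("sigma must be positive")
    if np.any(mu < 0):
        raise ValueError("mu_lin must be non-negative")
    u = (mu * s**2 - d) / (np.sqrt(2.0) * s)
    safe = u > -25.0
    # R <= 1 always, so the full-burial exponent is non-positive where used;
    # clip it to keep the unevaluated branch of np.where overflow-free.
    burial_exponent = np.minimum(mu**2 * s**2 / 2.0 - mu * d, 0.0)
    out = np.where(
        safe,
        0.5 * erfcx(np.where(safe, u, 0.0)) * np.exp(-(d**2) / (2 * s**2)),
        np.exp(burial_exponent),
    )
    return float(out) if out.ndim == 0 else out


def effective_linear_mu(
    comp: Composition, energy, cal: SetupCalibration
) -> np.ndarray | float:
    """Effective linear attenuation mu_bar(E) in 1/um:
    rho * (mu_m(E_eff_in)/sin(theta_e) + mu_m(E)/sin(theta_d)) with the
    cm^2/g * g/cm^3 product converted from 1/cm to 1/um."""
    sin_e = np.sin(np.radians(cal.theta_e))
    sin_d = np.sin(np.radians(cal.theta_d))
    mu_in = physics.mixture_mu(comp, cal.effective_excitation_energy)
    mu_out = physics.mixture_mu(comp, energy)
    return comp.density * (mu_in / sin_e + mu_out / sin_d) * 1e-4


def transform(
    spec: MXRFSpectrum,
    comp: Composition,
    cal: SetupCalibration | None = None,
    x0: float = 75.0,
    depth_grid: np.ndarray | None = None,
) -> DepthProfile:
    """Apply the confocal transformation to an MXRF spectrum.

    Returns the (n_steps, n_channels) expected-count matrix
    Phi(E, x_n) = Phi_0(E) * T(E) * R(x_n - x0; mu_bar(E), sigma(E)).
    Channels at or below 1 keV (outside the attenuation model's domain)
    carry zero intensity.
    """
    cal = cal or SetupCalibration()
    cal.validate()
    depth_grid = default_depth_grid() if depth_grid is None else np.asarray(depth_grid, float)
    e = spec.energy_grid
    usable = e > 1.0
    e_use = e[usable]

    t_opt = optic_transmission(e_use, cal)
    sig = probe_sigma(e_use, cal)
    mu_bar = effective_linear_mu(comp, e_use, cal)

    d = depth_grid[:, None] - x0  # (n_steps, 1)
    r = depth_response(d, mu_bar[None, :], sig[None, :])
    intensity = np.zeros((len(depth_grid), len(e)))
    intensity[:, usable] = spec.intensity[usable][None, :] * t_opt[None, :] * r
    return DepthProfile(depth_grid, e, intensity, float(x0), cal, spec.composition_ref)


def spectral_centroid(
    profile: DepthProfile, band: tuple[float, float] = SENSITIVITY_BAND
) -> np.ndarray:
    """Intensity-weighted mean energy per depth step over ``band``.

    Absorption hardens the detected spectrum with depth, so the centroid
    rises once the probing volume is fully inside the sample; within
    roughly one probe FWHM (at the soft band edge) of the surface the
    half-submerged probe can produce a small non-monotonic transition.
    """
    e = profile.energy_grid
    m = (e >= band[0]) & (e <= band[1])
    w = profile.intensity[:, m]
    return (w * e[m]).sum(axis=1) / np.maximum(w.sum(axis=1), 1e-300)


_RANDOMIZED = ("T_A", "T_B", "T_M", "sigma_max", "sigma_exp", "sigma_off")


def randomize_calibration(
    ranges: CalibrationRanges,
    rng: np.random.Generator | int,
    nominal: SetupCalibration | None = None,
    max_attempts: int = 100,
) -> SetupCalibration:
    """Draw a calibration with each bounded parameter uniform in its
    range, resampling (up to ``max_attempts``) until the invariants hold."""
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    nominal = nominal or SetupCalibration()
    for _ in range(max_attempts):
        draws = {
            name: float(rng.uniform(lo, hi)) if hi > lo else float(lo)
            for name, (lo, hi) in ranges.bounds.items()
        }
        cal = replace(nominal, **draws)
        try:
            cal.validate()
        except ValueError:
            continue
        return cal
    raise ValueError("no valid calibration found within the given ranges")


def add_poisson_noise(
    profile: DepthProfile,
    exposure_scale: float = 1.0,
    rng: np.random.Generator | int = 0,
) -> DepthProfile:
    """Replace each expected-count cell by a Poisson draw with mean
    exposure_scale * intensity (integer counts; same seed, same noise)."""
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    noisy = rng.poisson(exposure_scale * profile.intensity).astype(np.int64)
    return DepthProfile(
        profile.depth_grid,
        profile.energy_grid,
        noisy,
        profile.x0,
        profile.calibration,
        profile.label,
    )
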