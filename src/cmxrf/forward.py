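"""Deterministic fundamental-parameter MXRF forward model.

Produces the (non-confocal) micro-XRF spectrum Phi_0(E) of a thick
homogeneous sample under polychromatic tube excitation:

* tube excitation: Kramers continuum with simple self-filtration plus
  the anode characteristic lines;
* primary fluorescence: Sherman equation in its thick-sample form,
  summed over the excitation channels above each absorption edge
  (primary fluorescence only - no secondary enhancement);
* scatter continuum: tube spectrum scattered out of the sample, weighted
  by the composition's scattering cross section and self-absorption;
* detector: Gaussian response with energy-dependent FWHM, no escape or
  pile-up artifacts.

The confocal transformation downstream is agnostic to how Phi_0(E) was
produced; externally simulated spectra (e.g. Monte-Carlo) can be loaded
into :class:`MXRFSpectrum` instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import physics
from .samples import Composition

__all__ = [
    "DEFAULT_N_CHANNELS",
    "DEFAULT_CHANNEL_WIDTH",
    "default_energy_grid",
    "ExcitationSpectrum",
    "MXRFSpectrum",
    "kramers_continuum",
    "tube_spectrum",
    "primary_fluorescence",
    "scatter_background",
    "detector_response",
    "simulate_mxrf",
]

DEFAULT_N_CHANNELS = 2048
DEFAULT_CHANNEL_WIDTH = 0.02  # keV -> grid covers 0-40.96 keV

#: sensitivity band of the modelled spectrometer, keV
SENSITIVITY_BAND = (3.0, 20.0)

_SIN = np.sin
_DEG = np.pi / 180.0


def default_energy_grid(
    n_channels: int = DEFAULT_N_CHANNELS, width: float = DEFAULT_CHANNEL_WIDTH
) -> np.ndarray:
    """Uniform channel-center grid in keV."""
    return (np.arange(n_channels) + 0.5) * width


@dataclass
class ExcitationSpectrum:
    energy_grid: np.ndarray  # keV, channel centers
    flux: np.ndarray  # photons per channel (arbitrary exposure unit)
    tube_voltage: float  # kV
    anode: int  # atomic number

    def __post_init__(self) -> None:
        self.energy_grid = np.asarray(self.energy_grid, dtype=float)
        self.flux = np.asarray(self.flux, dtype=float)
        if np.any(self.flux < 0):
            raise ValueError("flux must be non-negative")
        if np.any(self.flux[self.energy_grid > self.tube_voltage] > 0):
            raise ValueError("flux above the tube voltage must vanish")


@dataclass
class MXRFSpectrum:
    """Energy-gridded expected fluorescence intensity Phi_0(E)."""

    energy_grid: np.ndarray
    intensity: np.ndarray
    composition_ref: str = ""

    def __post_init__(self) -> None:
        self.energy_grid = np.asarray(self.energy_grid, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != self.energy_grid.shape:
            raise ValueError("intensity and grid shapes differ")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be non-negative")
        widths = np.diff(self.energy_grid)
        if widths.size and not np.allclose(widths, widths[0], rtol=1e-9):
            raise ValueError("channel width must be uniform")

    @property
    def channel_width(self) -> float:
        return float(self.energy_grid[1] - self.energy_grid[0])

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"energy_keV": self.energy_grid, "intensity": self.intensity}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, composition_ref: str = "") -> "MXRFSpectrum":
        df = pd.read_csv(path)
        return cls(df["energy_keV"].to_numpy(), df["intensity"].to_numpy(), composition_ref)


def kramers_continuum(energy, voltage: float, anode_z: int) -> np.ndarray:
    """Unfiltered Kramers bremsstrahlung shape I(E) ~ Z*(E0/E - 1),
    clipped to zero outside (0, E0)."""
    e = np.asarray(energy, dtype=float)
    with np.errstate(divide="ignore"):
        shape = anode_z * (voltage / e - 1.0)
    return np.where((e > 0) & (e < voltage), shape, 0.0)


# Rh-anode characteristic lines carried as a fraction of the continuum flux.
_ANODE_LINE_FRACTIONS = {"K-L3": 0.040, "K-M3": 0.008, "L3-M5": 0.020, "L2-M4": 0.012}


def tube_spectrum(
    voltage: float = 50.0,
    anode: int = 45,
    grid: np.ndarray | None = None,
    photons: float = 2.0e7,
    filtration_keV: float = 1.5,
) -> ExcitationSpectrum:
    """Tube excitation: filtered Kramers continuum plus anode lines.

    ``photons`` normalizes the total emitted flux (continuum + lines);
    ``filtration_keV`` models inherent beam hardening as
    exp(-(filtration/E)^3), suppressing the soft tail.
    """
    if not (10.0 < voltage <= 60.0):
        raise ValueError("tube voltage must lie in (10, 60] kV")
    grid = default_energy_grid() if grid is None else np.asarray(grid, dtype=float)
    cont = kramers_continuum(grid, voltage, anode)
    with np.errstate(divide="ignore"):
        cont = cont * np.exp(-((filtration_keV / np.maximum(grid, 1e-9)) ** 3))
    total_cont = cont.sum()
    if total_cont <= 0:
        raise ValueError("grid does not overlap the emitted continuum")
    flux = cont / total_cont

    line_budget = sum(_ANODE_LINE_FRACTIONS.values())
    flux *= 1.0 - line_budget
    for label, frac in _ANODE_LINE_FRACTIONS.items():
        try:
            e_line = physics.line_energy(anode, label)
        except physics.UnknownLineError:
            continue
        shell = "K" if label.startswith("K") else "L3"
        if physics.edge_energy(anode, shell) >= voltage or e_line >= grid[-1]:
            continue
        idx = int(np.argmin(np.abs(grid - e_line)))
        flux[idx] += frac
    return ExcitationSpectrum(grid, flux * photons, voltage, anode)


_SHELL_OF_LINE = {"K-L3": "K", "K-M3": "K", "L3-M5": "L3", "L2-M4": "L12"}


def primary_fluorescence(
    comp: Composition,
    exc: ExcitationSpectrum,
    theta_e: float = 50.0,
    theta_d: float = 50.0,
    e_min: float = 2.0,
    e_max: float | None = None,
) -> dict[tuple[int, str], float]:
    """Sherman-equation expected line intensities from a thick sample.

    For each line i of each present element,

        I_i = w_i * omega_i * p_i * sum_E' flux(E') * tau_shell(Z, E')
              / (mu_s(E')/sin(theta_e) + mu_s(E_i)/sin(theta_d))

    summed over excitation channels above the shell's edge.  Geometry
    and solid-angle constants are absorbed into the flux normalization.
    """
    e_max = e_max if e_max is not None else float(exc.energy_grid[-1])
    sin_e, sin_d = _SIN(theta_e * _DEG), _SIN(theta_d * _DEG)
    mask = (exc.flux > 0) & (exc.energy_grid > 1.0)
    e_exc = exc.energy_grid[mask]
    flux = exc.flux[mask]
    mu_in = physics.mixture_mu(comp, e_exc)

    # collect lines first so the outgoing mixture attenuation is one call
    entries = []
    for z, w in comp.mass_fractions.items():
        if w <= 0:
            continue
        for line in physics.element_lines(z, e_min, e_max):
            entries.append((z, w, line))
    if not entries:
        return {}
    mu_outs = physics.mixture_mu(comp, np.array([ln.energy for _, _, ln in entries]))

    out: dict[tuple[int, str], float] = {}
    for (z, w, line), mu_out in zip(entries, mu_outs):
        shell = _SHELL_OF_LINE[line.line_label]
        tau = _tau_shell_cached(z, line.line_label, shell, e_exc)
        if not np.any(tau > 0):
            continue  # no tabulated edge reachable: contributes nothing
        omega = physics.fluorescence_yield(z, "K" if shell == "K" else "L")
        integrand = flux * tau / (mu_in / sin_e + mu_out / sin_d)
        out[(z, line.line_label)] = float(
            w * omega * line.relative_intensity * integrand.sum()
        )
    return out


# tau_shell on a fixed excitation grid is composition-independent; cache
# it across the many samples of a dataset generation run
_TAU_CACHE: dict[tuple, np.ndarray] = {}


def _tau_shell_cached(z: int, label: str, shell: str, e_exc: np.ndarray) -> np.ndarray:
    key = (z, label, len(e_exc), float(e_exc[0]), float(e_exc[-1]))
    tau = _TAU_CACHE.get(key)
    if tau is None:
        tau = physics.shell_photo_share(z, e_exc, shell) * _photo_mu(z, e_exc)
        if len(_TAU_CACHE) > 4096:
            _TAU_CACHE.clear()
        _TAU_CACHE[key] = tau
    return tau


def _photo_mu(z: int, e: np.ndarray) -> np.ndarray:
    from . import _fp_synthetic as _fp

    return _fp.photoelectric_mu(z, e)


def scatter_background(
    comp: Composition,
    exc: ExcitationSpectrum,
    theta_e: float = 50.0,
    theta_d: float = 50.0,
    scatter_scale: float = 1.0,
    flat_floor: float = 0.0,
) -> np.ndarray:
    """Scatter continuum: tube photons elastically/inelastically scattered
    out of the sample.  Modelled as flux(E) weighted by the sample's
    scattering cross section over its total self-absorption, plus an
    optional flat floor inside the excited band."""
    sin_e, sin_d = _SIN(theta_e * _DEG), _SIN(theta_d * _DEG)
    bg = np.zeros_like(exc.flux)
    mask = (exc.flux > 0) & (exc.energy_grid > 1.0)
    e = exc.energy_grid[mask]
    mu_s = physics.mixture_mu(comp, e)
    sig = physics.mixture_scatter_mu(comp, e)
    bg[mask] = scatter_scale * exc.flux[mask] * sig / (mu_s / sin_e + mu_s / sin_d)
    bg[mask] += flat_floor
    return bg


def detector_fwhm(energy, mn_ka_fwhm: float = 0.150, noise: float = 0.080) -> np.ndarray:
    """Detector resolution model FWHM(E) = sqrt(noise^2 + k*E), with k
    fixed by the configured FWHM at Mn K-alpha (5.899 keV)."""
    e_mn = 5.899
    k = (mn_ka_fwhm**2 - noise**2) / e_mn
    return np.sqrt(noise**2 + k * np.asarray(energy, dtype=float))


def detector_response(
    lines: Mapping[tuple[int, str], float] | Sequence[tuple[float, float]],
    grid: np.ndarray | None = None,
    background: np.ndarray | None = None,
    mn_ka_fwhm: float = 0.150,
    noise: float = 0.080,
    composition_ref: str = "",
) -> MXRFSpectrum:
    """Render line intensities into a detector spectrum.

    Each line becomes a Gaussian of energy-dependent FWHM whose channel
    sum equals the line intensity; the optional per-channel background is
    added as-is.  ``lines`` is either the (Z, label) -> intensity map of
    :func:`primary_fluorescence` or an explicit (energy, intensity) list.
    """
    grid = default_energy_grid() if grid is None else np.asarray(grid, dtype=float)
    width = grid[1] - grid[0]
    if isinstance(lines, Mapping):
        pairs = [(physics.line_energy(z, lab), i) for (z, lab), i in lines.items()]
    else:
        pairs = list(lines)
    spec = np.zeros_like(grid)
    for e_line, intensity in pairs:
        if intensity <= 0:
            continue
        sigma = detector_fwhm(e_line, mn_ka_fwhm, noise) / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        lo = np.searchsorted(grid, e_line - 8 * sigma)
        hi = np.searchsorted(grid, e_line + 8 * sigma)
        spec[lo:hi] += intensity * width / (sigma * np.sqrt(2 * np.pi)) * np.exp(
            -0.5 * ((grid[lo:hi] - e_line) / sigma) ** 2
        )
    if background is not None:
        spec = spec + np.asarray(background, dtype=float)
    return MXRFSpectrum(grid, spec, composition_ref)


def simulate_mxrf(
    comp: Composition,
    exc: ExcitationSpectrum | None = None,
    theta_e: float = 50.0,
    theta_d: float = 50.0,
    scatter_scale: float = 1.0,
    flat_floor: float = 0.0,
    mn_ka_fwhm: float = 0.150,
    noise: float = 0.080,
    composition_ref: str = "",
) -> MXRFSpectrum:
    """End-to-end forward simulation: tube -> Sherman -> scatter -> detector."""
    exc = exc if exc is not None else tube_spectrum()
    lines = primary_fluorescence(comp, exc, theta_e, theta_d)
    bg = scatter_background(comp, exc, theta_e, theta_d, scatter_scale, flat_floor)
    return detector_response(
        lines, exc.energy_grid, bg, mn_ka_fwhm, noise, composition_ref
    )
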