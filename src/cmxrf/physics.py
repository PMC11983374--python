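"""Atomic and fundamental-parameter data behind a single query interface.

All other modules obtain fluorescence-line energies, absorption edges,
fluorescence yields and mass attenuation coefficients from here, so the
data backend can be swapped without touching the simulation or the model.
The default backend is the bundled analytic compilation in
:mod:`cmxrf._fp_synthetic`.

Energies are keV, mass attenuation is cm^2/g, mass fractions are
dimensionless in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from . import _fp_synthetic as _fp

__all__ = [
    "ElementLine",
    "UnknownLineError",
    "DARK_MATRIX_CELLULOSE",
    "line_energy",
    "element_lines",
    "edge_energy",
    "fluorescence_yield",
    "shell_photo_share",
    "mass_attenuation",
    "scatter_attenuation",
    "mixture_mu",
    "mixture_scatter_mu",
    "symbol",
    "atomic_number",
    "atomic_weight",
]

SUPPORTED_LINES = ("K-L3", "K-M3", "L3-M5", "L2-M4")

#: Mass fractions of the default dark-matrix stand-in, a cellulose-like
#: light-element pseudo-compound (C6H10O5).  Used for attenuation only.
DARK_MATRIX_CELLULOSE: dict[int, float] = {6: 0.4445, 1: 0.0622, 8: 0.4933}


class UnknownLineError(KeyError):
    """Raised when an element has no tabulated line of the requested type."""


@dataclass(frozen=True)
class ElementLine:
    """One fluorescence line of one element."""

    atomic_number: int
    line_label: str
    energy: float  # keV
    relative_intensity: float  # within its line family, sums to <= 1

    def __post_init__(self) -> None:
        if self.energy <= 0:
            raise ValueError("line energy must be positive")
        if not (0 < self.relative_intensity <= 1):
            raise ValueError("relative intensity must be in (0, 1]")
        if not (_fp.Z_MIN <= self.atomic_number <= _fp.Z_MAX):
            raise ValueError("Z outside supported range 11-92")


def symbol(Z: int) -> str:
    return _fp.SYMBOLS[Z - 1]


def atomic_number(sym: str) -> int:
    return _fp.SYMBOLS.index(sym) + 1


def atomic_weight(Z: int) -> float:
    return float(_fp.ATOMIC_WEIGHTS[Z - 1])


def line_energy(Z: int, line: str) -> float:
    """Fluorescence energy of ``line`` (e.g. ``"K-L3"``) of element ``Z``.

    Raises :class:`UnknownLineError` if the element has no such line in
    the backend (e.g. L lines of light elements).
    """
    e = _fp.line_energy_table(Z, line)
    if e is None:
        raise UnknownLineError(f"{symbol(Z) if 1 <= Z <= 92 else Z} has no {line} line")
    return e


def element_lines(Z: int, e_min: float = 0.0, e_max: float = np.inf) -> list[ElementLine]:
    """All tabulated lines of element ``Z`` with energy inside [e_min, e_max]."""
    out = []
    for label in SUPPORTED_LINES:
        e = _fp.line_energy_table(Z, label)
        if e is not None and e_min <= e <= e_max:
            out.append(ElementLine(Z, label, e, _fp.LINE_FAMILY_WEIGHTS[label]))
    return out


def edge_energy(Z: int, shell: str) -> float:
    """Absorption edge energy in keV; shell is 'K', 'L12' or 'L3'."""
    if shell == "K":
        return float(_fp.k_edge(Z))
    if shell == "L12":
        return float(_fp.l2_edge(Z))
    if shell == "L3":
        return float(_fp.l3_edge(Z))
    raise ValueError(f"unknown shell {shell!r}")


def fluorescence_yield(Z: int, shell: str) -> float:
    return _fp.fluorescence_yield(Z, shell)


def shell_photo_share(Z: int, energy, shell: str):
    """Fraction of the photoelectric cross section at ``energy`` that
    ionizes ``shell`` of element ``Z``."""
    return _fp.shell_photo_share(Z, np.asarray(energy, dtype=float), shell)


def mass_attenuation(Z: int, energy) -> np.ndarray | float:
    """Total mass attenuation coefficient mu/rho in cm^2/g."""
    e = np.asarray(energy, dtype=float)
    if np.any(e <= 0):
        raise ValueError("energy must be positive")
    out = _fp.total_mu(Z, e)
    return float(out) if np.isscalar(energy) else out


def scatter_attenuation(Z: int, energy) -> np.ndarray | float:
    """Scattering-only (incoherent + coherent) part of mu/rho, cm^2/g."""
    e = np.asarray(energy, dtype=float)
    out = _fp.scatter_mu(Z, e)
    return float(out) if np.isscalar(energy) else out


def _fractions(composition) -> tuple[Mapping[int, float], float, Mapping[int, float]]:
    """Accept either a mapping Z -> w or an object exposing
    ``mass_fractions`` and ``dark_matrix_fraction``."""
    if hasattr(composition, "mass_fractions"):
        w = composition.mass_fractions
        dark = getattr(composition, "dark_matrix_fraction", 1.0 - sum(w.values()))
        matrix = getattr(composition, "dark_matrix", None) or DARK_MATRIX_CELLULOSE
    else:
        w = composition
        dark = max(0.0, 1.0 - sum(w.values()))
        matrix = DARK_MATRIX_CELLULOSE
    return w, dark, matrix


def _weighted_mu(composition, energy, elemental) -> np.ndarray | float:
    w, dark, matrix = _fractions(composition)
    total = sum(w.values()) + dark
    if total > 1.0 + 1e-6:
        raise ValueError(f"mass fractions sum to {total:.6f} > 1")
    e = np.asarray(energy, dtype=float)
    out = np.zeros_like(e)
    for Z, wi in w.items():
        if wi > 0:
            out = out + wi * elemental(Z, e)
    for Z, wi in matrix.items():
        out = out + dark * wi * elemental(Z, e)
    return float(out) if np.isscalar(energy) else out


def mixture_mu(composition, energy) -> np.ndarray | float:
    """Mass attenuation of a mixture: the mass-fraction-weighted sum of
    elemental coefficients, with the unassigned (dark matrix) fraction
    attenuating as the configured light-element pseudo-compound.

    ``energy`` must lie in (1, 50] keV (scalar or array).
    """
    e = np.asarray(energy, dtype=float)
    if np.any((e <= 1.0) | (e > 50.0)):
        raise ValueError("energy outside tabulated range (1, 50] keV")
    return _weighted_mu(composition, energy, _fp.total_mu)


def mixture_scatter_mu(composition, energy) -> np.ndarray | float:
    """Scattering-only mass attenuation of a mixture (for backgrounds)."""
    return _weighted_mu(composition, energy, _fp.scatter_mu)
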