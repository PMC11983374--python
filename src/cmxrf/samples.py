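"""Synthetic homogeneous bulk-sample compositions.

Samples are drawn with the statistical structure used to build the
training corpus: every target element is present with a Bernoulli
occurrence probability estimated from reference-material compilations,
its mass fraction (if present) follows a log-normal distribution, the
density is uniform, and everything not assigned to a detectable element
is "dark matrix" - light elements the confocal setup cannot see but
which dominate absorption.

Concentrations are mass fractions in [0, 1] throughout; percent appears
only at I/O boundaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import physics

__all__ = [
    "TARGET_ELEMENTS",
    "OccurrenceTable",
    "Composition",
    "default_occurrence_table",
    "build_occurrence_table",
    "draw_composition",
    "draw_density",
    "draw_batch",
    "save_compositions",
    "load_compositions",
]

DENSITY_RANGE = (0.5, 3.5)  # g/cm^3
DETECTABLE_CAP = 0.35  # max summed detectable mass fraction before rescaling


def _target_elements() -> tuple[int, ...]:
    """The 53 quantified elements: K..Nb, Cd..W and Pt..Bi, excluding the
    noble gases Kr and Xe and (lacking stable isotopes) Pm."""
    zs = [z for z in range(19, 42) if z != 36]
    zs += [z for z in range(48, 75) if z not in (54, 61)]
    zs += list(range(78, 84))
    return tuple(zs)


TARGET_ELEMENTS: tuple[int, ...] = _target_elements()
assert len(TARGET_ELEMENTS) == 53


@dataclass
class OccurrenceTable:
    """Per-element occurrence rate and log-normal concentration model.

    ``lognorm_mu``/``lognorm_sigma`` parametrize the natural log of the
    mass fraction of an element when it is present.
    """

    elements: tuple[int, ...]
    rate: np.ndarray
    lognorm_mu: np.ndarray
    lognorm_sigma: np.ndarray

    def __post_init__(self) -> None:
        self.rate = np.asarray(self.rate, dtype=float)
        self.lognorm_mu = np.asarray(self.lognorm_mu, dtype=float)
        self.lognorm_sigma = np.asarray(self.lognorm_sigma, dtype=float)
        n = len(self.elements)
        if not (len(self.rate) == len(self.lognorm_mu) == len(self.lognorm_sigma) == n):
            raise ValueError("table columns must align with the element list")
        if np.any((self.rate < 0) | (self.rate > 1)):
            raise ValueError("occurrence rates must lie in [0, 1]")
        if np.any(self.lognorm_sigma[self.rate > 0] <= 0):
            raise ValueError("lognorm_sigma must be positive where rate > 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "Z": self.elements,
                "rate": self.rate,
                "log_mu": self.lognorm_mu,
                "log_sigma": self.lognorm_sigma,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "OccurrenceTable":
        df = pd.read_csv(path)
        return cls(
            tuple(int(z) for z in df["Z"]),
            df["rate"].to_numpy(),
            df["log_mu"].to_numpy(),
            df["log_sigma"].to_numpy(),
        )


@dataclass
class Composition:
    """Ground truth for one homogeneous bulk sample.

    ``mass_fractions`` holds the detectable elements only; the remainder
    of the unit mass is ``dark_matrix_fraction``, attenuating as a
    light-element pseudo-compound (see :mod:`cmxrf.physics`).
    """

    mass_fractions: dict[int, float]
    density: float  # g/cm^3
    dark_matrix_fraction: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        s = float(sum(self.mass_fractions.values()))
        if any(w < 0 for w in self.mass_fractions.values()):
            raise ValueError("mass fractions must be non-negative")
        if self.dark_matrix_fraction is None:
            self.dark_matrix_fraction = 1.0 - s
        if abs(s + self.dark_matrix_fraction - 1.0) > 1e-9:
            raise ValueError("mass fractions + dark matrix must sum to 1")
        if self.density <= 0:
            raise ValueError("density must be positive")

    def fraction(self, Z: int) -> float:
        return self.mass_fractions.get(Z, 0.0)

    def as_vector(self, elements: Sequence[int] = TARGET_ELEMENTS) -> np.ndarray:
        return np.array([self.fraction(z) for z in elements])

    def mu(self, energy):
        """Mass attenuation of the full sample (detectable + dark matrix)."""
        return physics.mixture_mu(self, energy)


def default_occurrence_table() -> OccurrenceTable:
    """Bundled default table.

    Rates and log-normal parameters are hand-set to plausible geochemical
    magnitudes (rock-forming elements common at the percent level, trace
    metals rare at the ppm level); the resulting samples are >65% dark
    matrix on average.  Fully user-replaceable via CSV.
    """
    # symbol: (rate, median mass fraction, sigma of ln w)
    spec = {
        "K": (0.85, 1.5e-2, 1.0), "Ca": (0.90, 3.0e-2, 1.1),
        "Sc": (0.30, 1.5e-5, 1.0), "Ti": (0.70, 3.0e-3, 1.2),
        "V": (0.50, 1.0e-4, 1.0), "Cr": (0.55, 1.2e-4, 1.2),
        "Mn": (0.80, 8.0e-4, 1.2), "Fe": (0.95, 3.0e-2, 1.1),
        "Co": (0.45, 2.0e-5, 1.0), "Ni": (0.55, 6.0e-5, 1.2),
        "Cu": (0.60, 5.0e-5, 1.2), "Zn": (0.65, 1.0e-4, 1.2),
        "Ga": (0.35, 1.8e-5, 0.8), "Ge": (0.20, 1.5e-6, 0.8),
        "As": (0.35, 1.0e-5, 1.3), "Se": (0.25, 2.0e-6, 1.2),
        "Br": (0.25, 5.0e-6, 1.3), "Rb": (0.55, 8.0e-5, 1.2),
        "Sr": (0.70, 3.0e-4, 1.2), "Y": (0.40, 2.5e-5, 1.0),
        "Zr": (0.50, 1.5e-4, 1.2), "Nb": (0.30, 1.2e-5, 1.0),
        "Cd": (0.25, 1.0e-6, 1.3), "In": (0.10, 2.0e-7, 1.0),
        "Sn": (0.30, 3.0e-6, 1.2), "Sb": (0.25, 1.0e-6, 1.2),
        "Te": (0.08, 2.0e-7, 1.0), "I": (0.12, 2.0e-6, 1.2),
        "Cs": (0.35, 4.0e-6, 1.2), "Ba": (0.65, 4.0e-4, 1.2),
        "La": (0.45, 3.0e-5, 1.1), "Ce": (0.45, 6.0e-5, 1.1),
        "Pr": (0.30, 7.0e-6, 1.0), "Nd": (0.40, 2.5e-5, 1.1),
        "Sm": (0.35, 5.0e-6, 1.0), "Eu": (0.30, 1.2e-6, 1.0),
        "Gd": (0.30, 5.0e-6, 1.0), "Tb": (0.25, 8.0e-7, 1.0),
        "Dy": (0.28, 4.0e-6, 1.0), "Ho": (0.22, 9.0e-7, 1.0),
        "Er": (0.25, 2.5e-6, 1.0), "Tm": (0.18, 4.0e-7, 1.0),
        "Yb": (0.25, 2.5e-6, 1.0), "Lu": (0.18, 4.0e-7, 1.0),
        "Hf": (0.30, 4.0e-6, 1.1), "Ta": (0.20, 8.0e-7, 1.0),
        "W": (0.25, 2.0e-6, 1.2), "Pt": (0.06, 1.0e-7, 1.0),
        "Au": (0.08, 1.0e-7, 1.2), "Hg": (0.15, 5.0e-7, 1.3),
        "Tl": (0.12, 5.0e-7, 1.0), "Pb": (0.55, 5.0e-5, 1.3),
        "Bi": (0.15, 4.0e-7, 1.1),
    }
    rates, mus, sigmas = [], [], []
    for z in TARGET_ELEMENTS:
        rate, median, sigma = spec[physics.symbol(z)]
        rates.append(rate)
        mus.append(np.log(median))
        sigmas.append(sigma)
    return OccurrenceTable(TARGET_ELEMENTS, np.array(rates), np.array(mus), np.array(sigmas))


def build_occurrence_table(
    reference_compositions: Iterable[Composition],
    elements: Sequence[int] = TARGET_ELEMENTS,
    sigma_floor: float = 1e-6,
) -> OccurrenceTable:
    """Estimate occurrence rates and log-normal parameters from a set of
    reference compositions (the procedure applied to CRM compilations).

    Rate is the fraction of references containing the element; mu/sigma
    are the mean and std of ln(w) over the nonzero occurrences, with
    ``sigma_floor`` guarding degenerate (constant or single-occurrence)
    fits.  Absent elements get rate 0 and unused placeholder parameters.
    """
    refs = list(reference_compositions)
    if len(refs) < 2:
        raise ValueError("need at least two reference compositions")
    rates, mus, sigmas = [], [], []
    for z in elements:
        ws = np.array([r.fraction(z) for r in refs])
        nz = ws[ws > 0]
        rates.append(len(nz) / len(refs))
        if len(nz) == 0:
            mus.append(np.log(sigma_floor))
            sigmas.append(sigma_floor)
        else:
            logs = np.log(nz)
            mus.append(logs.mean())
            sigmas.append(max(logs.std(ddof=0), sigma_floor))
    return OccurrenceTable(tuple(elements), np.array(rates), np.array(mus), np.array(sigmas))


def draw_density(
    rng: np.random.Generator | int,
    lo: float = DENSITY_RANGE[0],
    hi: float = DENSITY_RANGE[1],
) -> float:
    """Uniform density draw in [lo, hi] g/cm^3 (defaults 0.5-3.5)."""
    if not (0 < lo <= hi):
        raise ValueError("invalid density range")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    return float(rng.uniform(lo, hi)) if lo < hi else float(lo)


def draw_composition(
    table: OccurrenceTable,
    rng: np.random.Generator | int,
    density_range: tuple[float, float] = DENSITY_RANGE,
    cap: float = DETECTABLE_CAP,
) -> Composition:
    """Draw one synthetic composition.

    Presence of each element is Bernoulli(rate); present elements draw
    their mass fraction from the configured log-normal.  If the summed
    detectable fractions exceed ``cap`` they are rescaled proportionally,
    keeping the sample inside the dark-matrix-dominated regime.  The
    remainder is dark matrix.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    present = rng.random(len(table.elements)) < table.rate
    draws = np.exp(rng.normal(table.lognorm_mu, table.lognorm_sigma))
    w = np.where(present, draws, 0.0)
    total = w.sum()
    if total > cap:
        w *= cap / total
    fractions = {z: float(wi) for z, wi in zip(table.elements, w) if wi > 0}
    density = draw_density(rng, *density_range)
    return Composition(fractions, density)


def draw_batch(
    n: int,
    table: OccurrenceTable | None = None,
    seed: int = 0,
    density_range: tuple[float, float] = DENSITY_RANGE,
    cap: float = DETECTABLE_CAP,
) -> list[Composition]:
    """Draw ``n`` compositions from one seeded generator (deterministic
    stream: identical seed, identical batch)."""
    table = table or default_occurrence_table()
    rng = np.random.default_rng(seed)
    return [draw_composition(table, rng, density_range, cap) for _ in range(n)]


def save_compositions(comps: Sequence[Composition], path) -> None:
    """JSON-lines export: one object per sample."""
    with open(path, "w") as fh:
        for c in comps:
            fh.write(
                json.dumps(
                    {
                        "mass_fractions": {str(z): w for z, w in c.mass_fractions.items()},
                        "density": c.density,
                        "dark_matrix_fraction": c.dark_matrix_fraction,
                    }
                )
                + "\n"
            )


def load_compositions(path) -> list[Composition]:
    out = []
    with open(path) as fh:
        for line in fh:
            d = json.loads(line)
            out.append(
                Composition(
                    {int(z): float(w) for z, w in d["mass_fractions"].items()},
                    d["density"],
                    d.get("dark_matrix_fraction"),
                )
            )
    return out
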