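"""Synthetic training-set generation.

One training example is one depth profile of one synthetic sample:
composition and density are drawn from the occurrence model, the MXRF
spectrum is produced by the fundamental-parameter forward model, the
setup calibration is randomized per profile, the surface position is
drawn uniformly so the rise is always inside the scan, and the confocal
transformation yields the (depth x energy) expected-count matrix.

Profiles are stored as *expected counts* on a cropped, energy-binned
grid (the network input grid); Poisson noise is applied per epoch during
training, not here, so each epoch sees a fresh noise realization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import confocal, forward, samples

__all__ = ["GeneratorConfig", "ProfileDataset", "bin_profile", "generate_dataset"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for synthetic data generation."""

    e_crop: tuple[float, float] = (2.0, 26.0)  # keV window kept for the model
    bin_factor: int = 8  # detector channels per model bin (20 eV -> 160 eV)
    x0_range: tuple[float, float] = (25.0, 125.0)  # um, surface placement
    calibration_spread: float = 0.2  # +-20% uniform randomization
    photons: float = 2.0e7  # tube photons per depth step (exposure unit)
    scatter_scale: float = 1.0
    flat_floor: float = 0.0
    density_range: tuple[float, float] = samples.DENSITY_RANGE

    def model_energy_grid(self) -> np.ndarray:
        grid = forward.default_energy_grid()
        m = (grid >= self.e_crop[0]) & (grid < self.e_crop[1])
        kept = grid[m]
        n = (len(kept) // self.bin_factor) * self.bin_factor
        return kept[:n].reshape(-1, self.bin_factor).mean(axis=1)


@dataclass
class ProfileDataset:
    """Expected-count profiles plus the 55-entry regression labels."""

    X: np.ndarray  # (n, n_depth, n_bins) float32, expected counts
    Y: np.ndarray  # (n, 55): 53 mass fractions, density, x0
    elements: tuple[int, ...]
    depth_grid: np.ndarray
    energy_grid: np.ndarray  # binned model grid, keV
    config: GeneratorConfig

    def __len__(self) -> int:
        return len(self.X)


def bin_profile(
    intensity: np.ndarray, energy_grid: np.ndarray, config: GeneratorConfig
) -> np.ndarray:
    """Crop a (n_depth, n_channels) profile to the model window and sum
    adjacent channels into bins (count-preserving within the window)."""
    m = (energy_grid >= config.e_crop[0]) & (energy_grid < config.e_crop[1])
    kept = intensity[:, m]
    n = (kept.shape[1] // config.bin_factor) * config.bin_factor
    return kept[:, :n].reshape(kept.shape[0], -1, config.bin_factor).sum(axis=2)


def generate_dataset(
    n: int,
    seed: int = 0,
    table: samples.OccurrenceTable | None = None,
    config: GeneratorConfig | None = None,
    progress: bool = False,
) -> ProfileDataset:
    """Generate ``n`` (profile, label) pairs; deterministic in ``seed``."""
    table = table or samples.default_occurrence_table()
    if len(table.elements) != 53:
        raise ValueError("occurrence table must cover the 53 target elements")
    config = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    exc = forward.tube_spectrum(photons=config.photons)
    ranges = confocal.CalibrationRanges.relative(spread=config.calibration_spread)
    depth_grid = confocal.default_depth_grid()
    model_grid = config.model_energy_grid()

    X = np.empty((n, len(depth_grid), len(model_grid)), dtype=np.float32)
    Y = np.empty((n, 55), dtype=np.float64)
    for i in range(n):
        comp = samples.draw_composition(table, rng, config.density_range)
        spec = forward.simulate_mxrf(
            comp, exc, scatter_scale=config.scatter_scale, flat_floor=config.flat_floor
        )
        cal = confocal.randomize_calibration(ranges, rng)
        x0 = float(rng.uniform(*config.x0_range))
        prof = confocal.transform(spec, comp, cal, x0, depth_grid)
        X[i] = bin_profile(prof.intensity, prof.energy_grid, config)
        Y[i, :53] = comp.as_vector(table.elements)
        Y[i, 53] = comp.density
        Y[i, 54] = x0
        if progress and (i + 1) % 500 == 0:
            print(f"  generated {i + 1}/{n} profiles")
    return ProfileDataset(X, Y, tuple(table.elements), depth_grid, model_grid, config)
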