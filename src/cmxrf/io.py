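"""HDF5 / CSV persistence for spectra and depth profiles.

Depth-profile HDF5 layout (one group per profile, or the file root for a
single profile):

    /depth_grid   (n_steps,)   um
    /energy_grid  (n_channels,) keV
    /intensity    (n_steps, n_channels)
    attrs: x0 (um), label, calibration (JSON of the six parameters
    + geometry), plus any provenance metadata passed by the caller.

The CSV fallback for measured-profile ingestion is a long-format table
with columns ``depth_um, energy_keV, counts`` on a complete rectangular
grid, so third-party instrument exports can be adapted with a one-line
reshape.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .confocal import DepthProfile, SetupCalibration
from .forward import MXRFSpectrum

__all__ = [
    "save_profile",
    "load_profile",
    "save_profiles",
    "load_profiles",
    "save_spectra",
    "load_spectra",
    "profile_from_csv",
    "profile_to_csv",
]


def _write_profile(g: h5py.Group, p: DepthProfile, metadata: dict | None = None) -> None:
    g.create_dataset("depth_grid", data=p.depth_grid)
    g.create_dataset("energy_grid", data=p.energy_grid)
    g.create_dataset("intensity", data=p.intensity)
    g.attrs["x0"] = p.x0
    g.attrs["label"] = p.label
    g.attrs["calibration"] = json.dumps(dataclasses.asdict(p.calibration))
    for k, v in (metadata or {}).items():
        g.attrs[k] = v


def _read_profile(g: h5py.Group) -> DepthProfile:
    cal = SetupCalibration(**json.loads(g.attrs["calibration"]))
    return DepthProfile(
        g["depth_grid"][()],
        g["energy_grid"][()],
        g["intensity"][()],
        float(g.attrs["x0"]),
        cal,
        str(g.attrs.get("label", "")),
    )


def save_profile(path, profile: DepthProfile, metadata: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        _write_profile(f, profile, metadata)


def load_profile(path) -> DepthProfile:
    with h5py.File(path, "r") as f:
        return _read_profile(f)


def save_profiles(path, profiles: Sequence[DepthProfile], metadata: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        for k, v in (metadata or {}).items():
            f.attrs[k] = v
        for i, p in enumerate(profiles):
            _write_profile(f.create_group(f"profile_{i:06d}"), p)


def load_profiles(path) -> list[DepthProfile]:
    out = []
    with h5py.File(path, "r") as f:
        for name in sorted(k for k in f.keys() if k.startswith("profile_")):
            out.append(_read_profile(f[name]))
    return out


def save_spectra(path, spectra: Sequence[MXRFSpectrum], metadata: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        for k, v in (metadata or {}).items():
            f.attrs[k] = v
        f.create_dataset("energy_grid", data=spectra[0].energy_grid)
        f.create_dataset(
            "intensity", data=np.stack([s.intensity for s in spectra])
        )
        f.create_dataset(
            "composition_ref",
            data=np.array([s.composition_ref for s in spectra], dtype=h5py.string_dtype()),
        )


def load_spectra(path) -> list[MXRFSpectrum]:
    with h5py.File(path, "r") as f:
        grid = f["energy_grid"][()]
        intens = f["intensity"][()]
        refs = [r.decode() if isinstance(r, bytes) else str(r) for r in f["composition_ref"][()]]
    return [MXRFSpectrum(grid, i, r) for i, r in zip(intens, refs)]


def profile_to_csv(path, profile: DepthProfile) -> None:
    d, e = np.meshgrid(profile.depth_grid, profile.energy_grid, indexing="ij")
    pd.DataFrame(
        {
            "depth_um": d.ravel(),
            "energy_keV": e.ravel(),
            "counts": profile.intensity.ravel(),
        }
    ).to_csv(path, index=False)


def profile_from_csv(
    path, x0: float = np.nan, calibration: SetupCalibration | None = None, label: str = ""
) -> DepthProfile:
    """Ingest a measured depth profile from the documented long-format
    CSV (depth_um, energy_keV, counts on a rectangular grid)."""
    df = pd.read_csv(path)
    depths = np.unique(df["depth_um"].to_numpy())
    energies = np.unique(df["energy_keV"].to_numpy())
    pivot = df.pivot_table(index="depth_um", columns="energy_keV", values="counts")
    intensity = pivot.reindex(index=depths, columns=energies).to_numpy()
    if np.any(~np.isfinite(intensity)):
        raise ValueError("CSV profile is not a complete rectangular grid")
    return DepthProfile(
        depths, energies, intensity, x0, calibration or SetupCalibration(), label
    )
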