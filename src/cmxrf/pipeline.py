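"""End-to-end pipeline: samples -> spectra -> profiles -> train -> predict -> evaluate.

A single YAML-serializable configuration drives every stage; the SHA-256
hash of the canonical config is embedded in each artifact so mismatched
artifacts can be detected.  Identical config + seed reproduces identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import datasets, evaluation, model as model_mod, samples
from .datasets import GeneratorConfig
from .model import ModelConfig

__all__ = ["PipelineConfig", "run_pipeline", "config_hash"]


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "cmxrf_run"
    n_train: int = 5000
    n_val: int = 500
    occurrence_table: str | None = None  # CSV path; bundled default if None
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    density_tolerance: float = 0.30
    x0_tolerance_um: float = 10.0
    verbose: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        gen = raw.pop("generator", {})
        mod = raw.pop("model", {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for d, c in ((gen, GeneratorConfig), (mod, ModelConfig)):
            bad = set(d) - {f.name for f in dataclasses.fields(c)}
            if bad:
                raise ValueError(f"unknown {c.__name__} keys: {sorted(bad)}")
        for k in ("e_crop", "x0_range", "density_range"):
            if k in gen:
                gen[k] = tuple(gen[k])
        for k in ("input_shape", "conv_channels", "pool_after", "feature_shape", "mlp_widths"):
            if k in mod:
                mod[k] = tuple(mod[k])
        return cls(generator=GeneratorConfig(**gen), model=ModelConfig(**mod), **raw)

    def to_dict(self) -> dict:
        def listify(obj):
            if isinstance(obj, tuple):
                return [listify(v) for v in obj]
            if isinstance(obj, dict):
                return {k: listify(v) for k, v in obj.items()}
            return obj

        return listify(dataclasses.asdict(self))


def config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all stages, writing artifacts (with provenance metadata) into
    ``config.outdir``; returns the output directory path."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    log = _StageLogger(config.verbose)

    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump({**config.to_dict(), "config_hash": chash}, fh)

    table = (
        samples.OccurrenceTable.from_csv(config.occurrence_table)
        if config.occurrence_table
        else samples.default_occurrence_table()
    )

    with log.stage("simulate (train)"):
        train_cfg = dataclasses.replace(config.model, seed=config.seed)
        ds = datasets.generate_dataset(
            config.n_train, seed=config.seed, table=table, config=config.generator
        )
    with log.stage("simulate (validation)"):
        val = datasets.generate_dataset(
            config.n_val, seed=config.seed + 1, table=table, config=config.generator
        )
        _save_truth(out / "validation_truth.jsonl", val)

    with log.stage("train"):
        m = model_mod.build_model(train_cfg, config.generator)
        model_mod.train(m, ds, val, verbose=config.verbose)
        m.save(out / "model.npz")
        pd.DataFrame(m.training_log).assign(config_hash=chash).to_csv(
            out / "training_log.csv", index=False
        )

    with log.stage("predict"):
        rng = np.random.default_rng(config.seed + 2)
        noisy = rng.poisson(val.X.astype(np.float64)).astype(np.float64)
        preds = model_mod.predict(m, noisy)
        _save_predictions(out / "predictions.csv", preds, chash)

    with log.stage("evaluate"):
        truths = [_truth_composition(val, i) for i in range(len(val))]
        report = evaluation.build_report(
            preds,
            truths,
            x0_true=[float(val.Y[i, 54]) for i in range(len(val))],
            density_tolerance=config.density_tolerance,
            x0_tolerance_um=config.x0_tolerance_um,
        )
        report.summary["config_hash"] = chash
        report.save(str(out / "report"))

    return out


def _truth_composition(ds: datasets.ProfileDataset, i: int) -> samples.Composition:
    fr = {z: float(w) for z, w in zip(ds.elements, ds.Y[i, :53]) if w > 0}
    return samples.Composition(fr, float(ds.Y[i, 53]))


def _save_truth(path, ds: datasets.ProfileDataset) -> None:
    comps = [_truth_composition(ds, i) for i in range(len(ds))]
    samples.save_compositions(comps, path)


def _save_predictions(path, preds, chash: str) -> None:
    from . import physics

    rows = []
    for i, p in enumerate(preds):
        row = {"profile": i}
        row.update(
            {physics.symbol(z): w for z, w in zip(p.elements, p.concentrations)}
        )
        row["density_g_cm3"] = p.density
        row["x0_um"] = p.x0
        rows.append(row)
    pd.DataFrame(rows).assign(config_hash=chash).to_csv(path, index=False)


class _StageLogger:
    def __init__(self, verbose: bool) -> None:
        self.verbose = verbose

    def stage(self, name: str):
        return _Stage(name, self.verbose)


class _Stage:
    def __init__(self, name: str, verbose: bool) -> None:
        self.name, self.verbose = name, verbose

    def __enter__(self):
        self.t0 = time.time()
        if self.verbose:
            print(f"[cmxrf] stage {self.name} ...", flush=True)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.time() - self.t0
        if exc_type is not None:
            print(f"[cmxrf] stage {self.name} FAILED after {dt:.1f} s: {exc}", flush=True)
            return False
        if self.verbose:
            print(f"[cmxrf] stage {self.name} done in {dt:.1f} s", flush=True)
        return False
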