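"""Configuration schema, dataset loaders, and run manifests.

A single YAML configuration drives every command: blocks ``model``,
``smoothing``, ``simulation``, ``optimizer`` and ``output``.  CLI flags can
override any leaf.  Every run writes a manifest (config copy, seeds,
package version, wall-clock) so results are reproducible from the run
directory alone.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dga_core import DGAConfig, SmoothingParams
from .inference import MomentTargets
from .promoters import FourStateParams, TwoStateParams


class ConfigError(ValueError):
    pass


_DEFAULTS = {
    "model": {"kind": "two_state"},
    "smoothing": {"one_over_a": 200.0, "one_over_b": 20.0},
    "simulation": {"n_traj": 2000, "T": 1e4, "max_steps": 1_000_000, "seed": 0},
    "optimizer": {"n_iter": 300, "lr": 0.05, "lr_decay": 0.01},
    "output": {"dir": "runs"},
}


def load_config(path=None, overrides: dict | None = None) -> dict:
    cfg = {k: dict(v) for k, v in _DEFAULTS.items()}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for block, vals in user.items():
            if block not in cfg:
                cfg[block] = {}
            if not isinstance(vals, dict):
                raise ConfigError(f"config block {block!r} must be a mapping")
            cfg[block].update(vals)
    for dotted, v in (overrides or {}).items():
        block, _, leaf = dotted.partition(".")
        if not leaf:
            raise ConfigError(f"override {dotted!r} must be 'block.leaf'")
        cfg.setdefault(block, {})[leaf] = v
    _validate(cfg)
    return cfg


def _validate(cfg: dict) -> None:
    sim = cfg["simulation"]
    if int(sim["n_traj"]) < 1:
        raise ConfigError("simulation.n_traj must be >= 1")
    if float(sim["T"]) <= 0:
        raise ConfigError("simulation.T must be positive")
    sm = cfg["smoothing"]
    if float(sm["one_over_a"]) <= 0 or float(sm["one_over_b"]) <= 0:
        raise ConfigError("smoothing parameters must be positive")


def smoothing_from_config(cfg: dict) -> SmoothingParams:
    sm = cfg["smoothing"]
    return SmoothingParams.from_inverse(float(sm["one_over_a"]), float(sm["one_over_b"]))


def dga_config_from_config(cfg: dict) -> DGAConfig:
    sim = cfg["simulation"]
    return DGAConfig(n_traj=int(sim["n_traj"]), max_steps=int(sim["max_steps"]))


def model_from_config(cfg: dict):
    m = dict(cfg["model"])
    kind = m.pop("kind", "two_state")
    if kind == "two_state":
        keys = {"kon_r", "koff_r", "r", "gamma"}
        return TwoStateParams(**{k: float(v) for k, v in m.items() if k in keys})
    if kind == "four_state":
        return FourStateParams(**{k: float(v) for k, v in m.items()})
    raise ConfigError(f"unknown model kind {kind!r}")


def load_dataset(path) -> pd.DataFrame:
    """Load a (condition_id, mean, fano) summary CSV for multi-condition fits.

    Row order is preserved; malformed rows are reported by number.
    """
    df = pd.read_csv(path)
    required = {"condition_id", "mean", "fano"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigError(f"dataset {path} missing columns {sorted(missing)}")
    bad = df.index[(df["mean"] <= 0) | (df["fano"] <= 0)].tolist()
    if bad:
        raise ConfigError(f"dataset {path} has non-positive mean/fano in rows {bad}")
    return df


def dataset_targets(df: pd.DataFrame) -> list[MomentTargets]:
    return [
        MomentTargets.from_mean_fano(float(row["mean"]), float(row["fano"]))
        for _, row in df.iterrows()
    ]


def write_dataset(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


@dataclass
class RunDir:
    """Output directory with a reproducibility manifest."""

    path: Path

    @classmethod
    def create(cls, base, name: str) -> "RunDir":
        p = Path(base) / name
        p.mkdir(parents=True, exist_ok=True)
        return cls(p)

    def write_manifest(self, cfg: dict, seeds: dict, extra: dict | None = None):
        from . import __version__

        manifest = {
            "config": cfg,
            "seeds": seeds,
            "version": __version__,
            "wall_clock": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        manifest.update(extra or {})
        with open(self.path / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=_jsonable)
        return manifest

    def write_json(self, name: str, obj) -> Path:
        out = self.path / name
        with open(out, "w") as fh:
            json.dump(obj, fh, indent=2, default=_jsonable)
        return out

    def write_csv(self, name: str, df: pd.DataFrame) -> Path:
        out = self.path / name
        df.to_csv(out, index=False)
        return out


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")


def export_noise_record(batch, path) -> None:
    """Dump a batch's uniform draws (and seed) to HDF5 for exact replay."""
    import h5py

    if batch.noise_record is None:
        raise ValueError("batch was run without record_noise=True")
    with h5py.File(path, "w") as fh:
        fh.create_dataset("uniforms", data=batch.noise_record)
        fh.attrs["seed"] = str(batch.seed)
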