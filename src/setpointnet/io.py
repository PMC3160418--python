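"""Configuration files, trajectory tables, reports and run manifests.

Configs are YAML documents mirroring :class:`SimulationConfig`; every key
is optional (defaults are the published study conditions) and unknown
keys are rejected.  Trajectories are written as a pair of TSV tables —
a wide per-iteration table for the scalar series and a long table for
the per-tissue series — with 17 significant digits so a round trip is
bit-faithful.  A manifest JSON snapshots the fully resolved parameters
of a run so it can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .engine import (
    ConvergenceReport,
    SimulationConfig,
    Trajectory,
    check_calibration,
)
from .physiology import PhysiologyParams
from .plasticity import LearningParams

__all__ = [
    "load_config",
    "config_to_dict",
    "config_from_dict",
    "write_config",
    "write_trajectory",
    "read_trajectory",
    "write_report",
    "write_manifest",
    "load_manifest_config",
]

_SCALAR_COLUMNS = ("arterial_po2", "arterial_pco2", "mixed_po2v",
                   "mixed_pco2v", "C_instant", "C_delayed", "alpha", "beta")
_TISSUE_COLUMNS = ("E", "F", "po2v", "pco2v", "Wr")
_FLOAT_FMT = "%.17g"


def _init_fields(obj) -> dict[str, Any]:
    return {f.name: getattr(obj, f.name)
            for f in dataclasses.fields(obj) if f.init}


def config_to_dict(config: SimulationConfig) -> dict[str, Any]:
    """Nested plain-python dict of every run-determining parameter."""
    out = {f.name: getattr(config, f.name)
           for f in dataclasses.fields(config)
           if f.name not in ("physiology", "learning")}
    out["physiology"] = _init_fields(config.physiology)
    out["learning"] = _init_fields(config.learning)
    return out


def _build_section(cls, data: dict[str, Any], path: str):
    known = {f.name for f in dataclasses.fields(cls) if f.init}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config key(s): "
                         + ", ".join(f"{path}.{k}" for k in sorted(unknown)))
    try:
        return cls(**data)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"invalid config section '{path}': {exc}") from exc


def config_from_dict(data: dict[str, Any]) -> SimulationConfig:
    """Build a validated config from a (possibly partial) nested dict."""
    data = dict(data or {})
    phys = _build_section(PhysiologyParams, dict(data.pop("physiology", {})),
                          "physiology")
    learn = _build_section(LearningParams, dict(data.pop("learning", {})),
                           "learning")
    top_known = {f.name for f in dataclasses.fields(SimulationConfig)
                 if f.name not in ("physiology", "learning")}
    unknown = set(data) - top_known
    if unknown:
        raise ValueError("unknown config key(s): "
                         + ", ".join(sorted(unknown)))
    try:
        config = SimulationConfig(physiology=phys, learning=learn, **data)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"invalid config: {exc}") from exc
    check_calibration(config.physiology, config.learning, strict=False)
    return config


def load_config(path: str | Path) -> SimulationConfig:
    """Load a YAML config; missing keys default to the study conditions."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping, got {type(data).__name__}")
    return config_from_dict(data)


def write_config(config: SimulationConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def write_trajectory(traj: Trajectory, out_dir: str | Path,
                     prefix: str = "trajectory") -> tuple[Path, Path]:
    """Write the wide scalar table and the long per-tissue table.

    Returns the two file paths (``<prefix>_scalars.tsv``,
    ``<prefix>_tissues.tsv``).  Iterations are numbered from 1.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    T, N = traj.n_iterations, traj.n_tissues

    scalars = pd.DataFrame({"iteration": np.arange(1, T + 1)})
    for col in _SCALAR_COLUMNS:
        scalars[col] = getattr(traj, col)
    scalar_path = out_dir / f"{prefix}_scalars.tsv"
    scalars.to_csv(scalar_path, sep="\t", index=False, float_format=_FLOAT_FMT)

    tissues = pd.DataFrame({
        "iteration": np.repeat(np.arange(1, T + 1), N),
        "tissue": np.tile(np.arange(1, N + 1), T),
    })
    for col in _TISSUE_COLUMNS:
        tissues[col] = getattr(traj, col).ravel()
    tissue_path = out_dir / f"{prefix}_tissues.tsv"
    tissues.to_csv(tissue_path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return scalar_path, tissue_path


def read_trajectory(out_dir: str | Path,
                    prefix: str = "trajectory") -> Trajectory:
    """Read back a trajectory written by :func:`write_trajectory`."""
    out_dir = Path(out_dir)
    scalars = pd.read_csv(out_dir / f"{prefix}_scalars.tsv", sep="\t",
                          float_precision="round_trip")
    tissues = pd.read_csv(out_dir / f"{prefix}_tissues.tsv", sep="\t",
                          float_precision="round_trip")
    T = len(scalars)
    N = tissues["tissue"].max()
    kwargs: dict[str, np.ndarray] = {}
    for col in _SCALAR_COLUMNS:
        kwargs[col] = scalars[col].to_numpy()
    for col in _TISSUE_COLUMNS:
        kwargs[col] = tissues[col].to_numpy().reshape(T, N)
    return Trajectory(**kwargs)


def write_report(report: ConvergenceReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(report), fh, indent=2)
        fh.write("\n")


def write_manifest(config: SimulationConfig, out_dir: str | Path,
                   paths: dict[str, str], started: datetime,
                   finished: datetime) -> Path:
    """Snapshot the resolved parameters and provenance of a run."""
    manifest = {
        "software": {"name": "setpointnet", "version": __version__},
        "config": config_to_dict(config),
        "seed": config.seed,
        "started": started.astimezone(timezone.utc).isoformat(),
        "finished": finished.astimezone(timezone.utc).isoformat(),
        "outputs": paths,
    }
    path = Path(out_dir) / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
    return path


def load_manifest_config(path: str | Path) -> SimulationConfig:
    """Rebuild the exact config of a previous run from its manifest."""
    with open(path) as fh:
        manifest = json.load(fh)
    return config_from_dict(manifest["config"])
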