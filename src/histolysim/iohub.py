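"""Configuration files, trajectory tables, and run manifests.

Trajectories are written as long-format CSV (one row per particle per
sampled step, lengths in micrometres with 4 decimals); each run directory
carries a JSON manifest with the resolved configuration, seeds, software
version, and output checksums, sufficient to reproduce the run
bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from .mechanics import ModelParams
from .scenarios import (FatMode, Heterogeneity, ScenarioConfig,
                        Stabilization, Trajectory)

__all__ = ["TRAJ_COLUMNS", "write_trajectories", "read_trajectories",
           "write_manifest", "read_manifest", "load_config", "config_to_dict"]

TRAJ_COLUMNS = ["trial", "step", "hapf", "id", "kind", "state", "host_id",
                "x_um", "y_um", "r_um", "subtype"]


def write_trajectories(trajs, path) -> Path:
    """Write one or more trials to a single long-format CSV."""
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    frames = [t.to_dataframe(trial=i) for i, t in enumerate(trajs)]
    df = pd.concat(frames, ignore_index=True)[TRAJ_COLUMNS]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.4f")
    return path


def read_trajectories(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False,
                     dtype={"state": str, "subtype": str})
    missing = set(TRAJ_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trajectory file lacks columns {sorted(missing)}")
    return df


def positions_from_table(df: pd.DataFrame, trial: int, kind: str = "muscle"):
    """(S, n, 2) position array [um] for one trial and particle kind."""
    sub = df[(df.trial == trial) & (df.kind == kind)]
    steps = np.sort(sub.step.unique())
    ids = np.sort(sub.id.unique())
    piv_x = sub.pivot(index="step", columns="id", values="x_um")
    piv_y = sub.pivot(index="step", columns="id", values="y_um")
    pos = np.stack([piv_x.loc[steps, ids].to_numpy(),
                    piv_y.loc[steps, ids].to_numpy()], axis=-1)
    return steps, ids, pos


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for block in iter(lambda: f.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def config_to_dict(config: ScenarioConfig) -> dict:
    d = dataclasses.asdict(config)
    d["fat_mode"] = config.fat_mode.value
    d["heterogeneity"] = config.heterogeneity.value
    d["stabilization"] = config.stabilization.value
    return d


def write_manifest(path, config: ScenarioConfig, seeds, outputs=()) -> Path:
    from . import __version__
    path = Path(path)
    manifest = {
        "version": __version__,
        "config": config_to_dict(config),
        "seeds": list(map(int, seeds)),
        "steps_total": config.steps_total,
        "outputs": {str(Path(p).name): _sha256(Path(p)) for p in outputs},
    }
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=2))
    return path


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())


def config_from_dict(d: dict) -> ScenarioConfig:
    params = ModelParams(**d.get("params", {}))
    kw = {k: v for k, v in d.items() if k in {
        "magnitude", "scale", "n_trials", "seed", "steps",
        "fat_r_min", "fat_r_max"}}
    return ScenarioConfig(
        fat_mode=FatMode(d.get("fat_mode", "floating")),
        heterogeneity=Heterogeneity(d.get("heterogeneity", "homog")),
        stabilization=Stabilization(d.get("stabilization", "none")),
        params=params, **kw)


def load_config(path) -> ScenarioConfig:
    """Load a scenario from TOML ([scenario] and optional [params] tables)
    or from a flat/nested JSON file."""
    path = Path(path)
    if path.suffix == ".json":
        data = json.loads(path.read_text())
    else:
        with open(path, "rb") as f:
            data = tomllib.load(f)
    flat = dict(data.get("scenario", data))
    if "params" in data:
        flat["params"] = data["params"]
    return config_from_dict(flat)
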