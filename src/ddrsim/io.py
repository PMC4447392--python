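"""Run configuration, trajectory CSV I/O and manifests.

The interchange format is RFC-4180 CSV (header row, UTF-8, '.' decimal):
one ``cell_<seed>.csv`` per trajectory with the fixed observable schema,
plus ``focus_log_<seed>.csv`` / ``break_log_<seed>.csv`` event logs and a
``manifest.json`` recording the package version, preset, protocol, seeds
and config hash so a run can be reproduced byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import __version__ as _pkg_version
from .engine import Trajectory, TrajectorySet, TRAJECTORY_COLUMNS
from .protocols import Protocol, build_protocol

__all__ = ["RunConfig", "load_config", "write_outputs", "read_trajectory",
           "read_population"]

log = logging.getLogger("ddrsim")


class RunConfig(BaseModel):
    """Validated simulation run configuration (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")

    preset: str
    parameter_overlay: Optional[dict[str, float]] = None
    protocol: dict = Field(default_factory=dict)
    duration_h: float = 30.0
    n: int = 1
    seed: int = 0
    sample_every_min: float = 5.0
    out_dir: str = "."
    log_level: str = "INFO"

    @field_validator("n")
    @classmethod
    def _n_pos(cls, v: int) -> int:
        if v < 1:
            raise ValueError("n must be >= 1")
        return v

    @field_validator("duration_h")
    @classmethod
    def _dur_pos(cls, v: float) -> float:
        if v < 0:
            raise ValueError("duration must be >= 0")
        return v

    def build_protocol(self) -> Protocol:
        return build_protocol(self.protocol)

    @property
    def duration_min(self) -> float:
        return self.duration_h * 60.0

    def digest(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML run configuration."""
    doc = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig(**doc)


def _traj_frame(tr: Trajectory) -> pd.DataFrame:
    return pd.DataFrame(tr.data, columns=list(TRAJECTORY_COLUMNS))


def write_outputs(
    trajectories: TrajectorySet | None,
    out_dir: str | Path,
    config: RunConfig | None = None,
    tables: dict[str, pd.DataFrame] | None = None,
) -> Path:
    """Write trajectory CSVs and/or analysis tables plus a manifest.

    Returns the manifest path.  Re-running with the same config and seeds
    reproduces byte-identical CSVs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"package_version": _pkg_version}
    if config is not None:
        manifest["config"] = config.model_dump()
        manifest["config_hash"] = config.digest()
    if trajectories is not None and len(trajectories) == 0:
        log.warning("empty trajectory set; writing manifest only")
    if trajectories is not None and len(trajectories) > 0:
        manifest["preset"] = trajectories.preset
        manifest["protocol"] = {
            "label": trajectories.protocol.label,
            "irradiation": [
                {"t_min": e.time_min, "gy": e.dose_gy}
                for e in trajectories.protocol.irradiation
            ],
            "ros_multiplier": trajectories.protocol.ros_multiplier,
        }
        manifest["base_seed"] = trajectories.base_seed
        manifest["seeds"] = trajectories.seeds
        for tr in trajectories:
            _traj_frame(tr).to_csv(out / f"cell_{tr.seed}.csv", index=False)
            pd.DataFrame(
                tr.focus_episodes, columns=["site", "t_form", "t_res"]
            ).to_csv(out / f"focus_log_{tr.seed}.csv", index=False)
            pd.DataFrame(
                tr.break_episodes, columns=["site", "t_break", "t_ligate", "type"]
            ).to_csv(out / f"break_log_{tr.seed}.csv", index=False)
    if tables:
        manifest["tables"] = sorted(tables)
        for name, df in tables.items():
            df.to_csv(out / f"{name}.csv", index=False)
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest_path


def read_trajectory(out_dir: str | Path, seed: int) -> Trajectory:
    """Load one cell written by :func:`write_outputs`."""
    out = Path(out_dir)
    data = pd.read_csv(out / f"cell_{seed}.csv")
    focus = pd.read_csv(out / f"focus_log_{seed}.csv")
    breaks = pd.read_csv(out / f"break_log_{seed}.csv")
    sen_state = data["sen_state"].to_numpy()
    if sen_state[-1] >= 1:
        switch = float(data["time_min"][np.argmax(sen_state >= 1)])
    else:
        switch = float("nan")
    return Trajectory(
        data=data[list(TRAJECTORY_COLUMNS)].to_numpy(dtype=float),
        focus_episodes=focus.to_numpy(dtype=float).reshape(-1, 3),
        break_episodes=breaks.to_numpy(dtype=float).reshape(-1, 4),
        sen_switch_time=switch,
        seed=seed,
        protocol=Protocol(),
        sample_every=float(np.median(np.diff(data["time_min"])))
        if len(data) > 1 else 5.0,
    )


def read_population(out_dir: str | Path) -> TrajectorySet:
    """Load a population from a manifest directory."""
    out = Path(out_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    trs = tuple(read_trajectory(out, s) for s in manifest.get("seeds", []))
    return TrajectorySet(
        trajectories=trs,
        protocol=Protocol(),
        base_seed=manifest.get("base_seed", 0),
        preset=manifest.get("preset", ""),
    )
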