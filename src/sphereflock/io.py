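"""Trajectory and configuration serialization.

Two trajectory formats: a tidy columnar CSV (one row per recorded agent
step) for interchange, and an NPZ array container carrying the full
parameter set for lossless round-trips.  Simulation parameters mirror
:class:`~sphereflock.simulator.SimParams` field for field in a flat YAML
mapping.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulator import SimParams, SwarmState, Trajectory

__all__ = [
    "trajectory_to_csv",
    "trajectory_to_npz",
    "trajectory_from_npz",
    "load_params",
    "save_params",
]


def trajectory_to_csv(traj: Trajectory, path: str | Path) -> None:
    """Write recorded states as tidy CSV: step, agent, position, heading,
    speed, and the polarization magnitude that produced the state."""
    frames = []
    for st in traj.states:
        zn = st.zeta_norms if st.zeta_norms is not None else np.full(st.n, np.nan)
        frames.append(
            pd.DataFrame(
                {
                    "step": st.step,
                    "agent": np.arange(st.n),
                    "x": st.positions[:, 0],
                    "y": st.positions[:, 1],
                    "z": st.positions[:, 2],
                    "dx": st.directions[:, 0],
                    "dy": st.directions[:, 1],
                    "dz": st.directions[:, 2],
                    "v": st.speeds,
                    "zeta_norm": zn,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def trajectory_to_npz(traj: Trajectory, path: str | Path) -> None:
    """Lossless binary container: stacked state arrays plus a JSON
    parameter block (including the seed, so the run can be replayed)."""
    steps = np.array([st.step for st in traj.states])
    np.savez_compressed(
        path,
        steps=steps,
        positions=np.stack([st.positions for st in traj.states]),
        directions=np.stack([st.directions for st in traj.states]),
        speeds=np.stack([st.speeds for st in traj.states]),
        zeta_norms=traj.zeta_norms if traj.zeta_norms is not None else np.empty((0, 0)),
        params_json=np.array(json.dumps(dataclasses.asdict(traj.params))),
    )


def trajectory_from_npz(path: str | Path) -> Trajectory:
    with np.load(path, allow_pickle=False) as data:
        params = SimParams(**json.loads(str(data["params_json"])))
        zn_all = data["zeta_norms"]
        states = []
        for idx, k in enumerate(data["steps"]):
            k = int(k)
            states.append(
                SwarmState(
                    step=k,
                    positions=data["positions"][idx],
                    directions=data["directions"][idx],
                    speeds=data["speeds"][idx],
                    zeta_norms=zn_all[k - 1] if k > 0 and zn_all.size else None,
                )
            )
        zn = zn_all if zn_all.size else None
    return Trajectory(params=params, states=states, zeta_norms=zn)


def save_params(params: SimParams, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(params), sort_keys=False))


def load_params(path: str | Path, **overrides) -> SimParams:
    """Read a flat YAML mapping of simulation parameters; keyword
    overrides (e.g. from CLI flags) take precedence over file values."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - {f.name for f in dataclasses.fields(SimParams)}
    if unknown:
        raise ValueError(f"unknown parameter(s) in {path}: {sorted(unknown)}")
    raw.update({k: v for k, v in overrides.items() if v is not None})
    return SimParams(**raw)
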