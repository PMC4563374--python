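"""Evolution runs and statistical parameter sweeps.

The phase-transition phenomenology lives in terminal-step statistics:
run the simulator over a grid of parameter values (noise, interaction
radius, speed, agent count, speed exponent), repeat each grid point over
replicates with independent random initial configurations and noise
streams, and read the order parameters and scale measures at the terminal
step.  The location ``r_p`` of the maximum of the replicate-averaged
``phi_m`` versus interaction radius marks the transition from ordered
fragments to cohesive motion.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import sys
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .observables import (
    agent_scale_series,
    compute_series,
    local_density,
    manifold_centroid,
    phi,
    phi_m,
    phi_zeta,
    rotation_axis,
    scale_measures,
)
from .simulator import SimParams, SwarmState, Trajectory, run

__all__ = [
    "SweepSpec",
    "SweepResult",
    "replicate_seed",
    "terminal_observables",
    "run_evolution",
    "run_sweep",
    "detect_peak",
]

GRID_FIELDS = ("eta", "r0", "v0", "n", "alpha")


@dataclass(frozen=True)
class SweepSpec:
    """Grid definition for a sweep.

    ``grid`` maps parameter names (any subset of eta, r0, v0, n, alpha) to
    value lists; the sweep runs their Cartesian product.  Each grid point
    is repeated ``replicates`` times with seeds derived from ``base.seed``,
    re-randomizing both initial configurations and noise streams, and
    observables are read at ``terminal_step``.
    """

    base: SimParams
    grid: dict[str, list] = field(default_factory=dict)
    replicates: int = 40
    terminal_step: int = 600

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        unknown = set(self.grid) - set(GRID_FIELDS)
        if unknown:
            raise ValueError(f"cannot sweep over {sorted(unknown)}; allowed: {GRID_FIELDS}")

    def points(self) -> list[dict]:
        names = [f for f in GRID_FIELDS if f in self.grid]
        return [dict(zip(names, combo)) for combo in itertools.product(*(self.grid[n] for n in names))]


@dataclass(frozen=True)
class SweepResult:
    """Tidy per-run table and replicate-aggregated summary.

    ``table`` has one row per (grid point, replicate) with terminal-step
    observables; ``summary`` carries the replicate mean and standard
    deviation per grid point.  Failed runs appear in ``errors``.
    """

    spec: SweepSpec
    table: pd.DataFrame
    summary: pd.DataFrame
    errors: pd.DataFrame


def replicate_seed(base_seed: int, grid_index: int, rep: int) -> int:
    """Deterministic per-run seed decoupling grid cells and replicates."""
    ss = np.random.SeedSequence([int(base_seed), int(grid_index), int(rep)])
    return int(ss.generate_state(1)[0] % 2**31)


def terminal_observables(state: SwarmState, params: SimParams) -> dict:
    """Scalar observables of one state: order parameters, scales, density."""
    cfg = params.sphere
    m, pm = phi_m(state.positions, state.directions, cfg)
    centroid = manifold_centroid(state.positions, cfg)
    omega = rotation_axis(m)
    sc = scale_measures(state.positions, centroid, omega, cfg)
    _, rho_bar = local_density(state.positions, params.r0, cfg)
    pz = phi_zeta(state.zeta_norms) if state.zeta_norms is not None else float("nan")
    return {
        "phi": phi(state.directions),
        "phi_m": pm,
        "phi_zeta": pz,
        "c": sc.c,
        "e": sc.e,
        "rho_bar": rho_bar,
    }


def run_evolution(
    params: SimParams,
    out_dir: str | Path,
    record_agents: list[int] | None = None,
    record_every: int = 1,
) -> Trajectory:
    """Single evolution run with full observable recording.

    Writes ``observables.csv`` (per-step scalars), ``trajectory.npz``
    (lossless replayable container), ``params.json`` (snapshot), and —
    when ``record_agents`` is non-empty — ``agents.csv`` with per-agent
    distance-to-centroid and distance-to-principal-plane series.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    traj = run(params, record_every=record_every)
    compute_series(traj).to_csv(out / "observables.csv", index=False)
    from .io import trajectory_to_npz  # local import to avoid cycle

    trajectory_to_npz(traj, out / "trajectory.npz")
    (out / "params.json").write_text(json.dumps(dataclasses.asdict(params), indent=2))
    if record_agents:
        agent_scale_series(traj, record_agents).to_csv(out / "agents.csv", index=False)
    return traj


def run_sweep(spec: SweepSpec, progress: bool = False) -> SweepResult:
    """Execute all grid points x replicates and aggregate terminal stats.

    Runs are seeded independently via :func:`replicate_seed`, so results do
    not depend on execution order; a fixed spec reproduces the tables bit
    for bit.  Per-run failures are recorded and the sweep continues.
    """
    rows: list[dict] = []
    errors: list[dict] = []
    points = spec.points()
    for gi, point in enumerate(points):
        for rep in range(spec.replicates):
            seed = replicate_seed(spec.base.seed, gi, rep)
            try:
                params = replace(spec.base, **point, seed=seed, steps=spec.terminal_step)
                traj = run(params, record_every=max(1, spec.terminal_step))
                obs = terminal_observables(traj.final, params)
            except Exception as exc:  # noqa: BLE001 — sweep must survive bad cells
                errors.append({**point, "replicate": rep, "seed": seed, "error": repr(exc)})
                continue
            rows.append({**point, "replicate": rep, "seed": seed, **obs})
            if progress:
                print(
                    f"[sweep] point {gi + 1}/{len(points)} {point} rep {rep + 1}/{spec.replicates}",
                    file=sys.stderr,
                )
    table = pd.DataFrame(rows)
    keys = [f for f in GRID_FIELDS if f in spec.grid]
    if len(table) and keys:
        summary = (
            table.groupby(keys, sort=True)[["phi", "phi_m", "phi_zeta", "c", "e", "rho_bar"]]
            .agg(["mean", "std"])
            .reset_index()
        )
        summary.columns = ["_".join(c).rstrip("_") for c in summary.columns]
    else:
        summary = table.copy()
    return SweepResult(spec=spec, table=table, summary=summary, errors=pd.DataFrame(errors))


def detect_peak(
    r0_values: np.ndarray, mean_phi_m: np.ndarray, refine: bool = False
) -> tuple[float, bool]:
    """Interaction radius at which the replicate-mean ``phi_m`` peaks.

    Returns ``(r_p, at_boundary)``.  Ties break toward the smaller radius;
    a peak on the grid boundary (monotone curve) is flagged.  With
    ``refine=True`` an interior peak is sharpened by fitting a parabola
    through the peak and its two neighbors.
    """
    r0_values = np.asarray(r0_values, dtype=float)
    mean_phi_m = np.asarray(mean_phi_m, dtype=float)
    if len(r0_values) < 3:
        raise ValueError("need at least three grid points to locate a peak")
    order = np.argsort(r0_values)
    r0s, ys = r0_values[order], mean_phi_m[order]
    i = int(np.argmax(ys))  # argmax takes the first (smallest r0) on ties
    at_boundary = i in (0, len(r0s) - 1)
    r_p = float(r0s[i])
    if refine and not at_boundary:
        x = r0s[i - 1 : i + 2]
        y = ys[i - 1 : i + 2]
        a, b, _ = np.polyfit(x, y, 2)
        if a < 0:
            r_p = float(np.clip(-b / (2 * a), x[0], x[2]))
    return r_p, at_boundary
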