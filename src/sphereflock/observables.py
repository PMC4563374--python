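"""Order parameters, centroids, rotation axis, and scale measures.

Three order parameters characterize emergence on the sphere:

* ``phi`` — norm of the mean heading, the conventional Euclidean polar order
  parameter.  On a sphere it only approaches 1 when the swarm collapses to
  a small patch, so it under-reports global order.
* ``phi_m`` — norm of the mean specific angular momentum ``(p x d)/r``;
  equals 1 exactly when all agents circulate on one common great circle.
* ``phi_zeta`` — mean local polarization ``|zeta_i|``; for speed exponent
  ``alpha = 1`` it coincides with the mean speed divided by ``v0``.

Spatial scale is measured by ``c`` (mean geodesic distance to the
manifold centroid, the radial projection of the mean position) and ``e``
(mean Euclidean distance to the principal plane, the plane through the
center perpendicular to the rotation axis ``omega = m/|m|``).  Both
centroid and axis are undefined for degenerate (balanced) configurations;
degeneracy is reported explicitly rather than as silent NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import SphereConfig, great_circle_distance
from .rules import neighbor_sets
from .simulator import Trajectory

__all__ = [
    "phi",
    "phi_m",
    "phi_zeta",
    "manifold_centroid",
    "rotation_axis",
    "scale_measures",
    "local_density",
    "ScaleMeasures",
    "compute_series",
    "agent_scale_series",
]


def phi(directions: np.ndarray) -> float:
    """Norm of the mean heading, in [0, 1]."""
    return float(np.linalg.norm(np.mean(directions, axis=0)))


def phi_m(
    positions: np.ndarray, directions: np.ndarray, cfg: SphereConfig
) -> tuple[np.ndarray, float]:
    """Mean specific angular momentum ``m = mean((p x d)/r)`` and its norm.

    Each term is a unit vector (``p`` and ``d`` orthogonal, ``|p| = r``,
    ``|d| = 1``), so the norm lies in [0, 1]; it reaches 1 when all agents
    circulate the same oriented great circle.
    """
    m = np.mean(np.cross(positions, directions), axis=0) / cfg.r
    return m, float(np.linalg.norm(m))


def phi_zeta(zeta_norms: np.ndarray) -> float:
    """Mean local polarization magnitude, in [0, 1]."""
    return float(np.mean(zeta_norms))


def manifold_centroid(positions: np.ndarray, cfg: SphereConfig) -> np.ndarray | None:
    """Radial projection of the mean position back onto the sphere.

    Returns None when the mean position sits at the center within
    tolerance (e.g. a perfectly balanced swarm) — the swarm then has no
    meaningful aggregation point and geodesic scale is undefined.
    """
    pbar = np.mean(positions, axis=0)
    norm = np.linalg.norm(pbar)
    if norm <= cfg.tol * cfg.r:
        return None
    return cfg.r * pbar / norm


def rotation_axis(m: np.ndarray, tol: float = 1e-9) -> np.ndarray | None:
    """Unit rotation axis ``m/|m|``; None when ``|m|`` is below ``tol``.

    The principal plane is ``{x : x . omega = 0}`` and the principal
    great circle its intersection with the sphere.
    """
    norm = np.linalg.norm(m)
    if norm <= tol:
        return None
    return m / norm


@dataclass(frozen=True)
class ScaleMeasures:
    """Swarm extent about the centroid and the principal plane.

    ``c_i`` is agent i's geodesic distance to the manifold centroid and
    ``e_i`` its Euclidean distance to the principal plane; ``c``/``e`` are
    their means and ``delta_c``/``delta_e`` sample standard deviations
    (n-1 divisor).  Fields tied to an undefined centroid or axis are NaN.
    """

    c: float
    e: float
    delta_c: float
    delta_e: float
    c_i: np.ndarray
    e_i: np.ndarray


def _sd(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1)) if len(x) > 1 else 0.0


def scale_measures(
    positions: np.ndarray,
    centroid: np.ndarray | None,
    omega_hat: np.ndarray | None,
    cfg: SphereConfig,
) -> ScaleMeasures:
    n = len(positions)
    if centroid is not None:
        c_i = great_circle_distance(positions, centroid, cfg)
        c, delta_c = float(np.mean(c_i)), _sd(c_i)
    else:
        c_i = np.full(n, np.nan)
        c = delta_c = float("nan")
    if omega_hat is not None:
        e_i = np.abs(positions @ omega_hat)
        e, delta_e = float(np.mean(e_i)), _sd(e_i)
    else:
        e_i = np.full(n, np.nan)
        e = delta_e = float("nan")
    return ScaleMeasures(c=c, e=e, delta_c=delta_c, delta_e=delta_e, c_i=c_i, e_i=e_i)


def local_density(
    positions: np.ndarray, r0: float, cfg: SphereConfig
) -> tuple[np.ndarray, float]:
    """Fraction of the swarm within geodesic radius ``r0`` of each agent
    (self included), and its mean."""
    nbrs = neighbor_sets(positions, r0, cfg)
    rho_i = nbrs.counts / len(positions)
    return rho_i, float(np.mean(rho_i))


def compute_series(traj: Trajectory, vicinity_radius: float | None = None) -> pd.DataFrame:
    """Per-step observables for every recorded state of a trajectory.

    Returns a tidy frame with one row per recorded step: the three order
    parameters, the mean angular momentum and rotation axis, the manifold
    centroid, the scale measures ``c`` and ``e`` with their standard
    deviations, and the mean local density (vicinity radius defaults to
    the interaction radius ``r0``).  ``phi_zeta`` is NaN for the initial
    state, where no cooperative vector has been computed yet; scale
    columns are NaN where the centroid or axis is degenerate.
    """
    cfg = traj.params.sphere
    rad = traj.params.r0 if vicinity_radius is None else vicinity_radius
    rows = []
    for st in traj.states:
        m, pm = phi_m(st.positions, st.directions, cfg)
        centroid = manifold_centroid(st.positions, cfg)
        omega = rotation_axis(m)
        sc = scale_measures(st.positions, centroid, omega, cfg)
        _, rho_bar = local_density(st.positions, rad, cfg)
        cen = centroid if centroid is not None else np.full(3, np.nan)
        om = omega if omega is not None else np.full(3, np.nan)
        rows.append(
            {
                "step": st.step,
                "phi": phi(st.directions),
                "phi_m": pm,
                "phi_zeta": phi_zeta(st.zeta_norms) if st.zeta_norms is not None else np.nan,
                "mean_speed": float(np.mean(st.speeds)),
                "m_x": m[0], "m_y": m[1], "m_z": m[2],
                "centroid_x": cen[0], "centroid_y": cen[1], "centroid_z": cen[2],
                "omega_x": om[0], "omega_y": om[1], "omega_z": om[2],
                "c": sc.c, "e": sc.e,
                "delta_c": sc.delta_c, "delta_e": sc.delta_e,
                "rho_bar": rho_bar,
                "centroid_defined": centroid is not None,
                "axis_defined": omega is not None,
            }
        )
    return pd.DataFrame(rows)


def agent_scale_series(traj: Trajectory, agents: list[int]) -> pd.DataFrame:
    """Per-agent ``c_i`` and ``e_i`` time series for selected agents."""
    cfg = traj.params.sphere
    rows = []
    for st in traj.states:
        m, _ = phi_m(st.positions, st.directions, cfg)
        centroid = manifold_centroid(st.positions, cfg)
        omega = rotation_axis(m)
        sc = scale_measures(st.positions, centroid, omega, cfg)
        for i in agents:
            rows.append({"step": st.step, "agent": i, "c_i": sc.c_i[i], "e_i": sc.e_i[i]})
    return pd.DataFrame(rows)
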