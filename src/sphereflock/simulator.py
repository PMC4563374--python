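"""Synchronous framework iteration for collective motion on a sphere.

One step advances every agent along its own great circle by its current
speed, parallel-transports its heading, applies tangent-plane angular noise,
evaluates the cooperative rule at the *new* positions, and derives the next
heading (projection of ``zeta`` onto the tangent plane) and next speed
(``v0 |zeta|^alpha``, or the constant ``v0`` when ``alpha = 0``).  All
agents update from the step-k state; nothing in the update can push an
agent off the sphere.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import (
    SphereConfig,
    great_circle_step,
    parallel_transport,
    random_sphere_points,
    random_tangent_directions,
)
from .rules import CooperativeRule, NoiseModel, SDARule, apply_direction_noise

__all__ = ["SimParams", "SwarmState", "Trajectory", "init_uniform", "framework_step", "run"]

# relative drift allowed before the iteration is declared broken
_INTEGRITY_TOL = 1e-6


@dataclass(frozen=True)
class SimParams:
    """All scalar constants of one simulation.

    Parameters
    ----------
    n
        Number of agents.
    r
        Sphere radius (length units).
    v0
        Maximum speed, length per unit time; should satisfy ``v0 << r``.
    r0
        Interaction radius for the alignment rule, same units as ``r``.
    eta
        Noise strength in radians: tangent-plane swing angles are uniform
        on ``[-eta, eta]``.
    alpha
        Speed-adaptivity exponent (>= 0).  ``alpha = 0`` is constant-speed
        motion at ``v0``; larger ``alpha`` makes weakly polarized agents
        hesitate (``v = v0 |zeta|^alpha``).
    dt
        Time interval per step.
    steps
        Number of iterations to run.
    seed
        Seed for initial conditions and the noise stream.
    renormalize
        Rescale positions to radius ``r`` and re-orthogonalize headings
        after every step, bounding floating-point drift (on by default).
    initial_speed_v0
        Start agents at speed ``v0`` instead of the default ``v = 0``
        (with the default, the first step moves nobody and the first
        alignment averages the initial headings).
    """

    n: int
    r: float = 1.0
    v0: float = 0.02
    r0: float = 0.4
    eta: float = 0.0
    alpha: float = 1.0
    dt: float = 1.0
    steps: int = 600
    seed: int = 0
    renormalize: bool = True
    initial_speed_v0: bool = False

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"need at least one agent, got n={self.n}")
        for name in ("r", "v0", "r0", "dt"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.alpha < 0:
            raise ValueError(f"alpha must be nonnegative, got {self.alpha}")
        if self.eta < 0:
            raise ValueError(f"eta must be nonnegative, got {self.eta}")
        if self.steps < 0:
            raise ValueError(f"steps must be nonnegative, got {self.steps}")

    @property
    def sphere(self) -> SphereConfig:
        return SphereConfig(r=self.r)


@dataclass(frozen=True)
class SwarmState:
    """Positions, headings, and speeds of all agents at one step.

    ``zeta_norms`` holds the polarization magnitudes ``|zeta_i|`` that
    produced this state (None for an initial state).
    """

    step: int
    positions: np.ndarray  # (n, 3), |p_i| = r
    directions: np.ndarray  # (n, 3), unit, tangent
    speeds: np.ndarray  # (n,), in [0, v0]
    zeta_norms: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.positions)

    def validate(self, cfg: SphereConfig, tol: float = _INTEGRITY_TOL) -> None:
        """Raise if any manifold constraint is violated beyond ``tol``."""
        r = cfg.r
        pos_err = np.abs(np.linalg.norm(self.positions, axis=1) - r).max() / r
        unit_err = np.abs(np.linalg.norm(self.directions, axis=1) - 1.0).max()
        perp_err = np.abs(np.sum(self.positions * self.directions, axis=1)).max() / r
        if max(pos_err, unit_err, perp_err) > tol:
            raise FloatingPointError(
                f"state at step {self.step} violates sphere constraints: "
                f"position drift {pos_err:.2e}, unit drift {unit_err:.2e}, "
                f"tangency drift {perp_err:.2e} (tol {tol:.0e})"
            )


@dataclass
class Trajectory:
    """Recorded run: states at recorded steps plus per-step ``|zeta_i|``.

    ``zeta_norms[k]`` are the magnitudes used in the transition to step
    ``k+1``; they are kept for every step even when state recording is
    thinned.
    """

    params: SimParams
    states: list[SwarmState] = field(default_factory=list)
    zeta_norms: np.ndarray | None = None  # (steps, n)

    @property
    def final(self) -> SwarmState:
        return self.states[-1]


def init_uniform(params: SimParams) -> SwarmState:
    """Uniform-random initial configuration.

    Positions i.i.d. uniform on the sphere, each heading uniform on the
    tangent circle at its position, all speeds zero (or ``v0`` when
    ``initial_speed_v0`` is set).
    """
    cfg = params.sphere
    rng = np.random.default_rng(params.seed)
    p = random_sphere_points(params.n, cfg, rng)
    d = random_tangent_directions(p, cfg, rng)
    v = np.full(params.n, params.v0 if params.initial_speed_v0 else 0.0)
    return SwarmState(step=0, positions=p, directions=d, speeds=v)


def _renormalize(p: np.ndarray, d: np.ndarray, cfg: SphereConfig) -> tuple[np.ndarray, np.ndarray]:
    p = cfg.r * p / np.linalg.norm(p, axis=1, keepdims=True)
    d = d - (np.sum(d * p, axis=1) / cfg.r**2)[:, None] * p
    d = d / np.linalg.norm(d, axis=1, keepdims=True)
    return p, d


def framework_step(
    state: SwarmState,
    params: SimParams,
    rule: CooperativeRule,
    noise_angles: np.ndarray | None = None,
) -> SwarmState:
    """Advance the whole swarm by one synchronous step.

    Order of operations: great-circle move by ``v dt``; parallel transport
    of headings; tangent-plane noise; cooperative rule at the new
    positions; tangent projection of ``zeta`` for the new heading (an agent
    whose ``zeta`` has no tangent component keeps its noise-free transported
    heading); adaptive speed ``v0 |zeta|^alpha``.
    """
    cfg = params.sphere
    arcs = state.speeds * params.dt
    p_new = great_circle_step(state.positions, state.directions, arcs, cfg)
    d_minus = parallel_transport(state.positions, state.directions, arcs, cfg)

    if noise_angles is None or not np.any(noise_angles):
        d_tilde = d_minus
    else:
        d_tilde = apply_direction_noise(d_minus, p_new, noise_angles)

    zeta = rule(p_new, d_tilde, cfg)
    zeta_norm = np.linalg.norm(zeta, axis=1)

    # heading: component of zeta perpendicular to the new position, normalized;
    # degenerate zeta (zero, or radial) falls back to the transported heading
    w = zeta - (np.sum(zeta * p_new, axis=1) / cfg.r**2)[:, None] * p_new
    w_norm = np.linalg.norm(w, axis=1)
    ok = w_norm > cfg.tol
    d_new = np.where(ok[:, None], w / np.where(ok, w_norm, 1.0)[:, None], d_minus)

    if params.alpha == 0.0:
        v_new = np.full(state.n, params.v0)
    else:
        v_new = params.v0 * zeta_norm**params.alpha

    if params.renormalize:
        p_new, d_new = _renormalize(p_new, d_new, cfg)

    out = SwarmState(
        step=state.step + 1,
        positions=p_new,
        directions=d_new,
        speeds=v_new,
        zeta_norms=zeta_norm,
    )
    out.validate(cfg)
    return out


def run(
    params: SimParams,
    rule: CooperativeRule | None = None,
    initial: SwarmState | None = None,
    record_every: int = 1,
) -> Trajectory:
    """Run the full iteration and record the trajectory.

    ``rule`` defaults to spherical direction-alignment at radius
    ``params.r0``.  ``record_every = m`` keeps every m-th state (the final
    state is always kept); thinning never alters the dynamics.  Identical
    ``params`` (including seed) reproduce the trajectory bit for bit.
    """
    if rule is None:
        rule = SDARule(params.r0)
    noise = NoiseModel(eta=params.eta, seed=params.seed)
    state = init_uniform(params) if initial is None else initial

    states = [state]
    znorms = np.empty((params.steps, params.n))
    for k in range(params.steps):
        angles = noise.draw(params.n, step=k) if params.eta > 0 else None
        state = framework_step(state, params, rule, angles)
        znorms[k] = state.zeta_norms
        if state.step % record_every == 0 or state.step == params.steps:
            states.append(state)
    return Trajectory(params=params, states=states, zeta_norms=znorms)


def replay(params: SimParams, **overrides) -> Trajectory:
    """Re-run a simulation from stored parameters (optionally overriding
    e.g. ``steps``); byte-identical to the original for identical params."""
    return run(replace(params, **overrides))
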