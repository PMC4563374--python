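"""Cooperative rules: neighbor search, tangent-plane noise, and the
spherical direction-alignment (SDA) rule.

The framework advances every agent along a great circle, parallel-transports
its heading to the new position ("approaching direction"), optionally swings
that heading by a random angle within the tangent plane, and then hands the
noised approaching directions to a *cooperative rule* which returns, for
each agent, a polarization vector ``zeta``.  The SDA rule — the sphere
analogue of Vicsek direction averaging — sets ``zeta_i`` to the mean of the
noised approaching directions over the neighbor set of agent ``i``
(neighbors by great-circle distance, self included), so ``|zeta_i| <= 1``
with equality only under perfect local alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol

import numpy as np

from .geometry import SphereConfig, tangent_basis

__all__ = [
    "NeighborSets",
    "NoiseModel",
    "CooperativeRule",
    "SDARule",
    "neighbor_sets",
    "apply_direction_noise",
    "sda_rule",
]


@dataclass(frozen=True)
class NeighborSets:
    """Symmetric neighbor structure: ``adjacency[i, j]`` is True when the
    great-circle distance between agents ``i`` and ``j`` is strictly below
    the interaction radius.  ``adjacency[i, i]`` is always True, so every
    count is at least 1."""

    adjacency: np.ndarray  # (n, n) bool
    counts: np.ndarray  # (n,) int

    def members(self, i: int) -> np.ndarray:
        """Indices of the neighbors of agent ``i`` (including ``i``)."""
        return np.flatnonzero(self.adjacency[i])


def neighbor_sets(positions: np.ndarray, r0: float, cfg: SphereConfig) -> NeighborSets:
    """All-pairs neighbor search by great-circle distance.

    GCD(p_i, p_j) < r0 is equivalent to ``p_i . p_j / r^2 > cos(r0 / r)``
    (both sides monotone), evaluated as one Gram-matrix comparison — no
    arccos needed.  For ``r0 >= pi * r`` every pair is a neighbor.
    """
    if not r0 > 0:
        raise ValueError(f"interaction radius must be positive, got {r0}")
    p = np.asarray(positions, dtype=float)
    if r0 >= np.pi * cfg.r:
        adj = np.ones((len(p), len(p)), dtype=bool)
    else:
        gram = np.clip(p @ p.T / cfg.r**2, -1.0, 1.0)
        adj = gram > np.cos(r0 / cfg.r)
        np.fill_diagonal(adj, True)  # self-distance is 0, strict < r0 holds
    return NeighborSets(adjacency=adj, counts=adj.sum(axis=1))


@dataclass(frozen=True)
class NoiseModel:
    """Uniform angular noise on the tangent plane.

    Each agent's approaching direction is rotated within its tangent plane
    by an angle drawn uniformly from ``[-eta, eta]`` (radians), one draw per
    agent per step, shared by every neighbor that observes that agent.
    Draws are addressed by ``(seed, step)`` so any step can be replayed
    without regenerating the whole stream.
    """

    eta: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.eta < 0:
            raise ValueError(f"noise strength must be nonnegative, got {self.eta}")

    def draw(self, n: int, step: int) -> np.ndarray:
        """``n`` i.i.d. angles in ``[-eta, eta]`` for the given step."""
        if self.eta == 0.0:
            return np.zeros(n)
        rng = np.random.default_rng([self.seed, step])
        return rng.uniform(-self.eta, self.eta, n)


def apply_direction_noise(
    d_minus: np.ndarray, p: np.ndarray, theta: np.ndarray
) -> np.ndarray:
    """Swing each tangent direction by its angle within the tangent plane.

    With the in-plane basis ``x = d_minus``, ``y = (p/|p|) x d_minus`` the
    noised direction is ``cos(theta) x + sin(theta) y``; it stays unit and
    tangent, and deviates from ``d_minus`` by exactly ``|theta|``.
    """
    theta = np.asarray(theta, dtype=float)
    x, y = tangent_basis(p, d_minus)
    return np.cos(theta)[..., None] * x + np.sin(theta)[..., None] * y


def sda_rule(noised_approach_dirs: np.ndarray, neighbors: NeighborSets) -> np.ndarray:
    """Average of the noised approaching directions over each neighbor set.

    ``zeta_i = (1/n_i) sum_{j in N_i} d~_j``; computed for all agents at
    once as a masked matrix product.  A zero vector is a legal output (the
    "hesitating agent" singularity) handled by the caller.
    """
    d = np.asarray(noised_approach_dirs, dtype=float)
    sums = neighbors.adjacency @ d
    return sums / neighbors.counts[:, None]


class CooperativeRule(Protocol):
    """A cooperative rule maps the freshly advanced swarm state (positions
    and noised approaching directions at step k+1) to one polarization
    vector ``zeta`` per agent.  Implementations must keep ``|zeta_i| <= 1``
    so the adaptive speed ``v0 |zeta|^alpha`` never exceeds ``v0``."""

    def __call__(
        self,
        positions: np.ndarray,
        noised_approach_dirs: np.ndarray,
        cfg: SphereConfig,
    ) -> np.ndarray: ...


@dataclass(frozen=True)
class SDARule:
    """Spherical direction-alignment with interaction radius ``r0``."""

    r0: float

    def __call__(
        self,
        positions: np.ndarray,
        noised_approach_dirs: np.ndarray,
        cfg: SphereConfig,
    ) -> np.ndarray:
        nbrs = neighbor_sets(positions, self.r0, cfg)
        return sda_rule(noised_approach_dirs, nbrs)
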