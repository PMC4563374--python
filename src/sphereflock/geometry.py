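"""Exact kinematic primitives on a sphere of radius ``r``.

All operations act on Cartesian 3-vectors and are fully vectorized over a
leading axis, so a swarm of ``n`` agents is an ``(n, 3)`` array.  Positions
live on the sphere (``|p| = r``); headings are unit tangent vectors
(``|d| = 1``, ``d . p = 0``).  Motion along a heading follows the great
circle through ``p`` in direction ``d``, and headings are carried along the
arc by parallel transport, which preserves the angular-momentum-like
invariant ``p x d``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SphereConfig",
    "SingularityError",
    "perp_normalize",
    "great_circle_distance",
    "great_circle_step",
    "parallel_transport",
    "tangent_basis",
    "mapped_step_size",
    "random_sphere_points",
    "random_tangent_directions",
]


class SingularityError(ValueError):
    """Raised when a vector has no usable component perpendicular to another."""


@dataclass(frozen=True)
class SphereConfig:
    """Sphere radius and numerical tolerance.

    Parameters
    ----------
    r
        Sphere radius, in length units; must be positive.
    tol
        Relative tolerance for constraint checks (dimensionless).
    """

    r: float = 1.0
    tol: float = 1e-9

    def __post_init__(self) -> None:
        if not self.r > 0:
            raise ValueError(f"sphere radius must be positive, got {self.r}")
        if not self.tol > 0:
            raise ValueError(f"tolerance must be positive, got {self.tol}")


def _dot(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.sum(a * b, axis=-1)


def perp_normalize(u: np.ndarray, v: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Unit component of ``u`` perpendicular to ``v``.

    Subtracts from ``u`` its projection onto ``v`` and normalizes the
    remainder.  The result lies in ``span{u, v}``, is orthogonal to ``v``
    and has positive inner product with the perpendicular component of
    ``u``.

    Raises
    ------
    SingularityError
        If the perpendicular component has norm ``<= tol`` (``u`` parallel
        to ``v``, or numerically indistinguishable from parallel).  Scalar
        inputs only; batched callers should use :func:`_perp_normalize_batch`
        style masking instead.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    vv = _dot(v, v)
    w = u - (_dot(u, v) / vv)[..., None] * v
    norm = np.linalg.norm(w, axis=-1)
    if np.any(norm <= tol):
        raise SingularityError(
            "vector has no component perpendicular to the reference vector"
        )
    return w / norm[..., None]


def great_circle_distance(p: np.ndarray, q: np.ndarray, cfg: SphereConfig) -> np.ndarray:
    """Geodesic distance ``r * arccos(p.q / r^2)``, in ``[0, pi*r]``.

    The normalized dot product is clamped to ``[-1, 1]`` so rounding can
    never produce NaN.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    c = np.clip(_dot(p, q) / cfg.r**2, -1.0, 1.0)
    return cfg.r * np.arccos(c)


def great_circle_step(
    p: np.ndarray, d: np.ndarray, arc: float | np.ndarray, cfg: SphereConfig
) -> np.ndarray:
    """Advance ``p`` along its great circle in direction ``d`` by arc length ``arc``.

    Closed-form rotation in the plane spanned by ``p`` and ``d``::

        p' = cos(arc/r) p + sin(arc/r) r d

    so the great-circle distance from ``p`` to ``p'`` is exactly ``arc``
    (for ``arc < pi*r``) and ``p'`` stays on the sphere for any ``arc``.
    """
    p = np.asarray(p, dtype=float)
    d = np.asarray(d, dtype=float)
    theta = np.asarray(arc, dtype=float) / cfg.r
    return np.cos(theta)[..., None] * p + np.sin(theta)[..., None] * (cfg.r * d)


def parallel_transport(
    p: np.ndarray, d: np.ndarray, arc: float | np.ndarray, cfg: SphereConfig
) -> np.ndarray:
    """Carry the tangent vector ``d`` along the great circle from ``p`` by ``arc``.

    Returns the transported direction anchored at
    ``great_circle_step(p, d, arc)``::

        d' = -sin(arc/r) p/r + cos(arc/r) d

    Transport conserves the cross product: ``p' x d' = p x d``.  Physically
    ``d'`` is the heading an agent arrives with at its next position, before
    any alignment update (the "approaching direction").
    """
    p = np.asarray(p, dtype=float)
    d = np.asarray(d, dtype=float)
    theta = np.asarray(arc, dtype=float) / cfg.r
    return -np.sin(theta)[..., None] * (p / cfg.r) + np.cos(theta)[..., None] * d


def tangent_basis(p: np.ndarray, x_hint: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Right-handed orthonormal basis of the tangent plane at ``p``.

    ``x`` is ``x_hint`` itself (assumed unit and tangent at ``p``);
    ``y = (p/|p|) x x`` completes the pair.
    """
    p = np.asarray(p, dtype=float)
    x = np.asarray(x_hint, dtype=float)
    phat = p / np.linalg.norm(p, axis=-1, keepdims=True)
    y = np.cross(phat, x)
    return x, y


def mapped_step_size(arc: float | np.ndarray, cfg: SphereConfig) -> np.ndarray:
    """Euclidean displacement along the tangent whose radial projection
    realizes a great-circle arc of length ``arc``: ``l = r tan(arc/r)``.

    Diagnostic only; the step itself is computed in closed form by
    :func:`great_circle_step`.
    """
    return cfg.r * np.tan(np.asarray(arc, dtype=float) / cfg.r)


def random_sphere_points(n: int, cfg: SphereConfig, rng: np.random.Generator) -> np.ndarray:
    """``n`` i.i.d. uniform points on the sphere surface (Gaussian projection)."""
    g = rng.standard_normal((n, 3))
    return cfg.r * g / np.linalg.norm(g, axis=-1, keepdims=True)


def random_tangent_directions(
    p: np.ndarray, cfg: SphereConfig, rng: np.random.Generator
) -> np.ndarray:
    """One uniform-random unit tangent direction at each point of ``p``.

    A Gaussian 3-vector projected onto the tangent plane at ``p`` and
    normalized is uniform on the tangent circle by rotational symmetry.
    """
    p = np.asarray(p, dtype=float)
    g = rng.standard_normal(p.shape)
    g = g - (_dot(g, p) / cfg.r**2)[..., None] * p
    norm = np.linalg.norm(g, axis=-1, keepdims=True)
    # a Gaussian draw exactly radial has probability zero; guard anyway
    while np.any(norm == 0.0):  # pragma: no cover
        bad = norm[..., 0] == 0.0
        g2 = rng.standard_normal((int(bad.sum()), 3))
        g2 = g2 - (_dot(g2, p[bad]) / cfg.r**2)[..., None] * p[bad]
        g[bad] = g2
        norm = np.linalg.norm(g, axis=-1, keepdims=True)
    return g / norm
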