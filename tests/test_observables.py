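"""Order parameters, centroid, rotation axis, scale measures, density."""

import numpy as np
import pytest

from sphereflock.geometry import SphereConfig, great_circle_distance, great_circle_step
from sphereflock.observables import (
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
from sphereflock.simulator import SimParams, run
from .conftest import random_rotation, random_state_on_sphere


def equatorial_swarm(n, r=1.0, rng=None):
    """n agents on the equator heading east (tangent to the equator)."""
    lon = (
        np.linspace(0, 2 * np.pi, n, endpoint=False)
        if rng is None
        else rng.uniform(0, 2 * np.pi, n)
    )
    p = r * np.stack([np.cos(lon), np.sin(lon), np.zeros(n)], axis=1)
    d = np.stack([-np.sin(lon), np.cos(lon), np.zeros(n)], axis=1)
    return p, d


class TestPhi:
    def test_aligned_directions(self):
        d = np.tile([0.0, 0.0, 1.0], (7, 1))
        assert phi(d) == pytest.approx(1.0)

    def test_opposite_directions_cancel(self):
        d = np.array([[1.0, 0, 0], [-1.0, 0, 0]])
        assert phi(d) == pytest.approx(0.0)

    def test_random_directions_near_zero(self, rng, unit_sphere):
        _, d = random_state_on_sphere(100, unit_sphere, rng)
        val = phi(d)
        assert np.isclose(val, np.linalg.norm(d.mean(axis=0)))
        assert val < 0.5  # O(1/sqrt(n)) for incoherent directions


class TestPhiM:
    @pytest.mark.parametrize("r", [1.0, 2.0])
    def test_equatorial_swarm_is_fully_ordered(self, rng, r):
        """A common-great-circle swarm has unit angular-momentum order with
        the polar rotation axis."""
        p, d = equatorial_swarm(100, r=r, rng=rng)
        m, pm = phi_m(p, d, SphereConfig(r=r))
        assert pm == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(np.abs(m), [0, 0, 1], atol=1e-12)

    def test_counter_rotating_pair_cancels(self, unit_sphere):
        p = np.array([[1.0, 0, 0], [0.0, 1, 0]])
        d = np.array([[0.0, 1, 0], [1.0, 0, 0]])  # opposite circulation
        _, pm = phi_m(p, d, unit_sphere)
        assert pm == pytest.approx(0.0, abs=1e-12)

    def test_matches_loop_oracle(self, rng, unit_sphere):
        p, d = random_state_on_sphere(30, unit_sphere, rng)
        m, pm = phi_m(p, d, unit_sphere)
        m_loop = sum(np.cross(p[i], d[i]) for i in range(30)) / 30.0
        assert np.allclose(m, m_loop, atol=1e-12)
        assert 0.0 <= pm <= 1.0


class TestPhiZeta:
    def test_extremes(self):
        assert phi_zeta(np.ones(5)) == pytest.approx(1.0)
        assert phi_zeta(np.zeros(5)) == pytest.approx(0.0)

    def test_mean_speed_identity_at_unit_exponent(self):
        """With alpha = 1 the mean local polarization equals the mean
        adaptive speed divided by v0, at every step."""
        params = SimParams(n=80, v0=0.04, eta=0.2, alpha=1.0, steps=30, seed=13)
        traj = run(params)
        for st in traj.states[1:]:
            assert phi_zeta(st.zeta_norms) == pytest.approx(
                st.speeds.mean() / params.v0, abs=1e-12
            )


class TestManifoldCentroid:
    def test_colocated_swarm(self, unit_sphere):
        q = np.array([0.0, 0.6, 0.8])
        p = np.tile(q, (5, 1))
        assert np.allclose(manifold_centroid(p, unit_sphere), q)

    def test_antipodal_pair_undefined(self, unit_sphere):
        p = np.array([[1.0, 0, 0], [-1.0, 0, 0]])
        assert manifold_centroid(p, unit_sphere) is None

    def test_locally_minimizes_mean_squared_geodesic_distance(self, rng, unit_sphere):
        """Grid-search oracle: for a tight cluster, no probe point offset
        by >= 0.02 from the centroid does better on mean squared geodesic
        distance."""
        center = np.array([0.0, 0.0, 1.0])
        offsets = rng.normal(scale=0.1, size=(12, 3))
        p = center + offsets
        p = p / np.linalg.norm(p, axis=1, keepdims=True)
        cen = manifold_centroid(p, unit_sphere)
        obj = np.mean(great_circle_distance(p, cen, unit_sphere) ** 2)
        for _ in range(200):
            probe = cen + rng.normal(scale=0.05, size=3)
            probe /= np.linalg.norm(probe)
            if great_circle_distance(cen, probe, unit_sphere) < 0.02:
                continue
            assert np.mean(great_circle_distance(p, probe, unit_sphere) ** 2) > obj


class TestRotationAxisAndScales:
    def test_equatorial_axis_is_polar(self, rng, unit_sphere):
        p, d = equatorial_swarm(50, rng=rng)
        m, _ = phi_m(p, d, unit_sphere)
        omega = rotation_axis(m)
        assert np.allclose(np.abs(omega), [0, 0, 1], atol=1e-12)

    def test_balanced_state_axis_undefined(self, unit_sphere):
        assert rotation_axis(np.zeros(3)) is None

    def test_colocated_swarm_has_zero_spread(self, unit_sphere):
        q = np.array([1.0, 0.0, 0.0])
        p = np.tile(q, (6, 1))
        sc = scale_measures(p, q, np.array([0.0, 0.0, 1.0]), unit_sphere)
        assert sc.c == pytest.approx(0.0)
        assert sc.delta_c == pytest.approx(0.0)

    def test_principal_circle_swarm_has_zero_plane_distance(self, rng, unit_sphere):
        p, d = equatorial_swarm(50, rng=rng)
        m, _ = phi_m(p, d, unit_sphere)
        omega = rotation_axis(m)
        cen = manifold_centroid(p, unit_sphere)
        sc = scale_measures(p, cen if cen is not None else p[0], omega, unit_sphere)
        assert sc.e == pytest.approx(0.0, abs=1e-12)

    def test_e_invariant_to_axis_sign(self, rng, unit_sphere):
        p, _ = random_state_on_sphere(40, unit_sphere, rng)
        omega = np.array([0.0, 0.0, 1.0])
        a = scale_measures(p, p[0], omega, unit_sphere)
        b = scale_measures(p, p[0], -omega, unit_sphere)
        assert a.e == pytest.approx(b.e)
        assert np.allclose(a.e_i, b.e_i)

    def test_matches_loop_oracle_and_unbiased_sd(self, rng, unit_sphere):
        p, _ = random_state_on_sphere(25, unit_sphere, rng)
        cen = manifold_centroid(p, unit_sphere)
        omega = np.array([0.0, 1.0, 0.0])
        sc = scale_measures(p, cen, omega, unit_sphere)
        c_loop = np.array([great_circle_distance(p[i], cen, unit_sphere) for i in range(25)])
        e_loop = np.array([abs(p[i] @ omega) for i in range(25)])
        assert np.allclose(sc.c_i, c_loop, atol=1e-12)
        assert np.allclose(sc.e_i, e_loop, atol=1e-12)
        assert sc.delta_c == pytest.approx(np.std(c_loop, ddof=1))
        assert sc.delta_e == pytest.approx(np.std(e_loop, ddof=1))
        assert sc.e < 1.0


class TestLocalDensity:
    def test_colocated(self, unit_sphere):
        p = np.tile([1.0, 0, 0], (4, 1))
        rho_i, rho_bar = local_density(p, 0.3, unit_sphere)
        assert np.all(rho_i == 1.0) and rho_bar == 1.0

    def test_isolated(self, unit_sphere):
        p = np.eye(3)  # pairwise geodesic distance pi/2
        rho_i, rho_bar = local_density(p, 0.5, unit_sphere)
        assert np.all(rho_i == pytest.approx(1 / 3))

    def test_matches_brute_count(self, rng, unit_sphere):
        p, _ = random_state_on_sphere(40, unit_sphere, rng)
        rho_i, _ = local_density(p, 0.6, unit_sphere)
        for i in range(40):
            cnt = sum(
                1 for j in range(40)
                if great_circle_distance(p[i], p[j], unit_sphere) < 0.6
            )
            assert rho_i[i] == pytest.approx(cnt / 40)


def test_scalar_observables_rotation_invariant(rng, unit_sphere):
    p, d = random_state_on_sphere(30, unit_sphere, rng)
    R = random_rotation(rng)
    _, pm = phi_m(p, d, unit_sphere)
    _, pm_rot = phi_m(p @ R.T, d @ R.T, unit_sphere)
    assert pm_rot == pytest.approx(pm, abs=1e-12)
    assert phi(d @ R.T) == pytest.approx(phi(d), abs=1e-12)
    cen = manifold_centroid(p, unit_sphere)
    cen_rot = manifold_centroid(p @ R.T, unit_sphere)
    assert np.allclose(cen_rot, R @ cen, atol=1e-12)


def test_series_frame_shape_and_flags():
    params = SimParams(n=20, steps=5, eta=0.1, alpha=1.0, seed=4)
    df = compute_series(run(params))
    assert len(df) == 6
    assert np.isnan(df.loc[0, "phi_zeta"])  # no cooperative vector yet
    assert df["phi"].between(0, 1).all()
    assert df["phi_m"].between(0, 1).all()
    assert df.loc[1:, "phi_zeta"].between(0, 1).all()
    assert set(df["centroid_defined"]) <= {True, False}


def test_agent_scale_series_selects_agents():
    params = SimParams(n=15, steps=4, alpha=1.0, seed=4)
    df = agent_scale_series(run(params), agents=[0, 7])
    assert set(df["agent"]) == {0, 7}
    assert len(df) == 2 * 5


def test_emergence_trends_in_evolution_run():
    """Emergence in a dense, weak-noise, adaptive-speed swarm: angular-momentum
    order and local polarization rise (after smoothing) while both scale
    measures shrink."""
    params = SimParams(n=800, r=1.0, v0=0.02, r0=0.4, eta=0.1, alpha=1.0, steps=600, seed=42)
    df = compute_series(run(params, record_every=1))
    win = 50
    for col in ("phi_m", "phi_zeta"):
        smooth = df[col].rolling(win, min_periods=1).mean().to_numpy()[win:]
        assert smooth[-1] > smooth[0]
        assert np.all(np.diff(smooth) > -0.02)  # non-decreasing in trend
    assert df["c"].iloc[-1] < df["c"].iloc[1]
    assert df["e"].iloc[-1] < df["e"].iloc[1]
    assert df["phi_m"].iloc[-1] > 0.5
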