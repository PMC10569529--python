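"""Engine update rules: diffusion laws, reaction probabilities, conservation."""

import math

import numpy as np
import pytest
from scipy import stats

import cdc42polarity as cp
from cdc42polarity.engine import (
    Simulation,
    attempt_first_order,
    attempt_second_order,
    brownian_step,
    first_order_probability,
    initial_state,
    place_dissociated,
    second_order_probability,
)
from cdc42polarity.fixtures import InitialCondition
from cdc42polarity.params import ReactionSpec


def small_core(n_cdc42=300, n_bem1=30, mode="plane2d"):
    return cp.build_circuit("core", mode, {"Cdc42": n_cdc42, "Bem1GEF": n_bem1})


class TestProbabilities:
    def test_first_order_closed_form(self):
        # k = 0.35 /s over dt = 0.1 ms
        assert first_order_probability(0.35, 1e-4) == pytest.approx(3.49994e-5, rel=1e-5)
        assert first_order_probability(0.0, 1e-4) == 0.0

    def test_second_order_closed_form(self):
        assert second_order_probability(180.0, 1e-4) == pytest.approx(
            1 - math.exp(-0.018)
        )

    def test_attempts(self):
        r1 = ReactionSpec("k", "first_order", ("A",), ("B",), 0.35, "s^-1")
        p = first_order_probability(0.35, 1e-4)
        assert attempt_first_order(r1, 1e-4, p * 0.99)
        assert not attempt_first_order(r1, 1e-4, p * 1.01)
        r2 = ReactionSpec("l", "second_order", ("A", "B"), ("C",), 180.0, "s^-1", rho=0.05)
        assert not attempt_second_order(0.06, r2, 1e-4, 0.0)  # out of range
        assert attempt_second_order(0.04, r2, 1e-4, 0.017)
        assert not attempt_second_order(0.04, r2, 1e-4, 0.019)

    def test_monte_carlo_firing_rate(self, rng):
        p = 1 - math.exp(-0.01)
        r = ReactionSpec("k", "first_order", ("A",), ("B",), 100.0, "s^-1")
        fired = sum(attempt_first_order(r, 1e-4, u) for u in rng.random(10**6))
        se = math.sqrt(p * (1 - p) * 10**6)
        assert abs(fired - p * 10**6) < 3 * se


class TestBrownianStep:
    def test_displacement_std_matches_sqrt_2Ddt(self, plane, rng):
        n = 100_000
        pts = np.full((n, 2), plane.L / 2)
        moved = brownian_step(pts, D=0.0025, dt=1e-4, geometry=plane, rng=rng)
        d = moved - pts
        target = math.sqrt(2 * 0.0025 * 1e-4)
        assert target == pytest.approx(7.0711e-4, rel=1e-4)
        for ax in range(2):
            assert d[:, ax].std() == pytest.approx(target, rel=0.01)

    def test_zero_diffusion_is_identity(self, plane, rng):
        pts = rng.uniform(0, plane.L, (100, 2))
        assert np.array_equal(brownian_step(pts, 0.0, 1e-4, plane, rng), pts)

    def test_wrapping_and_sphere_constraints(self, plane, sphere, rng):
        pts = np.full((1000, 2), plane.L - 1e-6)
        out = brownian_step(pts, 15.0, 1e-4, plane, rng)
        assert ((out >= 0) & (out < plane.L)).all()
        mem = cp.uniform_pattern(1000, sphere, rng)
        out3 = brownian_step(mem, 0.0025, 1e-4, sphere, rng)
        assert np.allclose(np.linalg.norm(out3, axis=1), sphere.R, atol=1e-9)

    def test_msd_is_4Dt_on_the_plane(self, rng):
        # pre-wrap MSD on a huge domain so the boundary never interferes
        big = cp.Geometry.plane(L=1000.0)
        D, dt, nsteps = 0.0025, 1e-4, 200
        pts = np.full((2000, 2), 500.0)
        cur = pts
        for _ in range(nsteps):
            cur = brownian_step(cur, D, dt, big, rng)
        msd = ((cur - pts) ** 2).sum(axis=1).mean()
        expected = 4 * D * dt * nsteps
        se = expected * math.sqrt(2.0 / 2000)
        assert abs(msd - expected) < 4 * se

    def test_msd_on_sphere_at_short_times(self, sphere, rng):
        D, dt, nsteps = 0.0025, 1e-4, 200
        start = cp.uniform_pattern(2000, sphere, rng)
        cur = start
        for _ in range(nsteps):
            cur = brownian_step(cur, D, dt, sphere, rng)
        mu = np.clip((cur * start).sum(1) / sphere.R**2, -1, 1)
        geo_msd = (sphere.R * np.arccos(mu)) ** 2
        expected = 4 * D * dt * nsteps  # flat-space law, valid for steps << R
        assert geo_msd.mean() == pytest.approx(expected, rel=0.1)


class TestDissociationPlacement:
    def test_offset_distance_2d(self, plane, rng):
        p, q = place_dissociated([4.0, 4.0], 0.05, plane, rng)
        assert np.linalg.norm(q - p) == pytest.approx(0.05001, abs=1e-9)

    def test_sphere_products_on_membrane(self, sphere, rng):
        parent = np.array([0.0, 0.0, sphere.R])
        p, q = place_dissociated(parent, 0.05, sphere, rng)
        assert np.linalg.norm(p) == pytest.approx(sphere.R, abs=1e-9)
        assert np.linalg.norm(q) == pytest.approx(sphere.R, abs=1e-9)
        assert np.linalg.norm(q - p) == pytest.approx(0.05001, rel=1e-3)

    def test_directions_uniform_on_circle(self, plane):
        rng = np.random.default_rng(0)
        angles = []
        for _ in range(10_000):
            p, q = place_dissociated([4.0, 4.0], 0.05, plane, rng)
            d = q - p
            angles.append(math.atan2(d[1], d[0]))
        angles = np.asarray(angles)
        # Rayleigh test for circular uniformity
        rbar = np.hypot(np.cos(angles).mean(), np.sin(angles).mean())
        p_value = math.exp(-len(angles) * rbar**2)
        assert p_value > 0.01


class TestSimulationContracts:
    def test_same_seed_reproduces_trajectory(self):
        p = small_core()
        t1 = cp.run(p, t_end=3, seed=42, record_interval=1.0)
        t2 = cp.run(p, t_end=3, seed=42, record_interval=1.0)
        assert t1.counts.equals(t2.counts)
        assert np.array_equal(t1.snapshots[-1].positions, t2.snapshots[-1].positions)

    def test_conservation_groups_hold_at_every_snapshot(self):
        p = cp.build_circuit(
            "combined", "plane2d",
            {"Cdc42": 400, "Bem1GEF": 40, "Far1GEF": 10, "Receptor": 200},
        )
        traj = cp.run(p, t_end=5, seed=7, record_interval=1.0)
        c = traj.counts
        assert (c[["Cdc42D_c", "Cdc42D_m", "Cdc42T", "Cdc42T_Bem1GEF"]].sum(1) == 400).all()
        assert (c[["Bem1GEF_c", "Bem1GEF_m", "Cdc42T_Bem1GEF"]].sum(1) == 40).all()
        assert (c[["Far1GEF_c", "RaGEF"]].sum(1) == 10).all()
        assert (c[["Ra_m", "Ri_c", "RaGEF"]].sum(1) == 200).all()

    def test_empty_system_advances_time_only(self):
        p = cp.build_circuit("core", "plane2d", {"Cdc42": 0, "Bem1GEF": 0})
        traj = cp.run(p, t_end=2, seed=0, record_interval=1.0)
        assert traj.times[-1] == 2.0
        assert len(traj.snapshots[-1].positions) == 0

    def test_t_end_must_align_with_recording(self):
        with pytest.raises(ValueError):
            cp.run(small_core(), t_end=15.0, record_interval=10.0)

    def test_membrane_particles_stay_on_sphere(self):
        p = small_core(mode="sphere3d")
        traj = cp.run(p, t_end=3, seed=5, record_interval=1.0)
        st = traj.snapshots[-1]
        mem = st.positions_of(("Cdc42D_m", "Cdc42T", "Bem1GEF_m", "Cdc42T_Bem1GEF"))
        assert np.allclose(np.linalg.norm(mem, axis=1), 2.5, atol=1e-9)
        cyt = st.positions_of(("Cdc42D_c", "Bem1GEF_c"))
        assert (np.linalg.norm(cyt, axis=1) <= 2.5 + 1e-12).all()

    def test_plane_positions_stay_wrapped(self):
        traj = cp.run(small_core(), t_end=3, seed=6, record_interval=1.0)
        pos = traj.snapshots[-1].positions
        assert ((pos >= 0) & (pos < 8.8623)).all()

    def test_immobile_far1_seeds_do_not_move(self):
        p = cp.build_circuit("core", "plane2d", {"Cdc42": 100, "Bem1GEF": 10},
                             with_fixed_far1_seeds=True)
        init = InitialCondition(kind="fixed_far1_seeds", n_seeds=4)
        traj = cp.run(p, init=init, t_end=2, seed=3, record_interval=1.0)
        first = traj.snapshots[0].positions_of("Far1GEF_f")
        last = traj.snapshots[-1].positions_of("Far1GEF_f")
        assert np.array_equal(np.sort(first, 0), np.sort(last, 0))


class TestKinetics:
    def test_membrane_binding_equilibrium_of_inactive_cdc42(self):
        """Cdc42-GDP cycles membrane/cytosol as a two-state Markov chain:
        the membrane fraction approaches k_5a/(k_5a + k_5b) = 36/49."""
        p = small_core(n_cdc42=200, n_bem1=0)
        traj = cp.run(p, t_end=30, seed=9, record_interval=1.0)
        frac = traj.counts["Cdc42D_m"][traj.counts.index >= 2] / 200
        expected = 36.0 / 49.0
        assert frac.mean() == pytest.approx(expected, abs=0.02)

    def test_well_mixed_species_means_match_ode_oracle(self):
        """With fast diffusion everywhere the network is well mixed; particle
        means then follow mass-action kinetics with effective bimolecular
        rate lambda*pi*rho^2/A per pair (independent bookkeeping check)."""
        import dataclasses

        from scipy.integrate import solve_ivp

        p = small_core(n_cdc42=300, n_bem1=60)
        sp = {n: dataclasses.replace(s, D=15.0) for n, s in p.species.items()}
        p = p.with_updates(species=sp)
        names = list(p.species)
        idx = {n: i for i, n in enumerate(names)}

        def rhs(t, y):
            dy = np.zeros_like(y)
            for r in p.reactions:
                if r.kind == "first_order":
                    flux = r.rate * y[idx[r.reactants[0]]]
                else:
                    ke = r.rate * math.pi * p.rho**2 / p.geometry.A_m
                    flux = ke * y[idx[r.reactants[0]]] * y[idx[r.reactants[1]]]
                for s in r.reactants:
                    dy[idx[s]] -= flux
                for s in r.products:
                    dy[idx[s]] += flux
            return dy

        y0 = np.zeros(len(names))
        y0[idx["Cdc42D_m"]] = 300
        y0[idx["Bem1GEF_c"]] = 60
        sol = solve_ivp(rhs, (0, 25), y0, rtol=1e-8)
        ode = dict(zip(names, sol.y[:, -1]))

        acc = np.zeros(len(names))
        for seed in range(3):
            traj = cp.run(p, t_end=25, seed=seed, record_interval=2.5,
                          keep_snapshots=False)
            acc += traj.counts[names][traj.counts.index >= 15].mean().to_numpy()
        part = dict(zip(names, acc / 3))
        for n in names:
            assert part[n] == pytest.approx(ode[n], rel=0.15, abs=4.0), n

    def test_step_advances_one_dt(self):
        p = small_core(100, 10)
        st = initial_state(p, seed=1)
        out = cp.step(st, p)
        assert out.t == pytest.approx(p.dt)
        assert len(out.positions) == 110
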