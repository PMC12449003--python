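import numpy as np
import pytest

from cortexvasc import units
from cortexvasc.fixtures import ToyNetworkSpec, make_inflow_waveform, make_toy_network
from cortexvasc.flow1d import (
    HemoParams,
    InflowBC,
    Simulator,
    SolverConfig,
    VesselState,
    WallLaw,
    WindkesselBC,
    elastic_pressure,
    fv_step,
    run_simulation,
    tube_law_pressure,
    wave_speed,
    windkessel_update,
)

WALL = WallLaw(r0=0.05, h=0.012, e_e=2.0e6, e_c=2.0e7, eps0=0.25,
               eps_r=0.07, k_m=5.0e4, p0=units.mmhg_to_cgs(75.0))


class TestTubeLaw:
    def test_reference_state_elastin_only(self):
        w = WallLaw(r0=0.05, h=0.012, e_e=2e6, e_c=0.0, eps0=0.25,
                    eps_r=0.07, k_m=0.0, p0=1000.0)
        assert tube_law_pressure(w.a0, 0.0, w) == pytest.approx(1000.0)

    def test_km_zero_equals_elastic_only(self):
        w0 = WallLaw(**{**WALL.__dict__, "k_m": 0.0})
        a = np.linspace(0.5, 2.0, 7) * WALL.a0
        assert np.array_equal(tube_law_pressure(a, 123.0, w0),
                              elastic_pressure(a, w0))

    def test_collagen_softplus_linear_asymptote(self):
        # ln(e^chi + 1) -> chi for chi >> 0
        a = WALL.a0 * (1 + WALL.eps0 + 20 * WALL.eps_r)
        eps = a / WALL.a0 - 1
        chi = (eps - WALL.eps0) / WALL.eps_r
        asym = WALL.p0 + np.pi * WALL.r0 * WALL.h / a * (
            WALL.e_e * eps + WALL.e_c * WALL.eps_r * chi
        )
        assert tube_law_pressure(a, 0.0, WALL) == pytest.approx(asym, rel=1e-8)

    def test_rejects_nonpositive_area(self):
        with pytest.raises(ValueError):
            tube_law_pressure(-1.0, 0.0, WALL)


class TestWaveSpeed:
    def test_stiffer_wall_is_faster(self):
        w2 = WallLaw(**{**WALL.__dict__, "e_e": 2 * WALL.e_e})
        assert wave_speed(WALL.a0, w2) > wave_speed(WALL.a0, WALL)

    def test_matches_finite_difference_of_tube_law(self):
        for a in (0.7 * WALL.a0, WALL.a0, 1.5 * WALL.a0):
            da = 1e-7 * WALL.a0
            dpda = (elastic_pressure(a + da, WALL)
                    - elastic_pressure(a - da, WALL)) / (2 * da)
            c_fd = np.sqrt(a / 1.04 * dpda)
            assert wave_speed(a, WALL, rho=1.04) == pytest.approx(
                float(c_fd), rel=1e-6)

    def test_finite_positive_over_physiological_range(self):
        a = np.linspace(0.5, 2.0, 50) * WALL.a0
        c = wave_speed(a, WALL)
        assert np.all(np.isfinite(c)) and np.all(c > 0)


class TestWindkessel:
    BC = WindkesselBC(r1=1e4, r2=4e4, c=1e-6, p_t=units.mmhg_to_cgs(30))

    def test_constant_flow_steady_state(self):
        q = 5e-4
        p = self.BC.p_t
        for _ in range(200_000):
            p = windkessel_update(self.BC, q, p, 1e-5)
        assert p == pytest.approx(self.BC.p_t + (self.BC.r1 + self.BC.r2) * q,
                                  rel=1e-6)

    def test_rc_decay_matches_closed_form(self):
        p0 = units.mmhg_to_cgs(90)
        tau = self.BC.r2 * self.BC.c
        dt = tau / 5000
        p = p0
        for _ in range(5000):  # one time constant
            p = windkessel_update(self.BC, 0.0, p, dt)
        expected = self.BC.p_t + (p0 - self.BC.p_t) / np.e
        assert p == pytest.approx(expected, rel=1e-3)

    def test_c_zero_is_algebraic_resistive_relation(self):
        bc = WindkesselBC(r1=1e4, r2=4e4, c=0.0, p_t=1000.0)
        q = 3.3e-4
        assert windkessel_update(bc, q, 12345.0, 1e-3) == \
            1000.0 + (bc.r1 + bc.r2) * q


class TestFvStep:
    def _uniform_state(self, nc=8, q=0.0):
        return VesselState(a=np.full(nc, WALL.a0), q=np.full(nc, q),
                           dx=0.5, wall=WALL, mu=0.032)

    def test_uniform_steady_state_unchanged(self):
        s = self._uniform_state(q=0.0)
        out = fv_step(s, 1e-4, include_friction=False)
        assert np.array_equal(out.a, s.a)
        assert np.array_equal(out.q, s.q)

    def test_mass_conservation_to_machine_precision(self):
        rng = np.random.default_rng(0)
        a = WALL.a0 * (1 + 0.01 * rng.standard_normal(16))
        s = VesselState(a=a, q=np.zeros(16), dx=0.5, wall=WALL)
        end_l = {"fm": 1e-3, "fmom": 0.0, "p": float(elastic_pressure(a[0], WALL)),
                 "q": 1e-3}
        end_r = {"fm": 4e-4, "fmom": 0.0,
                 "p": float(elastic_pressure(a[-1], WALL)), "q": 4e-4}
        dt = 1e-4
        out = fv_step(s, dt, end_l=end_l, end_r=end_r)
        dv = (out.a - s.a).sum() * s.dx
        flux = (end_l["fm"] - end_r["fm"]) * dt
        assert dv == pytest.approx(flux, rel=1e-12)

    def test_cfl_violation_raises(self):
        s = self._uniform_state()
        with pytest.raises(ValueError, match="CFL"):
            fv_step(s, 1.0)

    def test_positivity_breach_raises(self):
        s = VesselState(a=np.array([WALL.a0]), q=np.array([0.0]), dx=0.5,
                        wall=WALL)
        drain = {"fm": 30.0, "fmom": 0.0, "p": WALL.p0, "q": 30.0}
        fill = {"fm": -30.0, "fmom": 0.0, "p": WALL.p0, "q": -30.0}
        with pytest.raises(FloatingPointError, match="area"):
            fv_step(s, 1e-4, end_l=fill, end_r=drain)

    def test_small_pulse_travels_at_wave_speed(self):
        # linearized right-moving pulse in a long elastic frictionless vessel
        w = WallLaw(**{**WALL.__dict__, "k_m": 0.0})
        nc, dx = 150, 0.2
        x = (np.arange(nc) + 0.5) * dx
        c0 = float(wave_speed(w.a0, w))
        bump = 1e-3 * np.exp(-((x - 6.0) ** 2) / 1.0)
        a = w.a0 * (1 + bump)
        q = c0 * (a - w.a0)
        s = VesselState(a=a, q=q, dx=dx, wall=w)
        dt = 0.5 * dx / c0
        n_steps = 120
        for _ in range(n_steps):
            s = fv_step(s, dt, include_friction=False, wall_model="elastic")
        d = s.a - w.a0
        x1 = float((x * d).sum() / d.sum())
        x0 = 6.0
        speed = (x1 - x0) / (n_steps * dt)
        assert speed == pytest.approx(c0, rel=0.02)


def _equilibrium_case(kind="bifurcation"):
    """Network at exact rest: zero flow, reference areas, identical walls
    everywhere (so the rest pressures match across junctions exactly)."""
    case = make_toy_network(ToyNetworkSpec(kind=kind, pulsatility=0.0,
                                           radius=0.03))
    wall = case.walls[0]
    walls = [wall] * case.tree.n_segments
    bcs = {}
    for tid, bc in case.terminal_bcs.items():
        bcs[tid] = WindkesselBC(r1=bc.r1, r2=bc.r2, c=0.0,
                                p_t=float(elastic_pressure(wall.a0, wall)))
    inflow = InflowBC(q_func=lambda t: 0.0 * np.asarray(t, float), period=1.0)
    case.walls = walls
    return case, bcs, inflow


class TestJunctions:
    def test_static_junction_preserves_rest_state(self):
        # all vessels at reference area, zero flow, venous pressure equal to
        # the rest tube-law pressure: the junction equations are satisfied
        # exactly and the state must not move at all
        case, bcs, inflow = _equilibrium_case()
        sim = Simulator(case.tree, case.walls, bcs, inflow,
                        SolverConfig(include_friction=False))
        a0 = sim.a.copy()
        sim.advance(0.01)
        assert np.array_equal(sim.a, a0)
        assert np.array_equal(sim.q, np.zeros_like(sim.q))

    def test_transparent_series_junction(self):
        case, bcs, inflow = _equilibrium_case(kind="series")
        sim = Simulator(case.tree, case.walls, bcs, inflow,
                        SolverConfig(include_friction=False))
        a0 = sim.a.copy()
        sim.advance(0.005)
        assert np.array_equal(sim.a, a0)

    def test_symmetric_bifurcation_splits_evenly(self):
        case = make_toy_network(ToyNetworkSpec(kind="bifurcation",
                                               pulsatility=0.8, radius=0.03))
        res = run_simulation(case.tree, case.walls, case.terminal_bcs,
                             case.inflow,
                             SolverConfig(n_cycles=2, samples_per_cycle=32))
        t, p, q = res.last_cycle()
        assert np.allclose(q[:, 1], q[:, 2], rtol=1e-9)

    def test_junction_mass_closure(self):
        case = make_toy_network(ToyNetworkSpec(kind="symmetric_tree", depth=2,
                                               pulsatility=0.8, radius=0.03))
        sim = Simulator(case.tree, case.walls, case.terminal_bcs, case.inflow,
                        SolverConfig())
        v0 = sim.total_volume()
        sim.advance(0.25)
        dv = sim.total_volume() - v0
        assert dv == pytest.approx(sim.mass_in - sim.mass_out, abs=1e-14 + 1e-9 * abs(dv))


class TestLocalTimeStepping:
    def test_homogeneous_network_single_level(self):
        case = make_toy_network(ToyNetworkSpec(kind="series", n_segments=3,
                                               pulsatility=0.5, radius=0.03))
        sim = Simulator(case.tree, case.walls, case.terminal_bcs, case.inflow,
                        SolverConfig())
        sim.advance(0.01)
        # identical vessels -> identical local steps
        assert sim.dt_stats["min"] == pytest.approx(sim.dt_stats["max"])

    def test_mixed_sizes_average_dt_between_extremes(self, demo_case):
        sim = Simulator(demo_case.tree, demo_case.walls,
                        demo_case.terminal_bcs, demo_case.inflow,
                        SolverConfig())
        sim.advance(0.02)
        st = sim.dt_stats
        assert st["min"] < st["sum"] / st["n"] < st["max"]

    def test_converges_to_global_minimum_step_run(self):
        # mixed-length bifurcation: the parent runs at a coarser level than
        # the daughters; the local-time-stepping solution must agree with a
        # run forced to the finest global step, with a discrepancy that is
        # small and first order in the coarse step
        spec = ToyNetworkSpec(kind="bifurcation", pulsatility=0.1,
                              radius=0.03, length=1.0)
        case = make_toy_network(spec)
        tree = case.tree.copy()
        # shorten the daughters so their admissible step is ~5x smaller
        tree._dist[1] = tree._prox[1] + 0.2 * (tree._dist[1] - tree._prox[1])
        tree._dist[2] = tree._prox[2] + 0.2 * (tree._dist[2] - tree._prox[2])
        from cortexvasc.ccogen import poiseuille_solve

        poiseuille_solve(tree)
        from cortexvasc.flow1d import build_walls, calibrate_windkessels

        walls = build_walls(tree, case.params)
        bcs = calibrate_windkessels(tree, case.params)

        def diff_at(dt_max):
            local = Simulator(tree, walls, bcs, case.inflow,
                              SolverConfig(dt_max=dt_max))
            glob = Simulator(tree, walls, bcs, case.inflow,
                             SolverConfig(dt_max=dt_max, uniform_level=True))
            local.advance(0.01)
            glob.advance(0.01)
            assert local.dt_stats["max"] > local.dt_stats["min"]
            return (float(np.max(np.abs(local.a - glob.a)))
                    / float(np.max(np.abs(glob.a))))

        d_coarse = diff_at(1e-3)
        d_fine = diff_at(2.5e-4)
        assert d_coarse < 3e-5
        assert d_fine < 0.5 * d_coarse


class TestRunSimulation:
    def test_periodicity_after_ten_cycles(self):
        case = make_toy_network(ToyNetworkSpec(kind="bifurcation",
                                               pulsatility=0.8, radius=0.03))
        res = run_simulation(case.tree, case.walls, case.terminal_bcs,
                             case.inflow,
                             SolverConfig(n_cycles=10, samples_per_cycle=32))
        assert res.periodicity_residual < 1e-3

    def test_km_zero_bitwise_equals_elastic_path(self):
        params = HemoParams(k_m=0.0)
        case = make_toy_network(ToyNetworkSpec(kind="bifurcation",
                                               pulsatility=0.8, radius=0.03,
                                               params=params))
        cfg_v = SolverConfig(n_cycles=1, samples_per_cycle=16)
        cfg_e = SolverConfig(n_cycles=1, samples_per_cycle=16,
                             wall_model="elastic")
        res_v = run_simulation(case.tree, case.walls, case.terminal_bcs,
                               case.inflow, cfg_v)
        res_e = run_simulation(case.tree, case.walls, case.terminal_bcs,
                               case.inflow, cfg_e)
        assert np.array_equal(res_v.p, res_e.p)
        assert np.array_equal(res_v.q, res_e.q)

    def test_missing_windkessel_rejected(self):
        case = make_toy_network(ToyNetworkSpec(kind="bifurcation"))
        with pytest.raises(ValueError, match="Windkessel"):
            Simulator(case.tree, case.walls, {}, case.inflow, SolverConfig())

    def test_viscoelastic_damps_pulse_pressure(self, demo_case):
        # shared demo network: the Kelvin-Voigt wall strictly reduces pulse
        # pressure relative to the purely elastic wall
        cfg = SolverConfig(n_cycles=2, samples_per_cycle=32)
        res_v = run_simulation(demo_case.tree, demo_case.walls,
                               demo_case.terminal_bcs, demo_case.inflow, cfg)
        res_e = run_simulation(demo_case.tree, demo_case.walls,
                               demo_case.terminal_bcs, demo_case.inflow,
                               SolverConfig(n_cycles=2, samples_per_cycle=32,
                                            wall_model="elastic"))
        t, pv, qv = res_v.last_cycle()
        t, pe, qe = res_e.last_cycle()
        pp_v = np.median(pv.max(0) - pv.min(0))
        pp_e = np.median(pe.max(0) - pe.min(0))
        assert pp_e > pp_v
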