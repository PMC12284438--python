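"""1D FSI solver: analytic limits, conservation, convergence, coupling."""

import numpy as np
import pytest

from pulmo1d.solver import (
    SimulationConfig,
    Simulator,
    WindkesselParams,
    boundary_layer_thickness,
    extract_waveforms,
    simulate,
    windkessel_outlet,
)
from pulmo1d.synthetic import TreeGenConfig, generate_inflow, generate_tree
from pulmo1d.tree import VascularTree, VesselSegment
from pulmo1d.waveform import Waveform
from pulmo1d._units import PA_TO_MMHG


def constant_inflow(q=1.0, period=0.2, n=64):
    return Waveform(np.arange(n) * period / n, np.full(n, q), period)


def single_tube(length=1.0, radius=0.2, wall_ratio=0.10):
    return VascularTree((VesselSegment("t", None, length, radius, wall_ratio),))


class TestBoundaryLayer:
    def test_value_and_scaling(self):
        assert boundary_layer_thickness(0.049, 0.5) == pytest.approx(0.06245, rel=1e-3)
        assert boundary_layer_thickness(0.046, 1.0) == pytest.approx(
            np.sqrt(2.0) * boundary_layer_thickness(0.046, 0.5))
        assert boundary_layer_thickness(0.0, 1.0) == 0.0


class TestWindkesselOutlet:
    def test_steady_state_is_q_times_total_resistance(self):
        wk = WindkesselParams(1.0, 1.0, 0.3)
        p = 0.0
        for _ in range(8000):
            p = windkessel_outlet(p, 1.0, 1.0, wk, 1e-3)
        assert p == pytest.approx(2.0, rel=1e-4)

    def test_zero_flow_decay_time_constant(self):
        wk = WindkesselParams(1.0, 1.0, 0.5)  # tau = 0.5 s
        dt = 1e-3
        p = 10.0
        for _ in range(500):  # one time constant
            p = windkessel_outlet(p, 0.0, 0.0, wk, dt)
        # implicit Euler decay (1 + dt/tau)^-n
        assert p == pytest.approx(10.0 * (1 + dt / 0.5) ** -500, rel=1e-12)
        assert p == pytest.approx(10.0 * np.exp(-1.0), rel=1e-2)

    def test_doubling_resistances_doubles_steady_pressure(self):
        p1 = p2 = 0.0
        for _ in range(8000):
            p1 = windkessel_outlet(p1, 1.0, 1.0, WindkesselParams(1, 1, 0.3), 1e-3)
            p2 = windkessel_outlet(p2, 1.0, 1.0, WindkesselParams(2, 2, 0.3), 1e-3)
        assert p2 == pytest.approx(2 * p1, rel=1e-4)

    def test_r1_equals_r2_convention_enforced(self):
        with pytest.raises(ValueError, match="allow_unequal"):
            WindkesselParams(1.0, 2.0, 0.1)
        WindkesselParams(1.0, 2.0, 0.1, allow_unequal=True)


class TestEquilibriaAndLimits:
    def test_rest_state_stays_at_rest(self, control_params):
        tree = single_tube()
        zero = Waveform(np.arange(32) * 0.2 / 32, np.zeros(32), 0.2)
        sim = Simulator(tree, {"t": WindkesselParams(1, 1, 0.1)}, zero, control_params)
        a0 = sim.A.copy()
        for _ in range(50):
            sim.advance_step()
        np.testing.assert_allclose(sim.A, a0, rtol=1e-12)
        np.testing.assert_allclose(sim.Q, 0.0, atol=1e-15)

    def test_steady_outlet_pressure_matches_rcr(self, control_params, fast_config):
        tree = single_tube()
        res = simulate(tree, {"t": WindkesselParams(1.0, 1.0, 0.3)},
                       constant_inflow(1.0), control_params, fast_config)
        p, q = extract_waveforms(res, "t", "distal")
        assert p.mean() == pytest.approx(2.0, rel=5e-3)
        assert res.converged

    def test_inlet_flow_reproduces_waveform(self, control_params, fast_config,
                                            rat_inflow):
        tree = single_tube()
        res = simulate(tree, {"t": WindkesselParams(2.0, 2.0, 0.05)},
                       rat_inflow, control_params, fast_config)
        _, q = extract_waveforms(res, "t", "proximal")
        want = rat_inflow.interp(q.time + 0.5 * (q.time[1] - q.time[0]))
        assert np.max(np.abs(q.values - want)) < 1e-6 * np.max(want)

    def test_near_rigid_tube_friction_drop(self, control_params):
        """Constant flow through a near-rigid tube with a free outflow gives
        a linear axial pressure profile matching the analytic friction drop."""
        from pulmo1d.wall import apply_stiffness_scaling
        stiff = apply_stiffness_scaling(control_params, 100.0)
        tree = single_tube(length=1.0, radius=0.15)
        cfg = SimulationConfig(warm_start=True, cfl=0.8, dt_band=(0.9, 1.3),
                               periodicity_tol=1e-6, dx=0.1)
        res = simulate(tree, {"t": WindkesselParams(0.0, 0.0, 1.0)},
                       constant_inflow(1.0), stiff, cfg)
        # interior cells only: the characteristic boundary closure is first
        # order and perturbs the two end cells
        p = res.P["t"][-1][1:-1]
        x = res.x["t"][1:-1]
        # analytic: dP/dx = -rho (2 pi nu r / delta) Q / A^2, SI
        import math
        nu, rho = 0.046e-4, 1055.0
        delta = math.sqrt(nu * 0.2 / (2 * math.pi))
        r = 0.15e-2
        area = math.pi * r**2
        dpdx = rho * 2 * math.pi * nu * r / delta * 1e-6 / area**2  # Pa/m
        drop_want = dpdx * 1.0e-2 * PA_TO_MMHG  # over 1 cm, in mmHg
        coeff = np.polyfit(x, p, 1)
        drop_got = -coeff[0] * 1.0  # mmHg over the tube length
        assert drop_got == pytest.approx(drop_want, rel=0.01)
        # profile is linear: residual from the line is tiny
        resid = p - np.polyval(coeff, x)
        assert np.max(np.abs(resid)) < 0.01 * drop_want


class TestJunctions:
    def test_symmetric_split_and_mass_defect(self, control_params, fast_config,
                                             small_tree, rat_inflow):
        wk = {t: WindkesselParams(4.0, 4.0, 0.01)
              for t in small_tree.terminal_ids}
        res = simulate(small_tree, wk, rat_inflow, control_params, fast_config)
        qa = extract_waveforms(res, small_tree.terminal_ids[0], "proximal")[1]
        qb = extract_waveforms(res, small_tree.terminal_ids[1], "proximal")[1]
        np.testing.assert_allclose(qa.values, qb.values, atol=1e-9)
        assert res.max_junction_defect < 1e-10  # mL/s
        assert abs(res.volume_balance) < 1e-6

    def test_flow_split_tracks_lumen_area_for_similar_daughters(self, control_params):
        """Mildly asymmetric daughters carry flow roughly in proportion to
        their lumen areas."""
        r1, r2 = 0.15, 0.135
        tree = VascularTree((
            VesselSegment("p", None, 0.6, 0.2),
            VesselSegment("a", "p", 0.45, r1),
            VesselSegment("b", "p", 0.45, r2),
        ))
        wk = {t: WindkesselParams(4.0, 4.0, 0.02) for t in ("a", "b")}
        cfg = SimulationConfig(warm_start=True, cfl=0.8)
        res = simulate(tree, wk, constant_inflow(1.5), control_params, cfg)
        qa = extract_waveforms(res, "a", "proximal")[1].mean()
        qb = extract_waveforms(res, "b", "proximal")[1].mean()
        area_ratio = (r1 / r2) ** 2
        assert qa / qb == pytest.approx(area_ratio, rel=0.25)

    def test_pressure_decreases_along_the_tree(self, control_params,
                                               fast_config, rat_inflow):
        """Mean pressure falls monotonically with generation (friction and
        downstream resistance).  Systolic pressure is deliberately not
        asserted: shallow trees show distal systolic amplification from
        terminal wave reflections."""
        tree = generate_tree(TreeGenConfig(n_generations=3))
        wk = {t: WindkesselParams(8.0, 8.0, 0.005) for t in tree.terminal_ids}
        res = simulate(tree, wk, rat_inflow, control_params, fast_config)
        mean_by_gen = {}
        for s in tree.segments:
            p, _ = extract_waveforms(res, s.id, "mid")
            mean_by_gen.setdefault(tree.generation(s.id), []).append(p.mean())
        means = [np.mean(mean_by_gen[g]) for g in sorted(mean_by_gen)]
        assert all(a > b for a, b in zip(means, means[1:]))


class TestNumerics:
    def test_grid_convergence_of_systolic_pressure(self, control_params, rat_inflow,
                                                   small_tree):
        wk = {t: WindkesselParams(4.0, 4.0, 0.01) for t in small_tree.terminal_ids}
        sys_p = []
        for dx in (0.15, 0.075):
            cfg = SimulationConfig(warm_start=True, cfl=0.8, dx=dx)
            res = simulate(small_tree, wk, rat_inflow, control_params, cfg)
            p, _ = extract_waveforms(res, small_tree.root_id, "proximal")
            sys_p.append(np.max(p.values))
        assert abs(sys_p[1] - sys_p[0]) / sys_p[1] < 0.01

    def test_linear_law_matches_nonlinear_at_small_pulse(self, control_params,
                                                         small_tree):
        """With a small pulse the tangent-matched linear wall gives the same
        MPA pulse pressure as the hyperelastic wall within 2%."""
        inflow = generate_inflow(stroke_volume=0.02)
        wk = {t: WindkesselParams(2.0, 2.0, 0.05) for t in small_tree.terminal_ids}
        pulses = []
        for kind in ("ho", "linear"):
            cfg = SimulationConfig(warm_start=True, cfl=0.8, tube_law_kind=kind)
            res = simulate(small_tree, wk, inflow, control_params, cfg)
            p, _ = extract_waveforms(res, small_tree.root_id, "proximal")
            pulses.append(np.max(p.values) - np.min(p.values))
        assert pulses[0] == pytest.approx(pulses[1], rel=0.02)

    def test_missing_windkessel_rejected(self, control_params, rat_inflow, small_tree):
        with pytest.raises(ValueError, match="Windkessel"):
            simulate(small_tree, {}, rat_inflow, control_params)

    def test_unknown_station_rejected(self, control_params, fast_config, rat_inflow):
        tree = single_tube()
        res = simulate(tree, {"t": WindkesselParams(1, 1, 0.1)}, rat_inflow,
                       control_params, fast_config)
        with pytest.raises(KeyError):
            extract_waveforms(res, "nope")
        with pytest.raises(ValueError):
            extract_waveforms(res, "t", "everywhere")


class TestBackends:
    def test_compiled_kernel_matches_reference_path(self, control_params,
                                                    rat_inflow):
        """The numba cycle kernel and the vectorized numpy reference produce
        the same periodic solution."""
        from dataclasses import replace
        tree = generate_tree(TreeGenConfig(n_generations=3, asymmetry=0.2, seed=6))
        wk = {t: WindkesselParams(8.0, 8.0, 0.004) for t in tree.terminal_ids}
        base = SimulationConfig(warm_start=True, cfl=0.8, n_cycles_max=4,
                                periodicity_tol=1e-12)  # fixed cycle count
        res_k = simulate(tree, wk, rat_inflow, control_params,
                         replace(base, backend="numba"))
        res_n = simulate(tree, wk, rat_inflow, control_params,
                         replace(base, backend="numpy"))
        for sid in (tree.root_id, tree.terminal_ids[0]):
            np.testing.assert_allclose(res_k.P[sid], res_n.P[sid],
                                       rtol=1e-9, atol=1e-9)
            np.testing.assert_allclose(res_k.Q[sid], res_n.Q[sid],
                                       rtol=1e-9, atol=1e-12)


class TestRaisingResistance:
    def test_doubling_terminal_resistance_raises_systolic_pressure(
            self, control_params, fast_config, small_tree, rat_inflow):
        sys_p = []
        for scale in (1.0, 2.0):
            wk = {t: WindkesselParams(4.0 * scale, 4.0 * scale, 0.01)
                  for t in small_tree.terminal_ids}
            res = simulate(small_tree, wk, rat_inflow, control_params, fast_config)
            p, _ = extract_waveforms(res, small_tree.root_id, "proximal")
            sys_p.append(float(np.max(p.values)))
        assert sys_p[1] > sys_p[0]
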