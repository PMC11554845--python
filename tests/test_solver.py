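import numpy as np
import pandas as pd
import pytest

from pulmuq.network import MMHG, MaterialParameters, load_network
from pulmuq.solver import SolverConfig, coupling_convolution, run_simulation
from pulmuq.structured_tree import SpectralGrid, TreeParameters, generate_tree_index, grand_admittance
from pulmuq.waveforms import Waveform, la_pressure, mpa_inflow

from conftest import FAST, N_MODES
from oracles import steady_vessel_drop_oracle


def single_vessel_network(L=5.0, r0=0.5, name="V"):
    """One venous vessel: inflow at x=0, pressure boundary at x=L."""
    df = pd.DataFrame(
        [dict(name=name, length_cm=L, radius_cm=r0, side="venous",
              parent="", daughter1="", daughter2="", terminal_partner="")]
    )
    return load_network(df, inlet=name, venous_outlets=(name,))


def constant_waveforms(q0, p_out, T=0.85, n=512):
    return (
        Waveform(T, np.full(n, q0), "flow"),
        Waveform(T, np.full(n, p_out), "pressure"),
    )


class TestSingleVessel:
    def test_steady_pressure_drop_matches_ode_oracle(self):
        q0, p_out = 60.0, 8.0 * MMHG
        net = single_vessel_network(L=5.0, r0=0.5)
        inflow, la = constant_waveforms(q0, p_out)
        field = run_simulation(net, {}, inflow, la, SolverConfig(dx=0.125))
        p = field.vessel("V", "p")[-1]  # steady profile, last time level
        drop_solver = p[0] - p[-1]
        K = net.materials.K_V
        p_in_oracle = steady_vessel_drop_oracle(q0, 5.0, 0.5, K, p_out)
        drop_oracle = p_in_oracle - p_out
        assert drop_solver == pytest.approx(drop_oracle, rel=5e-3)
        # flow is uniform along the vessel in steady state
        q = field.vessel("V", "q")[-1]
        assert np.allclose(q, q0, rtol=1e-4)

    def test_zero_forcing_stays_at_equilibrium(self):
        p0 = 8.0 * MMHG
        net = single_vessel_network()
        inflow, la = constant_waveforms(0.0, p0)
        field = run_simulation(net, {}, inflow, la, SolverConfig(dx=0.125))
        assert np.abs(field.vessel("V", "q")).max() < 1e-8
        assert np.abs(field.vessel("V", "p") - p0).max() < 1e-6

    def test_wall_law_roundtrip(self):
        # p <-> A closure is monotone and inverts to machine precision
        A0, f = np.pi * 0.81, 4.0 / 3.0 * 8e5
        A = np.linspace(0.2 * A0, 5 * A0, 1000)
        p = f * (np.sqrt(A / A0) - 1.0)
        assert np.all(np.diff(p) > 0)
        A_back = A0 * (1.0 + p / f) ** 2
        assert np.abs(A_back - A).max() < 1e-12 * A0


class TestFullNetwork:
    def test_converged_with_cycle_count(self, nominal_field):
        assert nominal_field.converged
        assert 1 < nominal_field.n_cycles <= 250
        assert nominal_field.cycle_error <= 1.0
        assert nominal_field.cfl_max < 1.0

    def test_global_mass_balance(self, net, nominal_field):
        mpa = nominal_field.midpoint("MPA", "q").mean()
        term = sum(nominal_field.end(a, "q", "L").mean() for a, _ in net.terminal_pairs)
        assert term == pytest.approx(mpa, rel=0.01)

    def test_junction_mass_defect(self, net, nominal_field):
        for par, d1, d2 in net.junctions():
            side = net[par].side
            if side == "arterial":
                qp = nominal_field.end(par, "q", "L")
                qd = nominal_field.end(d1, "q", "0") + nominal_field.end(d2, "q", "0")
            else:
                qp = nominal_field.end(par, "q", "0")
                qd = nominal_field.end(d1, "q", "L") + nominal_field.end(d2, "q", "L")
            assert np.abs(qp - qd).max() <= 1e-10 * np.abs(qp).max()

    def test_junction_pressure_continuity(self, net, nominal_field):
        scale = 4.0 / 3.0 * net.materials.K_A
        for par, d1, d2 in net.junctions():
            side = net[par].side
            xp, xd = ("L", "0") if side == "arterial" else ("0", "L")
            pp = nominal_field.end(par, "p", xp)
            for d in (d1, d2):
                pd_ = nominal_field.end(d, "p", xd)
                assert np.abs(pp - pd_).max() < 1e-6 * scale

    def test_symmetric_daughters_split_evenly(self):
        rows = [
            dict(name="P", length_cm=3.0, radius_cm=1.0, side="arterial",
                 parent="", daughter1="D1", daughter2="D2", terminal_partner=""),
            dict(name="D1", length_cm=2.0, radius_cm=0.7, side="arterial",
                 parent="P", daughter1="", daughter2="", terminal_partner="V1"),
            dict(name="D2", length_cm=2.0, radius_cm=0.7, side="arterial",
                 parent="P", daughter1="", daughter2="", terminal_partner="V2"),
            dict(name="V1", length_cm=2.0, radius_cm=0.7, side="venous",
                 parent="", daughter1="", daughter2="", terminal_partner="D1"),
            dict(name="V2", length_cm=2.0, radius_cm=0.7, side="venous",
                 parent="", daughter1="", daughter2="", terminal_partner="D2"),
        ]
        net = load_network(pd.DataFrame(rows), inlet="P", venous_outlets=("V1", "V2"))
        grid = SpectralGrid(0.85, N_MODES)
        beds = {}
        for a, v in net.terminal_pairs:
            p = TreeParameters(root_radius=net[a].radius)
            beds[a] = grand_admittance(generate_tree_index(p), p, grid)
        field = run_simulation(net, beds, mpa_inflow(0.85), la_pressure(0.85),
                               SolverConfig(**FAST))
        q1 = field.end("D1", "q", "0")
        q2 = field.end("D2", "q", "0")
        qp = field.end("P", "q", "L")
        assert np.allclose(q1, q2, rtol=1e-9, atol=1e-9)
        assert np.allclose(q1 + q2, qp, rtol=1e-10, atol=1e-10)

    def test_energy_sanity(self, nominal_field):
        mean_mpa = nominal_field.midpoint("MPA", "p").mean()
        mean_la = 8.0 * MMHG
        assert mean_mpa > mean_la

    def test_wall_law_consistency_of_outputs(self, net, nominal_field):
        seg = net["LPA"]
        f = 4.0 / 3.0 * net.materials.K_A
        A = nominal_field.vessel("LPA", "A")
        p = nominal_field.vessel("LPA", "p")
        p_from_A = f * (np.sqrt(A / (np.pi * seg.radius**2)) - 1.0)
        assert np.abs(p - p_from_A).max() <= 1e-10 * np.abs(p).max()

    def test_dt_refinement_self_convergence(self, net, nominal_beds):
        inflow, la = mpa_inflow(0.85), la_pressure(0.85)
        coarse = run_simulation(net, nominal_beds, inflow, la,
                                SolverConfig(dx=0.25, dt_target=2.05e-4, max_cycles=250))
        fine = run_simulation(net, nominal_beds, inflow, la,
                              SolverConfig(dx=0.25, dt_target=1.04e-4, max_cycles=250))
        pc = coarse.midpoint("MPA", "p")
        pf = fine.midpoint("MPA", "p")[1 :: 2]
        rms = np.sqrt(np.mean((pc - pf) ** 2)) / np.sqrt(np.mean(pc**2))
        assert rms < 5e-3

    def test_weak_nonlinearity_linear_scaling(self):
        # tiny inflow + stiff walls: pulse pressure scales linearly with inflow
        mats = MaterialParameters(K_A=8e7, K_V=8.5e7)
        pulses = []
        for scale in (0.01, 0.02):
            net = single_vessel_network(L=5.0, r0=0.5)
            net = net.with_materials(mats)
            T = 0.85
            q = mpa_inflow(T, stroke_volume=70.0 * scale, backflow_fraction=0.0)
            la = Waveform(T, np.full(512, 8.0 * MMHG), "pressure")
            # 100x stiffness means ~10x wave speed; shrink dt accordingly
            field = run_simulation(
                net, {}, q, la, SolverConfig(dx=0.25, dt_target=3e-5, max_cycles=250)
            )
            p = field.midpoint("V", "p")
            pulses.append(p.max() - p.min())
        assert pulses[1] / pulses[0] == pytest.approx(2.0, rel=0.02)


class TestCouplingConvolution:
    def test_dc_gain_matches_grand_admittance(self, nominal_beds):
        bed = nominal_beds["RIA D1"]
        n = 4 * bed.kernels.shape[0]
        pA = np.full(n, 2.0e4)
        pV = np.full(n, 1.0e4)
        qa, qv = coupling_convolution(pA, pV, bed.kernels, bed.grid.T)
        expect = (2.0e4 - 1.0e4) / bed.dc_resistance
        assert np.allclose(qa, expect, rtol=1e-8)
        assert np.allclose(qv, expect, rtol=1e-8)  # zero DC shunt: qA = qV

    def test_equal_pressures_give_zero_flow(self, nominal_beds):
        bed = nominal_beds["LIA D1"]
        n = bed.kernels.shape[0]
        pA = pV = np.full(n, 1.5e4)
        qa, qv = coupling_convolution(pA, pV, bed.kernels, bed.grid.T)
        scale = 1.5e4 / bed.dc_resistance
        assert np.abs(qa).max() < 1e-10 * scale
        assert np.abs(qv).max() < 1e-10 * scale

    def test_mean_flow_conservation_in_simulation(self, net, nominal_field):
        # DC two-port has no shunt: cycle-mean artery inflow = vein outflow
        for a, v in net.terminal_pairs:
            qa = nominal_field.end(a, "q", "L").mean()
            qv = nominal_field.end(v, "q", "0").mean()
            assert qv == pytest.approx(qa, rel=5e-3)

    def test_kernel_period_mismatch_rejected(self, nominal_beds):
        bed = nominal_beds["RIA D1"]
        with pytest.raises(ValueError):
            coupling_convolution(np.zeros(1000), np.zeros(1000), bed.kernels, 0.85)
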