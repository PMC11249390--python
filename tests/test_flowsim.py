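"""Network flow: Poiseuille solver oracle checks, stalls, tracer, transit."""

import math

import numpy as np
import pytest
from scipy.stats import spearmanr

from stallflow import (
    DEFAULT_FRACTION_GRID,
    NetworkSpec,
    apply_stalls,
    edge_conductance,
    generate_network,
    measure_transit,
    perturb_pressure,
    simulate_tracer,
    solve_flow,
    sweep_stall_fractions,
    transit_summary,
)
from stallflow.flowsim import MMHG_TO_MPA, rect_bolus

from conftest import make_chain_network


class TestEdgeConductance:
    def test_fourth_power_diameter_law(self):
        assert edge_conductance(60, 8, 2) == pytest.approx(16 * edge_conductance(60, 4, 2))

    def test_inverse_length_law(self):
        assert edge_conductance(120, 4, 2) == pytest.approx(0.5 * edge_conductance(60, 4, 2))

    def test_hand_computed_value(self):
        assert edge_conductance(60, 4, 2) == pytest.approx(math.pi * 256 / (128 * 2 * 60), rel=1e-12)

    @pytest.mark.parametrize("args", [(0, 4, 2), (60, -1, 2), (60, 4, 0)])
    def test_nonpositive_geometry_rejected(self, args):
        with pytest.raises(ValueError):
            edge_conductance(*args)


class TestSolveFlow:
    def test_single_tube_obeys_ohm_analogue(self, single_tube):
        sol = solve_flow(single_tube, viscosity_mPas=2.0)
        g = edge_conductance(60, 4, 2)
        q = abs(next(iter(sol.edge_flows.values())))
        assert q == pytest.approx(g * 10.0 * MMHG_TO_MPA, rel=1e-12)

    def test_series_parallel_matches_closed_form(self, series_parallel):
        """Oracle: hydraulic circuit solved by hand resistor algebra."""
        mu = 2.0
        sol = solve_flow(series_parallel, viscosity_mPas=mu)
        g_art = edge_conductance(100, 10, mu)
        g_cap = edge_conductance(60, 4, mu)
        g_ven = edge_conductance(100, 12, mu)
        g_branch = g_cap / 2  # two capillaries in series
        g_bed = 2 * g_branch  # two branches in parallel
        g_tot = 1.0 / (1.0 / g_art + 1.0 / g_bed + 1.0 / g_ven)
        q_expected = g_tot * (30.0 - 10.0) * MMHG_TO_MPA
        q_in = abs(sol.edge_flows[("in", "a")])
        assert q_in == pytest.approx(q_expected, rel=1e-12)
        # each branch carries half the flow
        assert abs(sol.edge_flows[("a", "m1")]) == pytest.approx(q_expected / 2, rel=1e-12)

    def test_symmetric_branches_have_mirror_pressures(self, series_parallel):
        sol = solve_flow(series_parallel)
        assert sol.pressures_mmHg["m1"] == pytest.approx(sol.pressures_mmHg["m2"], rel=1e-12)

    def test_conservation_residual_small_on_default_lattice(self):
        net = generate_network(NetworkSpec(seed=3))
        sol = solve_flow(net)
        assert sol.conservation_residual(net) <= 1e-9

    def test_pressures_bounded_by_boundary_values(self):
        net = generate_network(NetworkSpec(seed=5))
        sol = solve_flow(net)
        p = np.array(list(sol.pressures_mmHg.values()))
        assert p.min() >= 10.0 - 1e-9 and p.max() <= 60.0 + 1e-9


class TestApplyStalls:
    def test_zero_fraction_changes_nothing(self):
        net = generate_network(NetworkSpec(seed=0))
        stalled, assign = apply_stalls(net, 0.0, seed=1)
        assert assign.blocked_edges == []
        assert all(d.get("stall_factor", 1.0) == 1.0 for *_, d in stalled.graph.edges(data=True))

    def test_blocked_count_rounds(self, single_tube):
        net = generate_network(NetworkSpec(seed=0))
        n_caps = len(net.capillary_edges())
        _, assign = apply_stalls(net, 0.04, seed=2)
        assert len(assign.blocked_edges) == round(0.04 * n_caps)

    def test_determinism(self):
        net = generate_network(NetworkSpec(seed=0))
        _, a1 = apply_stalls(net, 0.05, seed=9)
        _, a2 = apply_stalls(net, 0.05, seed=9)
        assert a1.blocked_edges == a2.blocked_edges

    def test_only_capillaries_blocked(self):
        net = generate_network(NetworkSpec(seed=0))
        stalled, assign = apply_stalls(net, 0.10, seed=4)
        for u, v in assign.blocked_edges:
            assert stalled.graph.edges[u, v]["kind"] == "capillary"

    def test_rounding_to_zero_warns(self, series_parallel):
        with pytest.warns(UserWarning, match="zero blocked"):
            apply_stalls(series_parallel, 0.01, seed=0)


class TestSimulateTracer:
    def test_single_tube_plug_flow_delay(self, single_tube):
        sol = solve_flow(single_tube)
        q = abs(next(iter(sol.edge_flows.values())))
        volume = math.pi * 2.0**2 * 60.0
        tau = volume / q
        dt = tau / 10
        t, conc = simulate_tracer(
            single_tube, sol, lambda tt: rect_bolus(tt, 20 * dt, 5 * dt), dt, 200 * dt
        )
        onset_in = t[np.argmax(conc["in"] > 0)]
        onset_out = t[np.argmax(conc["out"] > 0)]
        assert onset_out - onset_in == pytest.approx(tau, abs=dt)

    def test_two_equal_parallel_paths_no_dispersion(self, series_parallel):
        """Two identical delay lines in parallel behave as one: the outlet
        curve equals the single-path response."""
        sol = solve_flow(series_parallel)
        taus = [
            math.pi * (d["diameter_um"] / 2) ** 2 * d["length_um"] / abs(sol.edge_flows[(u, v)])
            for u, v, d in series_parallel.graph.edges(data=True)
        ]
        dt = min(taus) / 5
        t, conc = simulate_tracer(
            series_parallel, sol, lambda tt: rect_bolus(tt, 20 * dt, 50 * dt), dt, 2000 * dt
        )
        # both mid nodes see identical concentration; outlet mixes two equal
        # delayed copies, so it is itself an undispersed delayed copy
        assert np.allclose(conc["m1"], conc["m2"])
        peak_widths = []
        for node in ("in", "out"):
            c = conc[node]
            peak_widths.append(np.sum(c > 0.5 * c.max()))
        assert abs(peak_widths[0] - peak_widths[1]) <= 1

    def test_tracer_mass_conserved(self, series_parallel):
        sol = solve_flow(series_parallel)
        taus = [
            math.pi * (d["diameter_um"] / 2) ** 2 * d["length_um"] / abs(sol.edge_flows[(u, v)])
            for u, v, d in series_parallel.graph.edges(data=True)
        ]
        dt = min(taus) / 5
        t, conc = simulate_tracer(
            series_parallel, sol, lambda tt: rect_bolus(tt, 10 * dt, 30 * dt), dt, 4000 * dt
        )
        q_in = abs(sol.edge_flows[("in", "a")])
        q_out = abs(sol.edge_flows[("b", "out")])
        mass_in = conc["in"].sum() * dt * q_in
        mass_out = conc["out"].sum() * dt * q_out
        assert mass_out == pytest.approx(mass_in, rel=0.01)

    def test_too_coarse_dt_names_limiting_edge(self, single_tube):
        sol = solve_flow(single_tube)
        with pytest.raises(ValueError, match="fastest edge transit"):
            simulate_tracer(single_tube, sol, lambda tt: rect_bolus(tt), 10.0, 100.0)


class TestMeasureTransit:
    def test_unstalled_network_pair_transits_cluster(self):
        net = generate_network(NetworkSpec(seed=1))
        res, _ = transit_summary(net)
        assert res.n_valid_pairs == 36
        vals = np.array(list(res.pair_transits_s.values()))
        assert vals.std() < 0.5 * vals.mean()

    def test_stalling_increases_mean_transit(self):
        net = generate_network(NetworkSpec(seed=1))
        base, _ = transit_summary(net)
        stalled, _ = apply_stalls(net, 0.10, seed=0)
        res, _ = transit_summary(stalled)
        assert res.mean_transit_s > base.mean_transit_s

    def test_blocking_every_capillary_invalidates_all_pairs(self):
        with pytest.warns(UserWarning, match="< 200"):
            net = generate_network(NetworkSpec(lattice_dims=(4, 4, 4), n_penetrating_per_side=4, seed=0))
        stalled, _ = apply_stalls(net, 1.0, seed=0)
        res, _ = transit_summary(stalled)
        assert res.n_valid_pairs == 0
        assert math.isnan(res.mean_transit_s)


class TestSweep:
    def test_default_grid_has_twelve_fractions(self):
        assert len(DEFAULT_FRACTION_GRID) == 12

    def test_row_count(self):
        net = generate_network(NetworkSpec(seed=0))
        df = sweep_stall_fractions(net, fractions=(0.0, 0.10), n_seeds=2)
        assert len(df) == 4
        assert set(df.columns) >= {"fraction", "seed", "mean_transit_s", "sd_transit_s", "n_valid_pairs"}

    def test_transit_increases_with_fraction_spearman(self):
        net = generate_network(NetworkSpec(seed=2))
        df = sweep_stall_fractions(net, fractions=(0.0, 0.02, 0.05, 0.08, 0.10), n_seeds=3)
        rho, _ = spearmanr(df["fraction"], df["mean_transit_s"])
        assert rho > 0


class TestPerturbPressure:
    def test_identity_scale_preserves_solution(self):
        net = generate_network(NetworkSpec(seed=1))
        s1 = solve_flow(net)
        s2 = solve_flow(perturb_pressure(net, 1.0))
        for e in s1.edge_flows:
            assert s1.edge_flows[e] == pytest.approx(s2.edge_flows[e], rel=1e-12)

    def test_doubling_pressure_doubles_flows(self):
        net = generate_network(NetworkSpec(seed=1))
        s1 = solve_flow(net)
        s2 = solve_flow(perturb_pressure(net, 2.0))
        for e, q in s1.edge_flows.items():
            if abs(q) > 1e-6:
                assert s2.edge_flows[e] == pytest.approx(2 * q, rel=1e-9)

    def test_higher_pressure_reduces_transit_under_stalls(self):
        net = generate_network(NetworkSpec(seed=1))
        stalled, _ = apply_stalls(net, 0.08, seed=1)
        base, _ = transit_summary(stalled)
        boosted, _ = transit_summary(perturb_pressure(stalled, 1.5))
        assert boosted.mean_transit_s < base.mean_transit_s
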