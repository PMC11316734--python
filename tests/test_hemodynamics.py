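"""Poiseuille solver closed forms, dense-solve oracle, bolus transport."""

import math

import numpy as np
import pytest

import retvasc as rv
from retvasc.hemodynamics import (MMHG_TO_PA, M3S_TO_ULMIN, BolusModel,
                                  FlowBoundaryConditions,
                                  mass_conservation_residual)

BC = FlowBoundaryConditions(56.2, 20.0)


def hagen_poiseuille_ul_min(r_um, l_mm, dp_mmhg, mu_mpa_s=3.5):
    """Independent closed-form q = π r⁴ Δp / (8 µ l), in µL/min."""
    r, l = r_um * 1e-6, l_mm * 1e-3
    q = math.pi * r ** 4 * (dp_mmhg * MMHG_TO_PA) / (8 * mu_mpa_s * 1e-3 * l)
    return q * M3S_TO_ULMIN


class TestPoiseuilleClosedForms:
    def test_single_segment_matches_hagen_poiseuille(self):
        net = rv.make_toy_fixture("single-vessel")
        sol = rv.solve_poiseuille(net, BC)
        expect = hagen_poiseuille_ul_min(50.0, 1.0, 36.2)
        assert sol.segment_flow_ul_min[0] == pytest.approx(expect, rel=1e-10)
        assert sol.total_inlet_flow_ul_min == pytest.approx(expect, rel=1e-10)

    def test_parallel_segments_split_evenly(self):
        net = rv.make_toy_fixture("parallel-pair")
        sol = rv.solve_poiseuille(net, BC)
        q = [abs(sol.segment_flow_ul_min[s]) for s in (0, 2)]
        assert q[0] == pytest.approx(q[1], rel=1e-10)
        assert sum(q) == pytest.approx(abs(sol.total_inlet_flow_ul_min),
                                       rel=1e-10)

    def test_series_resistances_add(self):
        net = rv.make_toy_fixture("series-pair")
        sol = rv.solve_poiseuille(net, BC)
        # R_total from the independent closed form
        mu = 3.5e-3
        r1, l1 = 60e-6, 1.0e-3
        r2, l2 = 40e-6, 1.5e-3
        R = 8 * mu * l1 / (math.pi * r1 ** 4) \
            + 8 * mu * l2 / (math.pi * r2 ** 4)
        expect = 36.2 * MMHG_TO_PA / R * M3S_TO_ULMIN
        assert sol.total_inlet_flow_ul_min == pytest.approx(expect, rel=1e-10)

    def test_radius_scaling_law_k4(self):
        net = rv.make_toy_fixture("Y-bifurcation")
        out = net.nodes[2]
        out.kind = "outlet-root"
        net.outlet_id = out.id
        base = rv.solve_poiseuille(net, BC)
        scaled = net.copy()
        for seg in scaled.segments.values():
            seg.radii = seg.radii * 2.0
        sol2 = rv.solve_poiseuille(scaled, BC)
        for sid, q in base.segment_flow_ul_min.items():
            if abs(q) < 1e-12:
                continue
            assert sol2.segment_flow_ul_min[sid] / q == pytest.approx(
                16.0, rel=1e-9)

    def test_reversing_pressures_negates_all_flows(self):
        net = rv.make_toy_fixture("series-pair")
        fwd = rv.solve_poiseuille(net, BC)
        rev = rv.solve_poiseuille(net, FlowBoundaryConditions(20.0, 56.2))
        for sid in net.segments:
            assert rev.segment_flow_ul_min[sid] == pytest.approx(
                -fwd.segment_flow_ul_min[sid], rel=1e-12)

    def test_disconnected_network_named_in_error(self):
        net = rv.make_toy_fixture("single-vessel")
        c = net.add_node([5, 5, 0], "bifurcation")
        d = net.add_node([6, 5, 0], "terminal")
        net.add_segment(c.id, d.id, 20.0, vessel_class="artery")
        with pytest.raises(ValueError, match="disconnected"):
            rv.solve_poiseuille(net, BC)


class TestDenseSolveOracle:
    def random_network(self, seed, n_nodes):
        """Random connected graph with cycles, moderate radius contrast."""
        rng = np.random.default_rng(seed)
        net = rv.VascularNetwork()
        pos = rng.uniform(-5, 5, size=(n_nodes, 2))
        net.add_node([pos[0][0], pos[0][1], 0], "inlet-root")
        for i in range(1, n_nodes):
            net.add_node([pos[i][0], pos[i][1], 0], "bifurcation")
        net.nodes[n_nodes - 1].kind = "outlet-root"
        net.outlet_id = n_nodes - 1
        edges = set()
        for i in range(1, n_nodes):  # spanning tree
            j = int(rng.integers(0, i))
            edges.add((j, i))
        for _ in range(n_nodes // 2):  # extra loops
            a, b = sorted(rng.choice(n_nodes, 2, replace=False))
            if a != b:
                edges.add((int(a), int(b)))
        for a, b in sorted(edges):
            net.add_segment(a, b, float(rng.uniform(10, 60)),
                            vessel_class="artery")
        return net

    @pytest.mark.parametrize("seed,n", [(1, 40), (2, 200), (3, 500)])
    def test_sparse_matches_dense_brute_force(self, seed, n):
        net = self.random_network(seed, n)
        sol = rv.solve_poiseuille(net, BC)
        # independent dense assembly: g = π r⁴ / (8 µ l) per segment
        index = {nid: i for i, nid in enumerate(sorted(net.nodes))}
        L = np.zeros((n, n))
        for seg in net.segments.values():
            r = seg.mean_radius_um * 1e-6
            l = seg.length_mm * 1e-3
            g = math.pi * r ** 4 / (8 * 3.5e-3 * l)
            a, b = index[seg.nodes[0]], index[seg.nodes[1]]
            L[a, a] += g
            L[b, b] += g
            L[a, b] -= g
            L[b, a] -= g
        p = np.zeros(n)
        fixed = [index[net.inlet_id], index[net.outlet_id]]
        p[fixed] = [56.2 * MMHG_TO_PA, 20.0 * MMHG_TO_PA]
        free = [i for i in range(n) if i not in fixed]
        A = L[np.ix_(free, free)]
        b = -L[np.ix_(free, fixed)] @ p[fixed]
        p[free] = np.linalg.solve(A, b)
        for nid, i in index.items():
            assert sol.node_pressure_mmhg[nid] * MMHG_TO_PA == pytest.approx(
                p[i], rel=1e-8, abs=1e-6)

    def test_mass_conserved_on_random_networks(self):
        for seed in range(10):
            net = self.random_network(seed + 10, 60)
            sol = rv.solve_poiseuille(net, BC)
            assert mass_conservation_residual(sol, net) < 1e-8
            # inlet equals outlet
            out_sum = sum(
                (-q if net.segments[s.id].nodes[0] == net.outlet_id else q)
                for s in net.segments_at(net.outlet_id)
                for q in [sol.segment_flow_ul_min[s.id]])
            assert out_sum == pytest.approx(sol.total_inlet_flow_ul_min,
                                            rel=1e-8)


class TestBolus:
    def test_peak_normalised_to_unity(self):
        model = BolusModel()
        t = np.linspace(0, 600, 120001)
        assert np.max(model.concentration(t)) == pytest.approx(1.0, abs=1e-6)

    def test_matches_independent_evaluation(self):
        """Direct evaluation of the fixed-convention formula, written out
        independently of the implementation."""
        model = BolusModel()
        for t in (0.0, 5.0, 10.26, 21.84, 28.92, 60.0, 300.0):
            raw = (0.833 * math.exp(-0.5 * ((t - 0.171 * 60) / 10.0) ** 2)
                   + 0.336 * math.exp(-0.5 * ((t - 0.364 * 60) / 25.0) ** 2))
            if t >= 0.482 * 60:
                raw += 1.064 * math.exp(-(0.043 / 60) * (t - 0.482 * 60))
            assert model.concentration(t) * model._norm == pytest.approx(
                raw, abs=1e-9)

    def test_first_pass_peak_exceeds_second_pass_shoulder(self):
        model = BolusModel()
        assert model.concentration(model.t1_s) > model.concentration(
            model.t2_s - 1e-9)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            rv.bolus_concentration(-1.0)


class TestBolusPropagation:
    def test_single_segment_pure_advection(self):
        net = rv.make_toy_fixture("single-vessel")
        sol = rv.solve_poiseuille(net, BC)
        t = np.linspace(0, 60, 6001)
        tc = rv.propagate_bolus(net, sol, time_s=t)
        transit = net.segments[0].length_mm / abs(
            sol.segment_velocity_mm_s[0])
        assert tc.delays_s[0] == pytest.approx(transit, rel=1e-9)
        model = BolusModel()
        expect = np.where(t >= transit,
                          model.concentration(np.clip(t - transit, 0, None)),
                          0.0)
        np.testing.assert_allclose(tc.curves[0], expect, atol=1e-12)

    def test_symmetric_bifurcation_halves_amplitude(self):
        net = rv.make_toy_fixture("parallel-pair")
        sol = rv.solve_poiseuille(net, BC)
        tc = rv.propagate_bolus(net, sol)
        assert tc.amplitudes[0] == pytest.approx(0.5, rel=1e-9)
        assert tc.amplitudes[2] == pytest.approx(0.5, rel=1e-9)
        assert tc.delays_s[0] == pytest.approx(tc.delays_s[2], rel=1e-9)

    def test_amplitude_conserved_across_branchings(self, mini_connected):
        """Tracer amount partitions with flow: outgoing amplitudes at any
        perfused node sum to the incoming amplitude."""
        net, _, _, _, sol = mini_connected
        tc = rv.propagate_bolus(net, sol)
        # amplitudes at the inlet sum to one; at every perfused interior
        # node amounts in = amounts out
        inlet_amp = sum(tc.amplitudes.get(s.id, 0.0)
                        for s in net.segments_at(net.inlet_id))
        assert inlet_amp == pytest.approx(1.0, rel=1e-9)
        checked = 0
        for nid in net.nodes:
            if nid in (net.inlet_id, net.outlet_id):
                continue
            incoming = outgoing = 0.0
            ok = True
            for seg in net.segments_at(nid):
                if seg.id not in tc.amplitudes:
                    ok = False
                    break
                q = sol.segment_flow_ul_min[seg.id]
                signed = q if seg.nodes[0] == nid else -q
                if signed < 0:
                    incoming += tc.amplitudes[seg.id]
                else:
                    outgoing += tc.amplitudes[seg.id]
            if ok and incoming > 1e-6:
                assert outgoing == pytest.approx(incoming, rel=1e-6)
                checked += 1
        assert checked > 50


class TestArteriovenousDelay:
    def test_uniform_path_delay_is_length_over_velocity(self):
        net = rv.make_toy_fixture("single-vessel")
        sol = rv.solve_poiseuille(net, BC)
        tc = rv.propagate_bolus(net, sol,
                                time_s=np.linspace(0, 60, 60001))
        delay = rv.arteriovenous_delay(tc, net)
        expect = net.segments[0].length_mm / abs(
            sol.segment_velocity_mm_s[0])
        assert delay == pytest.approx(expect, abs=2e-3)

    def test_vanishing_length_gives_zero_delay(self):
        net = rv.VascularNetwork()
        a = net.add_node([0, 0, 0], "inlet-root")
        b = net.add_node([1e-5, 0, 0], "outlet-root")
        net.add_segment(a.id, b.id, 50.0, vessel_class="vein")
        sol = rv.solve_poiseuille(net, BC)
        tc = rv.propagate_bolus(net, sol,
                                time_s=np.linspace(0, 60, 60001))
        assert rv.arteriovenous_delay(tc, net) == pytest.approx(0.0,
                                                                abs=1e-3)
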