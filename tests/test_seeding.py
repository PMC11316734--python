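"""Murray-law bifurcation geometry and L-system seed trees."""

import math

import numpy as np
import pytest

import retvasc as rv
from retvasc.growth import tree_structure

# independently evaluated optimal branching angles (30-digit arithmetic),
# frozen: alpha -> (theta1 small daughter, theta2 large daughter), degrees
ANGLE_ORACLE = {
    1.00: (37.4673112109363719, 37.4673112109363719),
    0.50: (64.5342694938960756, 13.0446707158377039),
    0.25: (78.6787634056738139, 3.5135088943314462),
    0.75: (49.9525602709134829, 25.5056741891595114),
}


class TestBifurcationAngles:
    @pytest.mark.parametrize("alpha", sorted(ANGLE_ORACLE))
    def test_angles_match_independent_evaluation(self, alpha):
        geo = rv.bifurcation_angles(alpha)
        t1, t2 = ANGLE_ORACLE[alpha]
        assert geo.theta1_deg == pytest.approx(t1, abs=1e-9)
        assert geo.theta2_deg == pytest.approx(t2, abs=1e-9)

    def test_symmetric_split_value(self):
        geo = rv.bifurcation_angles(1.0)
        assert geo.theta1_deg == pytest.approx(
            math.degrees(math.acos(2 ** (-1 / 3))), abs=1e-12)

    def test_vanishing_branch_limits(self):
        """α → 0⁺: the tiny branch leaves perpendicular, trunk undeflected."""
        geo = rv.bifurcation_angles(1e-6)
        assert geo.theta1_deg == pytest.approx(90.0, abs=0.01)
        assert geo.theta2_deg == pytest.approx(0.0, abs=0.01)

    def test_smaller_daughter_deflects_more(self):
        for alpha in (0.3, 0.5, 0.7, 0.9):
            geo = rv.bifurcation_angles(alpha)
            assert geo.theta1_deg > geo.theta2_deg
            assert 0 <= geo.theta2_deg <= geo.theta1_deg <= 90

    def test_alpha_out_of_range_rejected(self):
        for alpha in (0.0, -0.5, 1.5):
            with pytest.raises(ValueError):
                rv.bifurcation_angles(alpha)


class TestMurrayRadii:
    def test_symmetric_gamma3(self):
        rl, rs = rv.murray_daughter_radii(100.0, 1.0, 3.0)
        assert rl == rs == pytest.approx(100.0 / 2 ** (1 / 3))

    def test_symmetric_gamma2(self):
        rl, rs = rv.murray_daughter_radii(100.0, 1.0, 2.0)
        assert rl == pytest.approx(100.0 / math.sqrt(2))

    def test_asymmetric_against_root_finder_oracle(self):
        # frozen from an independent brentq solve of the two-equation system
        rl, rs = rv.murray_daughter_radii(100.0, 0.6, 2.4)
        assert rl == pytest.approx(89.8327959954903, abs=1e-9)
        assert rs == pytest.approx(53.8996775972942, abs=1e-9)

    def test_conservation_and_ratio_hold(self):
        for alpha in (0.4, 0.65, 1.0):
            for gamma in (2.0, 2.4, 3.0):
                rl, rs = rv.murray_daughter_radii(80.0, alpha, gamma)
                assert rl ** gamma + rs ** gamma == pytest.approx(
                    80.0 ** gamma, rel=1e-12)
                assert rs / rl == pytest.approx(alpha, rel=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            rv.murray_daughter_radii(-1.0, 0.5, 3.0)
        with pytest.raises(ValueError):
            rv.murray_daughter_radii(10.0, 0.5, 0.0)


class TestMurrayGeometryProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(alpha=st.floats(1e-3, 1.0), gamma=st.floats(1.5, 4.0),
           parent=st.floats(1.0, 200.0))
    @settings(deadline=None, derandomize=True, max_examples=200)
    def test_murray_split_conserves_and_orders(self, alpha, gamma, parent):
        rl, rs = rv.murray_daughter_radii(parent, alpha, gamma)
        assert 0 < rs <= rl <= parent
        assert rl ** gamma + rs ** gamma == pytest.approx(parent ** gamma,
                                                          rel=1e-9)

    @given(alpha=st.floats(1e-3, 1.0))
    @settings(deadline=None, derandomize=True, max_examples=200)
    def test_angles_are_valid_and_monotone(self, alpha):
        geo = rv.bifurcation_angles(alpha)
        assert 0.0 <= geo.theta2_deg <= geo.theta1_deg <= 90.0 + 1e-9


class TestSeedNetwork:
    def test_unbounded_domain_full_generations(self, params):
        net = rv.grow_seed_network(params, None, rv.stage_rng(0, "seeding"))
        terminals = [n for n in net.nodes.values() if n.kind == "terminal"]
        assert len(terminals) == 2 * 2 ** int(params["seed_generations"])

    def test_fixed_seed_reproducible(self, params):
        a = rv.grow_seed_network(params, None, rv.stage_rng(3, "seeding"))
        b = rv.grow_seed_network(params, None, rv.stage_rng(3, "seeding"))
        assert len(a.segments) == len(b.segments)
        for sid in a.segments:
            np.testing.assert_array_equal(a.segments[sid].path,
                                          b.segments[sid].path)
            np.testing.assert_array_equal(a.segments[sid].radii,
                                          b.segments[sid].radii)

    def test_radii_non_increasing_towards_terminals(self, params):
        net = rv.grow_seed_network(params, None, rv.stage_rng(0, "seeding"))
        for cls in ("artery", "vein"):
            t = tree_structure(net, cls)
            for nid, parent in t.parent_node.items():
                if parent not in t.parent_seg:
                    continue
                r_child = net.segments[t.parent_seg[nid]].mean_radius_um
                r_parent = net.segments[t.parent_seg[parent]].mean_radius_um
                assert r_child <= r_parent + 1e-9

    def test_murray_relation_exact_at_every_bifurcation(self, params):
        net = rv.grow_seed_network(params, None, rv.stage_rng(1, "seeding"))
        gamma = params["murray_exponent"]
        checked = 0
        for cls in ("artery", "vein"):
            t = tree_structure(net, cls)
            for nid, kids in t.children.items():
                if len(kids) != 2 or nid not in t.parent_seg:
                    continue
                rp = net.segments[t.parent_seg[nid]].mean_radius_um
                r1, r2 = (net.segments[t.parent_seg[c]].mean_radius_um
                          for c in kids)
                assert r1 ** gamma + r2 ** gamma == pytest.approx(
                    rp ** gamma, rel=1e-9)
                checked += 1
        assert checked > 20

    def test_angle_noise_is_zero_mean_with_configured_sd(self, params):
        """Residual branch-angle noise over many bifurcations: mean ≈ 0,
        sd ≈ the configured 5°."""
        residuals = []
        for seed in range(30):
            net = rv.grow_seed_network(params, None,
                                       rv.stage_rng(seed, "seeding"))
            for cls in ("artery", "vein"):
                t = tree_structure(net, cls)
                for nid, kids in t.children.items():
                    parent = t.parent_node.get(nid)
                    if len(kids) != 2 or parent is None \
                            or t.parent_node.get(parent) is None:
                        continue
                    u = (net.nodes[nid].position
                         - net.nodes[parent].position)[:2]
                    u /= np.linalg.norm(u)
                    segs = [net.segments[t.parent_seg[c]] for c in kids]
                    radii = [s.mean_radius_um for s in segs]
                    alpha = min(radii) / max(radii)
                    geo = rv.bifurcation_angles(alpha)
                    expect = {segs[int(np.argmax(radii))].id: geo.theta2_deg,
                              segs[int(np.argmin(radii))].id: geo.theta1_deg}
                    for c in kids:
                        s = net.segments[t.parent_seg[c]]
                        v = (net.nodes[c].position
                             - net.nodes[nid].position)[:2]
                        v /= np.linalg.norm(v)
                        ang = math.degrees(
                            math.acos(float(np.clip(u @ v, -1, 1))))
                        residuals.append(ang - expect[s.id])
        residuals = np.array(residuals)
        assert len(residuals) > 500
        sd = params["branch_angle_noise_sd_deg"]
        assert abs(residuals.mean()) < 3 * sd / math.sqrt(len(residuals))
        assert residuals.std() == pytest.approx(sd, rel=0.15)

    def test_first_branches_straddle_midline(self, params):
        net = rv.grow_seed_network(params, None, rv.stage_rng(0, "seeding"))
        for cls, root in (("artery", net.inlet_id), ("vein", net.outlet_id)):
            t = tree_structure(net, cls)
            top = t.children[root][0]
            gen1 = t.children[top]
            ys = [net.nodes[c].position[1] - net.nodes[top].position[1]
                  for c in gen1]
            assert len(gen1) == 2
            assert min(ys) < 0 < max(ys)
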