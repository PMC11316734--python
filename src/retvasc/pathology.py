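"""Pathology perturbations: retinal vein occlusion and diabetic retinopathy.

RVO is modelled by narrowing a large vein at a random artery-vein crossover
(default 80% diameter reduction) and re-solving the flow; the summed flow
decrease over the vein's drainage territory quantifies the perfusion
deficit.  DR is modelled as progressive batches of full arteriolar
occlusions (radius < 35 µm), starting in the periphery (> 1 cm from the
macula centre) and moving inward; non-perfused vessels are pruned after
each batch, carving out regions of ischaemia.
"""

from __future__ import annotations

import logging

import numpy as np

from .domain import RetinaDomain
from .growth import find_crossings, tree_structure
from .hemodynamics import FlowBoundaryConditions, FlowSolution, solve_poiseuille
from .vascular_graph import VascularNetwork

log = logging.getLogger(__name__)


def restrict_to_inlet_component(net: VascularNetwork) -> VascularNetwork:
    """Drop nodes/segments not connected to the inlet (in place)."""
    seen = {net.inlet_id}
    stack = [net.inlet_id]
    while stack:
        nid = stack.pop()
        for other, _ in net.neighbors(nid):
            if other not in seen:
                seen.add(other)
                stack.append(other)
    for sid in [s for s, seg in net.segments.items()
                if seg.nodes[0] not in seen or seg.nodes[1] not in seen]:
        net.remove_segment(sid)
    for nid in [n for n in net.nodes if n not in seen]:
        if not net._adj.get(nid):
            net._adj.pop(nid, None)
            net.nodes.pop(nid, None)
    return net


def prune_nonperfused(net: VascularNetwork, sol: FlowSolution,
                      flow_threshold_ul_min: float = 1e-4) -> VascularNetwork:
    """Remove segments whose |flow| is below the threshold (in place).

    Afterwards every surviving segment carried at least the threshold flow
    in the supplied solution, so it lay on an inlet→outlet path.  If pruning
    disconnects the inlet from the outlet the network is reported as fully
    ischaemic in metadata (and logged) rather than raising.
    """
    doomed = [sid for sid in net.segments
              if abs(sol.segment_flow_ul_min.get(sid, 0.0)) < flow_threshold_ul_min]
    for sid in doomed:
        net.remove_segment(sid)
    restrict_to_inlet_component(net)
    connected = False
    seen = {net.inlet_id}
    stack = [net.inlet_id]
    while stack:
        nid = stack.pop()
        if nid == net.outlet_id:
            connected = True
            break
        for other, _ in net.neighbors(nid):
            if other not in seen:
                seen.add(other)
                stack.append(other)
    if not connected:
        log.warning("prune_nonperfused: inlet and outlet disconnected "
                    "(fully ischaemic network)")
        net.metadata["fully_ischaemic"] = True
    return net


def _vein_crossing_candidates(net: VascularNetwork,
                              crossing_scale: float = 2.0) -> list[int]:
    """Vein segments in the top radius quartile with an artery crossing
    within crossing_scale × the sum of radii."""
    vein_radii = sorted(s.mean_radius_um for s in net.segments.values()
                        if s.vessel_class == "vein")
    if not vein_radii:
        return []
    q75 = vein_radii[int(0.75 * (len(vein_radii) - 1))]
    cands = set()
    for a, b in find_crossings(net, classes=("artery", "vein"),
                               same_class_only=False,
                               threshold_scale=crossing_scale):
        sa, sb = net.segments[a], net.segments[b]
        for s in (sa, sb):
            if s.vessel_class == "vein" and s.mean_radius_um >= q75 \
                    and {sa.vessel_class, sb.vessel_class} == {"artery", "vein"}:
                cands.add(s.id)
    return sorted(cands)


def occlude_segment(net: VascularNetwork, sid: int,
                    reduction_fraction: float) -> None:
    """Narrow a segment's diameter by the given fraction (1 = full block)."""
    if not (0.0 <= reduction_fraction <= 1.0):
        raise ValueError("reduction fraction must lie in [0, 1]")
    seg = net.segments[sid]
    if reduction_fraction >= 1.0:
        net.remove_segment(sid)
    else:
        seg.radii = seg.radii * (1.0 - reduction_fraction)
        seg.meta["occluded"] = reduction_fraction


def apply_rvo(net: VascularNetwork, sol: FlowSolution,
              bc: FlowBoundaryConditions, rng: np.random.Generator,
              reduction: float = 0.8):
    """Occlude a random artery-vein crossover on a large retinal vein.

    Returns (perturbed network, new flow solution, regional flow decrease in
    µL/min summed over the vein segments draining through the occlusion).
    """
    cands = _vein_crossing_candidates(net)
    if not cands:
        raise ValueError("no artery-vein crossing on a major vein")
    sid = int(rng.choice(cands))
    out = net.copy()
    occlude_segment(out, sid, reduction)
    new_sol = solve_poiseuille(out, bc)

    # drainage territory: the vein subtree distal to the occluded segment
    t = tree_structure(net, "vein")
    a, b = net.segments[sid].nodes
    distal = b if t.parent_node.get(b) == a else a
    territory = [sid]
    stack = [distal]
    while stack:
        nid = stack.pop()
        for child in t.children.get(nid, ()):
            territory.append(t.parent_seg[child])
            stack.append(child)
    delta = sum(abs(sol.segment_flow_ul_min[s])
                - abs(new_sol.segment_flow_ul_min.get(s, 0.0))
                for s in territory)
    out.metadata["rvo_segment"] = sid
    out.metadata["rvo_reduction"] = reduction
    return out, new_sol, float(delta)


def apply_dr_progression(net: VascularNetwork, bc: FlowBoundaryConditions,
                         domain: RetinaDomain, rng: np.random.Generator,
                         radius_threshold_um: float = 35.0,
                         batch_size: int = 5,
                         schedule_mm: tuple = (10.0, 7.5, 5.0, 2.5),
                         prune_threshold_ul_min: float = 1e-4):
    """Progressive arteriolar occlusion batches, periphery first.

    Per schedule distance, ``batch_size`` arterioles (artery segments with
    radius below the threshold, at least that far from the macula centre)
    are drawn uniformly and fully occluded; non-perfused vessels are pruned
    and the (network, flow solution) state appended.  The sequence ends
    early when no candidate arterioles remain.
    """
    states = []
    current = net.copy()
    mac = domain.macula_centre[:2]
    for min_dist in schedule_mm:
        cands = []
        for sid, seg in current.segments.items():
            if seg.vessel_class != "artery":
                continue
            if seg.mean_radius_um >= radius_threshold_um:
                continue
            mid = 0.5 * (seg.path[0][:2] + seg.path[-1][:2])
            if np.linalg.norm(mid - mac) > min_dist:
                cands.append(sid)
        if not cands:
            break
        chosen = rng.choice(sorted(cands),
                            size=min(batch_size, len(cands)), replace=False)
        for sid in chosen:
            occlude_segment(current, int(sid), 1.0)
        restrict_to_inlet_component(current)
        if current.outlet_id not in current.nodes:
            log.warning("apply_dr_progression: outlet lost; stopping")
            break
        sol = solve_poiseuille(current, bc)
        prune_nonperfused(current, sol, prune_threshold_ul_min)
        if current.metadata.get("fully_ischaemic"):
            break
        sol = solve_poiseuille(current, bc)
        current.metadata.setdefault("dr_occlusions", []).extend(
            int(s) for s in chosen)
        states.append((current.copy(), sol))
    return states
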