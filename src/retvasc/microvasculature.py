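"""Closing the circulation: capillary beds and artery-vein crossings.

The grown arterial and venous trees are joined through a capillary bed so
that the complete network carries flow from the single inlet to the single
outlet.  Two constructions are available: the edges of a Voronoi diagram of
random seed points (default), or a 2-D space-colonization growth toward
attractor points.  In-plane artery-vein collisions are resolved with smooth
out-of-plane excursions of the smaller vessel; terminal beds can be
interdigitated by removing the low-flow side of small-calibre crossings.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import Voronoi, cKDTree

from .domain import RetinaDomain
from .growth import find_crossings, _seg_seg_distance_2d
from .vascular_graph import VascularNetwork, dense_points, resample_path

log = logging.getLogger(__name__)


@dataclass
class CapillaryBedSpec:
    method: str = "voronoi"              # "voronoi" | "space-colonization"
    capillary_radius_um: float = 4.0
    seed_density_mm2: float = 25.0       # Voronoi seed points per mm²
    attraction_radius_um: float = 400.0  # colonization
    kill_radius_um: float = 120.0
    step_um: float = 100.0

    def __post_init__(self):
        if self.capillary_radius_um <= 0 or self.seed_density_mm2 <= 0:
            raise ValueError("capillary radius and seed density must be positive")


def terminal_nodes(net: VascularNetwork, cls: str) -> list[int]:
    """Leaf nodes of one tree (degree-1 nodes on a segment of that class)."""
    out = []
    for nid, node in net.nodes.items():
        if node.kind != "terminal" or net.degree(nid) != 1:
            continue
        if net.segments_at(nid)[0].vessel_class == cls:
            out.append(nid)
    return sorted(out)


def _sample_points_in_domain(domain: RetinaDomain, n: int,
                             rng: np.random.Generator) -> np.ndarray:
    pts = []
    c = domain.disc_centre[:2]
    R = domain.retina_radius_mm
    while len(pts) < n:
        cand = c + rng.uniform(-R, R, size=(4 * n, 2))
        p3 = np.column_stack([cand, np.zeros(len(cand))])
        ok = domain.in_retina(p3) & ~domain.in_fovea(p3)
        pts.extend(cand[ok][: n - len(pts)])
    return np.array(pts)


def build_capillary_bed_voronoi(net: VascularNetwork, domain: RetinaDomain,
                                spec: CapillaryBedSpec,
                                rng: np.random.Generator,
                                arterial_terminals=None,
                                venous_terminals=None) -> list[int]:
    """Connect the trees through the edge graph of a Voronoi diagram.

    Seed points are sampled uniformly over the retina disc (fovea excluded);
    Voronoi edges inside the domain become capillary segments; dead-end
    vertices are pruned and only the largest connected capillary component
    kept; every arterial and venous terminal then connects to its nearest
    surviving vertex, so each terminal ends with degree 2 and the network has
    an inlet→outlet path.  Returns the created segment ids.
    """
    a_term = arterial_terminals or terminal_nodes(net, "artery")
    v_term = venous_terminals or terminal_nodes(net, "vein")
    if not a_term or not v_term:
        raise ValueError("both terminal sets must be nonempty")
    usable = math.pi * domain.retina_radius_mm ** 2
    n_seeds = max(4, int(round(spec.seed_density_mm2 * usable)))
    seeds = _sample_points_in_domain(domain, n_seeds, rng)
    if len(seeds) < 3:
        raise ValueError("fewer than 3 capillary seed points")
    vor = Voronoi(seeds)
    verts = vor.vertices
    p3 = np.column_stack([verts, np.zeros(len(verts))])
    v_ok = domain.in_retina(p3) & ~domain.in_fovea(p3)

    # adjacency over kept vertices
    adj: dict[int, set[int]] = {}
    edges = set()
    for (i, j) in vor.ridge_vertices:
        if i < 0 or j < 0 or not (v_ok[i] and v_ok[j]):
            continue
        # the edge itself must clear the fovea
        mid = 0.5 * (verts[i] + verts[j])
        if domain.in_fovea(np.array([[mid[0], mid[1], 0.0]]))[0]:
            continue
        edges.add((min(i, j), max(i, j)))
        adj.setdefault(i, set()).add(j)
        adj.setdefault(j, set()).add(i)

    # iteratively prune dead-end vertices
    changed = True
    while changed:
        changed = False
        for v in list(adj):
            if len(adj[v]) <= 1:
                for u in adj[v]:
                    adj[u].discard(v)
                    edges.discard((min(u, v), max(u, v)))
                del adj[v]
                changed = True
    if not adj:
        raise ValueError("capillary bed empty after pruning; "
                         "increase seed density")
    # keep largest connected component
    comp_of = {}
    comp_id = 0
    for v in adj:
        if v in comp_of:
            continue
        stack = [v]
        comp_of[v] = comp_id
        while stack:
            u = stack.pop()
            for w in adj[u]:
                if w not in comp_of:
                    comp_of[w] = comp_id
                    stack.append(w)
        comp_id += 1
    sizes = np.bincount(list(comp_of.values()))
    main = int(np.argmax(sizes))
    kept = {v for v in adj if comp_of[v] == main}

    node_of = {}
    created = []
    for v in sorted(kept):
        node_of[v] = net.add_node(
            np.array([verts[v][0], verts[v][1], 0.0]), "interior").id
    for (i, j) in sorted(edges):
        if i in kept and j in kept:
            seg = net.add_segment(node_of[i], node_of[j],
                                  spec.capillary_radius_um,
                                  vessel_class="capillary")
            created.append(seg.id)
    kept_list = sorted(kept)
    kd = cKDTree(verts[kept_list])
    for t in (*a_term, *v_term):
        p = net.nodes[t].position[:2]
        _, idx = kd.query(p)
        seg = net.add_segment(t, node_of[kept_list[int(idx)]],
                              spec.capillary_radius_um,
                              vessel_class="capillary")
        created.append(seg.id)
    net.metadata["capillary_method"] = "voronoi"
    return created


def build_capillary_bed_colonization(net: VascularNetwork,
                                     terminals: list[int],
                                     spec: CapillaryBedSpec,
                                     rng: np.random.Generator,
                                     attractors: np.ndarray | None = None,
                                     domain: RetinaDomain | None = None,
                                     max_iter: int = 500) -> list[int]:
    """Grow capillary twigs from terminals toward attractor points.

    Classic 2-D space colonization: every live attractor pulls its nearest
    grown node (within the attraction radius); each pulled node extends one
    step along the mean attractor direction; attractors within the kill
    radius of any node die.  Stops when all attractors are killed or no
    growth occurs (a max-iteration guard is logged if hit).
    """
    if not terminals:
        raise ValueError("terminals must be nonempty")
    if spec.attraction_radius_um <= spec.kill_radius_um:
        raise ValueError("attraction radius must exceed kill radius")
    if attractors is None:
        if domain is None:
            return []
        usable = math.pi * domain.retina_radius_mm ** 2
        n = max(1, int(round(spec.seed_density_mm2 * usable)))
        attractors = _sample_points_in_domain(domain, n, rng)
    attractors = np.atleast_2d(np.asarray(attractors, float))[:, :2]
    if len(attractors) == 0:
        return []
    attract_mm = spec.attraction_radius_um / 1000.0
    kill_mm = spec.kill_radius_um / 1000.0
    step_mm = spec.step_um / 1000.0

    node_ids = list(terminals)
    node_pos = [net.nodes[t].position[:2] for t in terminals]
    alive = np.ones(len(attractors), dtype=bool)
    created = []
    for it in range(max_iter):
        pos = np.array(node_pos)
        kd = cKDTree(pos)
        d, nearest = kd.query(attractors[alive])
        # kill attractors already reached
        live_idx = np.flatnonzero(alive)
        reached = d <= kill_mm
        alive[live_idx[reached]] = False
        if not alive.any():
            break
        d, nearest = d[~reached], nearest[~reached]
        live_idx = live_idx[~reached]
        pulls: dict[int, list[np.ndarray]] = {}
        for ai, ni, dist in zip(live_idx, nearest, d):
            if dist <= attract_mm:
                v = attractors[ai] - pos[ni]
                pulls.setdefault(int(ni), []).append(v / (np.linalg.norm(v) or 1))
        if not pulls:
            break
        for ni in sorted(pulls):
            direction = np.mean(pulls[ni], axis=0)
            nrm = np.linalg.norm(direction)
            if nrm == 0:
                continue
            new2 = pos[ni] + step_mm * direction / nrm
            if domain is not None:
                p3 = np.array([[new2[0], new2[1], 0.0]])
                if not domain.in_retina(p3)[0] or domain.in_fovea(p3)[0]:
                    continue
            node = net.add_node(np.array([new2[0], new2[1], 0.0]), "interior")
            seg = net.add_segment(node_ids[ni], node.id,
                                  spec.capillary_radius_um,
                                  vessel_class="capillary")
            created.append(seg.id)
            node_ids.append(node.id)
            node_pos.append(new2)
    else:
        log.warning("space colonization hit max_iter=%d", max_iter)
    net.metadata["capillary_method"] = "space-colonization"
    return created


# -- artery-vein crossing resolution ---------------------------------------

def _crossing_param(seg, other, spacing_mm: float = 0.02):
    """Arclength position (mm) along ``seg`` of the closest xy approach to
    ``other`` (dense-sampled nearest-pair query)."""
    pa = dense_points(seg.path, spacing_mm)
    pb = dense_points(other.path, spacing_mm)
    kd = cKDTree(pb[:, :2])
    d, _ = kd.query(pa[:, :2])
    idx = int(np.argmin(d))
    x = np.concatenate([[0.0], np.cumsum(
        np.linalg.norm(np.diff(pa, axis=0), axis=1))])
    return float(x[idx])


def _lift_interval(seg, x_lo: float, x_hi: float, amp_mm: float,
                   spacing_mm: float, pin_start: bool = True,
                   pin_end: bool = True) -> None:
    """Displace the arclength window [x_lo, x_hi] of a path in z by a smooth
    trapezoid of height amp_mm (sign included); the window ramps over one
    window-width margin and tapers to zero at pinned path endpoints.
    Endpoints at free (terminal) nodes may be released via pin_start/end."""
    path, radii = resample_path(seg.path, seg.radii, spacing_mm)
    x = np.concatenate([[0.0], np.cumsum(
        np.linalg.norm(np.diff(path, axis=0), axis=1))])
    L = x[-1]
    ramp = max(1e-6, min(0.5 * (x_hi - x_lo) + 1e-6, 0.25))
    inside = np.clip(np.minimum(x - (x_lo - ramp), (x_hi + ramp) - x)
                     / ramp, 0.0, 1.0)
    w = 0.5 * (1 - np.cos(math.pi * inside))
    if pin_start:
        w = w * np.clip(x / ramp, 0.0, 1.0)
    if pin_end:
        w = w * np.clip((L - x) / ramp, 0.0, 1.0)
    ends = (seg.path[0].copy(), seg.path[-1].copy())
    path[:, 2] = path[:, 2] + amp_mm * w
    if pin_start:
        path[0] = ends[0]
    if pin_end:
        path[-1] = ends[1]
    seg.path, seg.radii = path, radii


def _violating_interval(seg, other, clearance_mm: float,
                        spacing_mm: float = 0.02):
    """Arclength window of ``seg`` whose xy distance to ``other`` is below
    the clearance, or None."""
    pa = dense_points(seg.path, spacing_mm)
    pb = dense_points(other.path, spacing_mm)
    kd = cKDTree(pb[:, :2])
    d, _ = kd.query(pa[:, :2])
    mask = d < clearance_mm
    if not mask.any():
        return None
    x = np.concatenate([[0.0], np.cumsum(
        np.linalg.norm(np.diff(pa, axis=0), axis=1))])
    return float(x[mask].min()), float(x[mask].max())


def resolve_av_crossings(net: VascularNetwork,
                         clearance_margin: float = 1.1,
                         max_passes: int = 6) -> VascularNetwork:
    """Separate artery-vein crossings with out-of-plane excursions.

    Wherever an artery and a vein approach within the sum of their radii
    in-plane, the artery's violating stretch is lifted anteriorly (+z) and
    the vein's pushed posteriorly (−z) by smooth trapezoidal excursions, so
    the pair clears the sum of radii; branch endpoints are never displaced
    (those stretches are cleared by the partner's excursion instead).
    Opposite displacement directions keep independently lifted vessels from
    colliding with each other; passes repeat until the all-pairs 3-D
    clearance check passes, with any survivors logged.
    """
    n_resolved = 0
    for _pass in range(max_passes):
        crossings = [
            (a, b) for a, b in
            find_crossings(net, classes=("artery", "vein"),
                           same_class_only=False)
            if net.segments[a].vessel_class != net.segments[b].vessel_class
            and _min_pair_distance_3d(net.segments[a], net.segments[b])
            < (net.segments[a].mean_radius_um
               + net.segments[b].mean_radius_um) / 1000.0 - 1e-12]
        if not crossings:
            break
        amp_scale = clearance_margin * (1.0 + 0.5 * _pass)
        for sid_a, sid_b in crossings:
            sa, sb = net.segments[sid_a], net.segments[sid_b]
            art, vein = (sa, sb) if sa.vessel_class == "artery" else (sb, sa)
            clearance = (sa.mean_radius_um + sb.mean_radius_um) / 1000.0
            if _min_pair_distance_3d(art, vein) >= clearance - 1e-9:
                continue
            spacing = min(0.02, clearance / 2.0)
            for seg, other, sign in ((art, vein, +1.0), (vein, art, -1.0)):
                window = _violating_interval(seg, other, clearance, spacing)
                if window is None:
                    continue
                pin = []
                for end_node in seg.nodes:
                    node = net.nodes[end_node]
                    pin.append(node.kind != "terminal")
                before = (seg.path[0].copy(), seg.path[-1].copy())
                _lift_interval(seg, window[0], window[1],
                               sign * 0.6 * amp_scale * clearance, spacing,
                               pin_start=pin[0], pin_end=pin[1])
                # released terminal endpoints drag their node (and any
                # attached capillary link ends) along
                for k, end_node in enumerate(seg.nodes):
                    new_pos = seg.path[0 if k == 0 else -1]
                    if pin[k] or np.allclose(new_pos, before[k]):
                        continue
                    net.nodes[end_node].position = new_pos.copy()
                    for s2 in net.segments_at(end_node):
                        if s2.id == seg.id:
                            continue
                        p2 = s2.path.copy()
                        if s2.nodes[0] == end_node:
                            p2[0] = new_pos
                        if s2.nodes[1] == end_node:
                            p2[-1] = new_pos
                        s2.path = p2
            n_resolved += 1
    leftovers = [
        (a, b) for a, b in find_crossings(net, classes=("artery", "vein"),
                                          same_class_only=False)
        if net.segments[a].vessel_class != net.segments[b].vessel_class
        and _min_pair_distance_3d(net.segments[a], net.segments[b])
        < (net.segments[a].mean_radius_um
           + net.segments[b].mean_radius_um) / 1000.0 - 1e-9]
    if leftovers:
        log.warning("resolve_av_crossings: %d crossings below clearance "
                    "after %d passes", len(leftovers), max_passes)
        net.metadata["av_crossings_unresolved"] = len(leftovers)
    net.metadata["av_crossings_resolved"] = n_resolved
    return net


def _min_pair_distance_3d(sa, sb) -> float:
    pa = dense_points(sa.path, 0.02)
    pb = dense_points(sb.path, 0.02)
    kd = cKDTree(pb)
    d, _ = kd.query(pa)
    return float(np.min(d))


def min_av_distance(net: VascularNetwork) -> float:
    """Brute-force minimum 3-D distance between artery and vein segments
    that approach within the sum of their radii in-plane (oracle helper)."""
    worst = np.inf
    pairs = [(a, b) for a, b in
             find_crossings(net, classes=("artery", "vein"),
                            same_class_only=False)
             if net.segments[a].vessel_class != net.segments[b].vessel_class]
    for a, b in pairs:
        worst = min(worst, _min_pair_distance_3d(net.segments[a],
                                                 net.segments[b]))
    return worst


def interleave_terminal_beds(net: VascularNetwork, flows: dict[int, float],
                             radius_threshold_um: float = 5.0) -> list[int]:
    """Remove the low-flow side of small-calibre artery-vein crossings.

    For crossings where both radii are below the threshold, the segment with
    the smaller |flow| is removed; all surviving geometry is untouched.
    Requires a solved flow (a segment-id → flow mapping); returns the removed
    segment ids.
    """
    if flows is None:
        raise ValueError("flow solution required to identify the low-flow side")
    removed = []
    for sid_a, sid_b in find_crossings(net, classes=("artery", "vein"),
                                       same_class_only=False):
        if sid_a not in net.segments or sid_b not in net.segments:
            continue
        sa, sb = net.segments[sid_a], net.segments[sid_b]
        if sa.vessel_class == sb.vessel_class:
            continue
        if sa.mean_radius_um >= radius_threshold_um \
                or sb.mean_radius_um >= radius_threshold_um:
            continue
        victim = sa if abs(flows.get(sid_a, 0.0)) <= abs(flows.get(sid_b, 0.0)) \
            else sb
        net.remove_segment(victim.id)
        removed.append(victim.id)
    return removed
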