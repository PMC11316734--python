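"""Space-filling growth of the seeded trees by multiscale lattice invasion.

The seed arcades are extended over the retina by repeatedly adding straight
terminal segments into unoccupied lattice sites adjacent to occupied ones,
committing at each step the candidate with the smallest expected increase of
the Murray-law network cost

    C(B, λ, ρ) = Σ_b r_b^ρ l_b^λ        (radii and lengths in µm)

over progressively finer lattices.  Segment radii are maintained bottom-up:
every leaf carries the terminal radius and each parent satisfies
r_p^γ = Σ_c r_c^γ, so the Murray relation holds exactly at every bifurcation
throughout growth; the whole tree is finally rescaled so the root matches the
sampled root calibre (the relation is homogeneous, so rescaling preserves it).

Geometric optimisation moves nodes to reduce the same cost, topological
optimisation rewires asymmetric or anomalously short branches, and in-plane
self-intersections are removed by re-attachment rather than excursions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.spatial import cKDTree

from .domain import RetinaDomain
from .parameters import SimulationParameters
from .vascular_graph import VascularNetwork, polyline_length

log = logging.getLogger(__name__)

TREE_CLASSES = ("artery", "vein")

#: shortest admissible inter-node segment (10 µm); geometric optimisation
#: and rewiring never shrink a segment below this
MIN_SEGMENT_LENGTH_MM = 0.01


# -- cost -----------------------------------------------------------------

def network_cost(net: VascularNetwork, rho: float = 1.0,
                 lam: float = 1.0) -> float:
    """Murray-law cost Σ r^ρ l^λ over all segments (r, l in µm)."""
    total = 0.0
    for seg in net.segments.values():
        total += seg.mean_radius_um ** rho * (seg.length_mm * 1000.0) ** lam
    return total


# -- tree bookkeeping -----------------------------------------------------

@dataclass
class TreeIndex:
    """Parent/children maps of one vessel-class tree."""
    root: int
    cls: str
    parent_node: dict[int, int] = field(default_factory=dict)
    parent_seg: dict[int, int] = field(default_factory=dict)
    children: dict[int, list[int]] = field(default_factory=dict)  # node -> child nodes
    order: list[int] = field(default_factory=list)  # topological, root first

    def is_descendant(self, nid: int, ancestor: int) -> bool:
        while nid in self.parent_node:
            if nid == ancestor:
                return True
            nid = self.parent_node[nid]
        return nid == ancestor


def tree_structure(net: VascularNetwork, cls: str) -> TreeIndex:
    root = net.inlet_id if cls == "artery" else net.outlet_id
    t = TreeIndex(root, cls)
    t.children[root] = []
    stack = [root]
    seen = {root}
    while stack:
        nid = stack.pop()
        for other, seg in net.neighbors(nid):
            if seg.vessel_class != cls or other in seen:
                continue
            seen.add(other)
            t.parent_node[other] = nid
            t.parent_seg[other] = seg.id
            t.children.setdefault(nid, []).append(other)
            t.children.setdefault(other, [])
            stack.append(other)
    # topological order via BFS
    t.order = [t.root]
    i = 0
    while i < len(t.order):
        t.order.extend(t.children.get(t.order[i], ()))
        i += 1
    return t


def recompute_radii_murray(net: VascularNetwork, gamma: float,
                           terminal_radius_um: float) -> None:
    """Assign radii bottom-up: leaves carry the terminal radius, parents obey
    r_p = (Σ r_c^γ)^{1/γ}.  Capillary segments are untouched."""
    for cls in TREE_CLASSES:
        t = tree_structure(net, cls)
        radius_of: dict[int, float] = {}
        for nid in reversed(t.order):
            if nid == t.root:
                continue
            kids = t.children.get(nid, ())
            if not kids:
                r = terminal_radius_um
            else:
                r = sum(radius_of[c] ** gamma for c in kids) ** (1.0 / gamma)
            radius_of[nid] = r
            seg = net.segments[t.parent_seg[nid]]
            seg.radii = np.full(len(seg.path), r)


def rescale_radii_to_root(net: VascularNetwork,
                          params: SimulationParameters) -> None:
    """Uniformly scale each tree so the root segment matches the sampled
    root calibre.  Murray relations are homogeneous and survive scaling."""
    for cls in TREE_CLASSES:
        t = tree_structure(net, cls)
        root_kids = t.children.get(t.root, ())
        if not root_kids:
            continue
        actual = net.segments[t.parent_seg[root_kids[0]]].mean_radius_um
        target = params.root_radius_um(cls)
        if actual <= 0:
            continue
        k = target / actual
        for seg in net.segments.values():
            if seg.vessel_class == cls:
                seg.radii = seg.radii * k


# -- leaf-node distribution -----------------------------------------------

def distribute_leaf_nodes(domain: RetinaDomain, spacing_mm: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Near-uniform leaf points on the retina disc, excluding the macula.

    Square-grid placement at the requested spacing with a circular jitter of
    radius spacing/4 guarantees a minimum pairwise distance of spacing/2 and
    a count within ~30% of usable_area / spacing².
    """
    if spacing_mm <= 0:
        raise ValueError("spacing must be positive")
    R = domain.retina_radius_mm
    if spacing_mm > 2 * R:
        raise ValueError("spacing larger than the domain")
    c = domain.disc_centre[:2]
    n = int(math.floor(2 * R / spacing_mm)) + 1
    xs = c[0] + (np.arange(n) - (n - 1) / 2.0) * spacing_mm
    ys = c[1] + (np.arange(n) - (n - 1) / 2.0) * spacing_mm
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    ang = rng.uniform(0, 2 * math.pi, len(pts))
    rad = (spacing_mm / 4.0) * np.sqrt(rng.uniform(0, 1, len(pts)))
    pts = pts + np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])
    p3 = np.column_stack([pts, np.zeros(len(pts))])
    keep = domain.in_retina(p3) & ~domain.in_macula(p3)
    out = p3[keep]
    if len(out) == 0:
        centre = (c + np.array([0.75 * R, 0.0]))  # off-macula fallback
        out = np.array([[centre[0], centre[1], 0.0]])
    return out


def attach_leaf_nodes(net: VascularNetwork, leaves: np.ndarray,
                      rng: np.random.Generator,
                      domain: RetinaDomain | None = None) -> list[int]:
    """Attach each leaf point to the nearest seed-tree node, alternating the
    receiving tree by proximity; attachments that would cut through the
    macula are skipped.  Returns the created segment ids (tagged so they can
    be removed after the initial growth stage)."""
    created = []
    node_ids = {cls: [] for cls in TREE_CLASSES}
    for nid, node in net.nodes.items():
        for other, seg in net.neighbors(nid):
            if seg.vessel_class in TREE_CLASSES and node.kind != "inlet-root" \
                    and node.kind != "outlet-root":
                node_ids[seg.vessel_class].append(nid)
                break
    trees = {}
    for cls in TREE_CLASSES:
        ids = sorted(set(node_ids[cls]))
        pos = np.array([net.nodes[i].position[:2] for i in ids])
        trees[cls] = (ids, cKDTree(pos))
    mac_c = domain.macula_centre[:2] if domain is not None else None
    mac_r = domain.macula_diameter_mm / 2.0 if domain is not None else 0.0
    for p in leaves:
        cands = []
        for cls in TREE_CLASSES:
            ids, kd = trees[cls]
            d, j = kd.query(p[:2])
            cands.append((d, cls, ids[j]))
        cands.sort()
        for _, cls, parent in cands:
            if mac_c is not None and not _segment_clears_region(
                    net.nodes[parent].position[:2], p[:2], mac_c, mac_r):
                continue
            child = net.add_node(p, "terminal")
            seg = net.add_segment(parent, child.id, 8.0, vessel_class=cls,
                                  meta={"leaf_seed": True})
            created.append(seg.id)
            break
    return created


# -- lattice growth -------------------------------------------------------

def stride_schedule(params: SimulationParameters) -> np.ndarray:
    """Linearly spaced stride lengths (µm), both endpoints included."""
    return np.linspace(params["lattice_stride_max_um"],
                       params["lattice_stride_min_um"],
                       int(params["lattice_iterations"]))


class GrowthLattice:
    """Square lattice over the retina disc with occupancy tracking.

    A site is occupied iff a vessel path point (paths sampled at stride/2)
    falls inside it.  Sites inside the macula region are excluded: the
    macula is kept vessel-free during the main growth.
    """

    def __init__(self, domain: RetinaDomain, stride_um: float,
                 exclude_macula: bool = True):
        if stride_um <= 0:
            raise ValueError("stride must be positive")
        self.stride_mm = stride_um / 1000.0
        self.domain = domain
        R = domain.retina_radius_mm
        c = domain.disc_centre[:2]
        self.origin = c - R
        self.n = int(math.ceil(2 * R / self.stride_mm))
        ix, iy = np.meshgrid(np.arange(self.n), np.arange(self.n))
        centres = self.origin + (np.column_stack([ix.ravel(), iy.ravel()])
                                 + 0.5) * self.stride_mm
        p3 = np.column_stack([centres, np.zeros(len(centres))])
        ok = self.domain.in_retina(p3)
        if exclude_macula:
            ok &= ~self.domain.in_macula(p3)
        self.valid = np.zeros(self.n * self.n, dtype=bool)
        self.valid[ok] = True
        self.centres = np.full((self.n * self.n, 2), np.nan)
        self.centres[ok] = centres[ok]
        self.occupied = np.zeros(self.n * self.n, dtype=bool)

    def site_of(self, pts2: np.ndarray) -> np.ndarray:
        ij = np.floor((pts2 - self.origin) / self.stride_mm).astype(int)
        ij = np.clip(ij, 0, self.n - 1)
        return ij[:, 1] * self.n + ij[:, 0]

    def mark_points(self, pts2: np.ndarray) -> None:
        if len(pts2):
            self.occupied[self.site_of(pts2)] = True

    def occupy_from_network(self, net: VascularNetwork) -> None:
        self.occupied[:] = False
        pts = sample_network_points(net, self.stride_mm / 2.0)
        self.mark_points(pts)

    def frontier(self) -> np.ndarray:
        """Valid, unoccupied sites with at least one occupied 8-neighbour."""
        occ = (self.occupied & self.valid).reshape(self.n, self.n)
        grown = np.zeros_like(occ)
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                if dx == 0 and dy == 0:
                    continue
                grown |= np.roll(np.roll(occ, dx, axis=0), dy, axis=1)
        cand = grown.ravel() & self.valid & ~self.occupied
        return np.flatnonzero(cand)

    def occupancy_fraction(self) -> float:
        nv = int(self.valid.sum())
        return float((self.occupied & self.valid).sum() / nv) if nv else 0.0


def sample_network_points(net: VascularNetwork, spacing_mm: float) -> np.ndarray:
    """xy-points sampled along every segment path at the given spacing."""
    chunks = []
    for seg in net.segments.values():
        p = seg.path[:, :2]
        for i in range(len(p) - 1):
            d = float(np.linalg.norm(p[i + 1] - p[i]))
            k = max(2, int(math.ceil(d / spacing_mm)) + 1)
            t = np.linspace(0, 1, k)[:, None]
            chunks.append(p[i] * (1 - t) + p[i + 1] * t)
    return np.concatenate(chunks) if chunks else np.zeros((0, 2))


def _segment_clears_region(p0, p1, centre, radius) -> bool:
    """True if the 2-D segment p0-p1 stays outside the disc (centre, radius)."""
    d = p1 - p0
    L2 = float(d @ d)
    if L2 == 0:
        return float(np.linalg.norm(p0 - centre)) > radius
    t = float(np.clip((centre - p0) @ d / L2, 0.0, 1.0))
    return float(np.linalg.norm(p0 + t * d - centre)) > radius


def _upstream_increment_costs(net, tree: TreeIndex, gamma, r_t, rho, lam):
    """U(n): expected cost increase on the path root→n if a terminal of
    radius r_t is attached below node n (Murray-consistent increments)."""
    U = {tree.root: 0.0}
    for nid in tree.order:
        if nid == tree.root:
            continue
        seg = net.segments[tree.parent_seg[nid]]
        r = seg.mean_radius_um
        r_new = (r ** gamma + r_t ** gamma) ** (1.0 / gamma)
        inc = (r_new ** rho - r ** rho) * (seg.length_mm * 1000.0) ** lam
        U[nid] = U[tree.parent_node[nid]] + inc
    return U


def lattice_growth(net: VascularNetwork, params: SimulationParameters,
                   domain: RetinaDomain, rng: np.random.Generator,
                   strides_um=None, remove_leaf_seeds: bool = True,
                   cost_trace: list | None = None,
                   max_node_children: int = 3) -> VascularNetwork:
    """Grow the network into unoccupied lattice sites, coarse to fine.

    For each stride the frontier (unoccupied sites next to occupied ones) is
    evaluated: each site's candidate is a straight terminal segment from the
    nearest tree node within two strides, scored by the expected Murray cost
    change (new segment + upstream radius updates).  Candidates are committed
    in ascending expected-cost order (ties broken by site index then node id)
    until the frontier stops advancing, then the stride is refined.  Sites or
    paths that would enter the macula are rejected.  Original leaf-seed
    terminals are removed after the first (coarsest) stride.
    """
    gamma = params["murray_exponent"]
    r_t = params["terminal_radius_um"]
    rho = params["cost_exponent_rho"]
    lam = params["cost_exponent_lambda"]
    if strides_um is None:
        strides_um = stride_schedule(params)
    mac_c = domain.macula_centre[:2]
    mac_r = domain.macula_diameter_mm / 2.0

    recompute_radii_murray(net, gamma, r_t)
    for it, stride in enumerate(strides_um):
        lat = GrowthLattice(domain, float(stride))
        while True:
            lat.occupy_from_network(net)
            frontier = lat.frontier()
            if len(frontier) == 0:
                break
            trees = {cls: tree_structure(net, cls) for cls in TREE_CLASSES}
            U = {cls: _upstream_increment_costs(net, trees[cls], gamma, r_t,
                                                rho, lam)
                 for cls in TREE_CLASSES}
            kd = {}
            for cls in TREE_CLASSES:
                ids = [n for n in trees[cls].order
                       if n != trees[cls].root
                       and len(trees[cls].children.get(n, ())) < max_node_children]
                pos = np.array([net.nodes[i].position[:2] for i in ids]) \
                    if ids else np.zeros((0, 2))
                kd[cls] = (ids, cKDTree(pos) if len(ids) else None)

            cand = []  # (dcost, site, cls, node_id)
            for site in frontier:
                centre = lat.centres[site]
                best = None
                for cls in TREE_CLASSES:
                    ids, tree_kd = kd[cls]
                    if tree_kd is None:
                        continue
                    d, j = tree_kd.query(centre,
                                         distance_upper_bound=2 * lat.stride_mm)
                    if not np.isfinite(d):
                        continue
                    nid = ids[j]
                    p0 = net.nodes[nid].position[:2]
                    if not _segment_clears_region(p0, centre, mac_c, mac_r):
                        continue
                    dc = r_t ** rho * (d * 1000.0) ** lam + U[cls][nid]
                    if best is None or (dc, site, nid) < best[:3]:
                        best = (dc, int(site), nid, cls)
                if best is not None:
                    cand.append(best)
            if not cand:
                break
            cand.sort()
            cost_before = network_cost(net, rho, lam)
            committed_estimate = 0.0
            progress = False
            for dc, site, nid, cls in cand:
                if lat.occupied[site]:
                    continue
                centre = lat.centres[site]
                child = net.add_node(np.array([centre[0], centre[1], 0.0]),
                                     "terminal")
                net.add_segment(nid, child.id, r_t, vessel_class=cls)
                if net.nodes[nid].kind == "terminal":
                    net.nodes[nid].kind = "bifurcation"
                committed_estimate += dc
                progress = True
                p0 = net.nodes[nid].position[:2]
                k = max(2, int(math.ceil(np.linalg.norm(centre - p0)
                                         / (lat.stride_mm / 2))) + 1)
                t = np.linspace(0, 1, k)[:, None]
                lat.mark_points(p0 * (1 - t) + centre * t)
            recompute_radii_murray(net, gamma, r_t)
            if cost_trace is not None:
                cost_trace.append({
                    "stride_um": float(stride),
                    "cost_before": cost_before,
                    "committed_estimate": committed_estimate,
                    "cost_after": network_cost(net, rho, lam)})
            if not progress:
                break
        if it == 0 and remove_leaf_seeds:
            _remove_leaf_seed_terminals(net)
            recompute_radii_murray(net, gamma, r_t)
    net.metadata["stage"] = "grown"
    return net


def _remove_leaf_seed_terminals(net: VascularNetwork) -> None:
    doomed = [sid for sid, s in net.segments.items()
              if s.meta.get("leaf_seed")
              and net.degree(s.nodes[1]) == 1]
    for sid in doomed:
        net.remove_segment(sid)


# -- geometric optimisation ------------------------------------------------

def optimize_geometry(net: VascularNetwork, params: SimulationParameters,
                      frozen_segments: set | None = None,
                      leaf_anchors: dict | None = None,
                      keep_out=None, keep_out_segment=None,
                      movable_nodes=None,
                      max_sweeps: int = 20, rel_tol: float = 1e-4,
                      pin_mm: float | None = None) -> float:
    """Coordinate-wise golden-section optimisation of node positions.

    Minimises the Murray cost by moving bifurcation and leaf nodes; only
    moves that reduce the local cost are kept, so the total cost is
    non-increasing.  Frozen segments are untouched; leaf nodes move at most
    pinning-fraction × leaf-spacing from their anchor; ``keep_out(p)`` can
    veto positions (e.g. the macula during main growth).  Returns the final
    cost.  Only nodes whose incident segments are straight 2-point polylines
    are eligible (curved paths are produced later, by the tortuosity stage).
    """
    rho = params["cost_exponent_rho"]
    lam = params["cost_exponent_lambda"]
    pin = (pin_mm if pin_mm is not None
           else params["pinning_distance_fraction"] * params["leaf_spacing_mm"])
    frozen_segments = frozen_segments or set()
    if leaf_anchors is None:
        leaf_anchors = {}
    # anchor every leaf at its entry position: the pinning distance bounds
    # total displacement, not per-sweep drift
    for nid, node in net.nodes.items():
        if node.kind == "terminal" and nid not in leaf_anchors:
            leaf_anchors[nid] = node.position[:2].copy()
    eligible = []
    for nid, node in net.nodes.items():
        if node.kind in ("inlet-root", "outlet-root"):
            continue
        segs = net.segments_at(nid)
        if not segs or any(s.id in frozen_segments or len(s.path) != 2
                           or s.vessel_class == "capillary" for s in segs):
            continue
        if movable_nodes is not None and nid not in movable_nodes:
            continue
        eligible.append((nid, segs))

    def local_cost(nid, p2, segs):
        c = 0.0
        for s in segs:
            a, b = s.nodes
            other = net.nodes[b if a == nid else a].position[:2]
            c += s.mean_radius_um ** rho * (
                float(np.linalg.norm(p2 - other)) * 1000.0) ** lam
        return c

    total = network_cost(net, rho, lam)
    for _ in range(max_sweeps):
        improved = 0.0
        for nid, segs in eligible:
            node = net.nodes[nid]
            p = node.position[:2].copy()
            before = local_cost(nid, p, segs)
            best = p.copy()
            for axis in (0, 1):
                span = 0.5  # mm search half-width per coordinate
                def f(x, axis=axis):
                    q = best.copy()
                    q[axis] = x
                    return local_cost(nid, q, segs)
                res = minimize_scalar(
                    f, bracket=None, method="bounded",
                    bounds=(best[axis] - span, best[axis] + span),
                    options={"xatol": 1e-6})
                trial = best.copy()
                trial[axis] = float(res.x)
                if node.kind == "terminal":
                    anchor = leaf_anchors[nid]
                    if np.linalg.norm(trial - np.asarray(anchor)[:2]) > pin:
                        continue
                if keep_out is not None and keep_out(trial):
                    continue
                # the Weber point degenerates onto a neighbour when one
                # weight dominates; keep segments at a finite length, and
                # never let a moved segment cut a forbidden region
                bad = False
                for s in segs:
                    a, b = s.nodes
                    other = net.nodes[b if a == nid else a].position[:2]
                    if np.linalg.norm(trial - other) < MIN_SEGMENT_LENGTH_MM:
                        bad = True
                        break
                    if keep_out_segment is not None \
                            and keep_out_segment(trial, other):
                        bad = True
                        break
                if bad:
                    continue
                if local_cost(nid, trial, segs) < local_cost(nid, best, segs):
                    best = trial
            after = local_cost(nid, best, segs)
            if after < before - 1e-12:
                improved += before - after
                node.position = np.array([best[0], best[1], node.position[2]])
                for s in segs:
                    a, b = s.nodes
                    s.path = np.array([net.nodes[a].position,
                                       net.nodes[b].position])
        total_new = total - improved
        if total > 0 and improved / total < rel_tol:
            total = total_new
            break
        total = total_new
    return network_cost(net, rho, lam)


# -- trimming and topological optimisation ---------------------------------

def bifurcation_asymmetries(net: VascularNetwork, cls: str):
    """Yield (node, small child, large child, alpha) over two-child nodes."""
    t = tree_structure(net, cls)
    for nid in t.order:
        kids = t.children.get(nid, ())
        if len(kids) != 2:
            continue
        r = [net.segments[t.parent_seg[c]].mean_radius_um for c in kids]
        small, large = (kids[0], kids[1]) if r[0] <= r[1] else (kids[1], kids[0])
        yield nid, small, large, min(r) / max(r), t


def _delete_subtree(net: VascularNetwork, tree: TreeIndex, nid: int) -> None:
    for child in list(tree.children.get(nid, ())):
        _delete_subtree(net, tree, child)
    net.remove_segment(tree.parent_seg[nid])


def trim_and_regrow(net: VascularNetwork, params: SimulationParameters,
                    domain: RetinaDomain, rng: np.random.Generator,
                    threshold: float | None = None, regrow: bool = True,
                    max_rounds: int = 3) -> VascularNetwork:
    """Remove the small side of highly asymmetric bifurcations
    (α below threshold) and re-enter the vacated territory into growth.
    The final pass trims without regrowth so no violating bifurcation
    remains."""
    thr = params["trim_alpha_threshold"] if threshold is None else threshold
    gamma = params["murray_exponent"]
    r_t = params["terminal_radius_um"]
    for round_ in range(max_rounds):
        trimmed = 0
        for cls in TREE_CLASSES:
            while True:
                victim = None
                for nid, small, large, alpha, t in bifurcation_asymmetries(net, cls):
                    if alpha < thr:
                        victim = (t, small)
                        break
                if victim is None:
                    break
                _delete_subtree(net, *victim)
                trimmed += 1
        if trimmed == 0:
            break
        recompute_radii_murray(net, gamma, r_t)
        if regrow and round_ < max_rounds - 1:
            lattice_growth(net, params, domain, rng,
                           strides_um=[params["lattice_stride_min_um"]],
                           remove_leaf_seeds=False)
    recompute_radii_murray(net, gamma, r_t)
    return net


def topological_optimize(net: VascularNetwork,
                         params: SimulationParameters,
                         domain: RetinaDomain | None = None) -> VascularNetwork:
    """Cost-decreasing rewirings of the tree topology.

    Two move classes, each accepted only if the Murray cost decreases:
    (1) an asymmetric bifurcation shifts its small (low-flow) side one
    generation downstream, below the large daughter; (2) an inter-bifurcation
    branch much shorter than its expectation under metabolic scaling
    (child length = parent length × 2^{−1/3}) is merged into a single
    higher-order split at its parent.  Acyclicity is preserved: re-attachment
    targets are never descendants of the moved subtree.
    """
    gamma = params["murray_exponent"]
    r_t = params["terminal_radius_um"]
    rho = params["cost_exponent_rho"]
    lam = params["cost_exponent_lambda"]
    short_frac = params["wbe_short_fraction"]
    mac_c = domain.macula_centre[:2] if domain is not None else None
    mac_r = domain.macula_diameter_mm / 2.0 if domain is not None else 0.0

    def clears_macula(p0, p1):
        return mac_c is None or _segment_clears_region(p0, p1, mac_c, mac_r)

    for cls in TREE_CLASSES:
        changed = True
        guard = 0
        while changed and guard < 10:
            changed = False
            guard += 1
            t = tree_structure(net, cls)
            # move small side downstream
            for nid in list(t.order):
                kids = t.children.get(nid, ())
                if len(kids) != 2:
                    continue
                r0 = net.segments[t.parent_seg[kids[0]]].mean_radius_um
                r1 = net.segments[t.parent_seg[kids[1]]].mean_radius_um
                small, large = (kids[0], kids[1]) if r0 <= r1 else (kids[1], kids[0])
                if not t.children.get(large):
                    continue
                seg_small = net.segments[t.parent_seg[small]]
                seg_large = net.segments[t.parent_seg[large]]
                p_new = net.nodes[large].position
                l_old = seg_small.length_mm * 1000.0
                l_new = float(np.linalg.norm(
                    net.nodes[small].position - p_new)) * 1000.0
                r_s = seg_small.mean_radius_um
                r_l = seg_large.mean_radius_um
                r_l_new = (r_l ** gamma + r_s ** gamma) ** (1.0 / gamma)
                dcost = (r_s ** rho * (l_new ** lam - l_old ** lam)
                         + (r_l_new ** rho - r_l ** rho)
                         * (seg_large.length_mm * 1000.0) ** lam)
                if dcost < -1e-12 and l_new >= MIN_SEGMENT_LENGTH_MM * 1000.0 \
                        and clears_macula(p_new[:2],
                                          net.nodes[small].position[:2]):
                    net.remove_segment(seg_small.id, drop_isolated_nodes=False)
                    net.add_segment(large, small, r_s, vessel_class=cls)
                    recompute_radii_murray(net, gamma, r_t)
                    changed = True
                    break
            if changed:
                continue
            # merge short inter-bifurcation branches into higher-order splits
            for nid in list(t.order):
                if nid == t.root or nid not in t.parent_node:
                    continue
                kids = t.children.get(nid, ())
                if len(kids) < 2:
                    continue
                parent = t.parent_node[nid]
                if parent == t.root or parent not in t.parent_node:
                    continue
                seg = net.segments[t.parent_seg[nid]]
                parent_seg = net.segments[t.parent_seg[parent]]
                expected = parent_seg.length_mm * 2.0 ** (-1.0 / 3.0)
                if seg.length_mm >= short_frac * expected:
                    continue
                p_new = net.nodes[parent].position
                dcost = -seg.mean_radius_um ** rho * (seg.length_mm * 1000.0) ** lam
                for c in kids:
                    cs = net.segments[t.parent_seg[c]]
                    l_old = cs.length_mm * 1000.0
                    l_new = float(np.linalg.norm(
                        net.nodes[c].position - p_new)) * 1000.0
                    dcost += cs.mean_radius_um ** rho * (l_new ** lam - l_old ** lam)
                if dcost < -1e-12 and all(
                        clears_macula(p_new[:2], net.nodes[c].position[:2])
                        and np.linalg.norm(net.nodes[c].position - p_new)
                        >= MIN_SEGMENT_LENGTH_MM
                        for c in kids):
                    for c in list(kids):
                        cs = net.segments[t.parent_seg[c]]
                        net.remove_segment(cs.id, drop_isolated_nodes=False)
                        net.add_segment(parent, c, cs.mean_radius_um,
                                        vessel_class=cls)
                    net.remove_segment(seg.id)
                    recompute_radii_murray(net, gamma, r_t)
                    changed = True
                    break
    return net


# -- self-intersection removal ---------------------------------------------

def _seg_seg_distance_2d(a0, a1, b0, b1) -> float:
    """Minimum distance between two 2-D segments."""
    def pt_seg(p, q0, q1):
        d = q1 - q0
        L2 = float(d @ d)
        if L2 == 0:
            return float(np.linalg.norm(p - q0))
        t = float(np.clip((p - q0) @ d / L2, 0.0, 1.0))
        return float(np.linalg.norm(q0 + t * d - p))

    d1, d2 = a1 - a0, b1 - b0
    denom = d1[0] * d2[1] - d1[1] * d2[0]
    if abs(denom) > 1e-12:
        r = b0 - a0
        s = (r[0] * d2[1] - r[1] * d2[0]) / denom
        u = (r[0] * d1[1] - r[1] * d1[0]) / denom
        if 0 <= s <= 1 and 0 <= u <= 1:
            return 0.0
    return min(pt_seg(a0, b0, b1), pt_seg(a1, b0, b1),
               pt_seg(b0, a0, a1), pt_seg(b1, a0, a1))


def find_crossings(net: VascularNetwork, classes=None,
                   same_class_only: bool = True,
                   threshold_scale: float = 1.0) -> list[tuple[int, int]]:
    """Pairs of segments whose 2-D distance is below threshold_scale × the
    sum of their radii, excluding pairs sharing a node.  KD-tree pre-filter
    followed by an exact chord-to-chord distance test."""
    classes = classes or TREE_CLASSES
    segs = [s for s in net.segments.values() if s.vessel_class in classes]
    if len(segs) < 2:
        return []
    mids = np.array([0.5 * (s.path[0][:2] + s.path[-1][:2]) for s in segs])
    half = np.array([0.5 * s.chord_mm for s in segs])
    rmax = max(s.mean_radius_um for s in segs) / 1000.0
    kd = cKDTree(mids)
    reach = float(half.max() * 2 + 2 * rmax * threshold_scale)
    pairs = kd.query_pairs(reach, output_type="ndarray")
    if len(pairs) == 0:
        return []
    # vectorised bounding-circle pre-filter before the exact test
    radii = np.array([s.mean_radius_um for s in segs]) / 1000.0
    i, j = pairs[:, 0], pairs[:, 1]
    dmid = np.linalg.norm(mids[i] - mids[j], axis=1)
    close = dmid <= half[i] + half[j] + threshold_scale * (radii[i] + radii[j])
    out = []
    for i, j in sorted(map(tuple, pairs[close])):
        si, sj = segs[i], segs[j]
        if same_class_only and si.vessel_class != sj.vessel_class:
            continue
        if set(si.nodes) & set(sj.nodes):
            continue
        thresh = threshold_scale * (si.mean_radius_um + sj.mean_radius_um) / 1000.0
        d = _seg_seg_distance_2d(si.path[0][:2], si.path[-1][:2],
                                 sj.path[0][:2], sj.path[-1][:2])
        if d < thresh:
            out.append((si.id, sj.id))
    return out


def resolve_self_intersections(net: VascularNetwork,
                               params: SimulationParameters | None = None,
                               domain: RetinaDomain | None = None,
                               max_passes: int = 5) -> VascularNetwork:
    """Remove same-tree in-plane crossings by re-attachment.

    The smaller-radius segment of each crossing pair is re-attached so its
    distal node hangs off the nearest endpoint of the other segment, which
    prevents later growth from recreating the same crossing.  Crossings that
    survive the bounded number of passes are resolved by deleting the
    offending segment (with its dependent subtree), logged as removed.
    """
    gamma = params["murray_exponent"] if params else 3.0
    r_t = params["terminal_radius_um"] if params else 8.0
    mac_c = domain.macula_centre[:2] if domain is not None else None
    mac_r = domain.macula_diameter_mm / 2.0 if domain is not None else 0.0
    removed = 0
    for _ in range(max_passes):
        crossings = find_crossings(net)
        if not crossings:
            break
        resolved_any = False
        handled = set()
        for sid_a, sid_b in crossings:
            if sid_a in handled or sid_b in handled \
                    or sid_a not in net.segments or sid_b not in net.segments:
                continue
            sa, sb = net.segments[sid_a], net.segments[sid_b]
            mover, fixed = (sa, sb) if sa.mean_radius_um <= sb.mean_radius_um \
                else (sb, sa)
            cls = mover.vessel_class
            # rebuilt per rewire: stale parent maps would let a segment be
            # re-attached inside its own subtree, detaching a cycle
            t = tree_structure(net, cls)
            # distal = the endpoint farther from the root
            pa, ch = mover.nodes
            if t.parent_node.get(ch) != pa:
                pa, ch = ch, pa
            dist_pos = net.nodes[ch].position
            cands = [n for n in fixed.nodes if n in t.parent_seg or n == t.root]
            cands = [n for n in cands if not t.is_descendant(n, ch) and n != ch
                     and np.linalg.norm(net.nodes[n].position - dist_pos)
                     >= MIN_SEGMENT_LENGTH_MM
                     and not any((s.nodes in ((n, ch), (ch, n)))
                                 for s in net.segments_at(n))
                     and (mac_c is None or _segment_clears_region(
                         net.nodes[n].position[:2], dist_pos[:2],
                         mac_c, mac_r))]
            cands.sort(key=lambda n: float(
                np.linalg.norm(net.nodes[n].position - dist_pos)))
            if cands and fixed.vessel_class == cls:
                new_parent = cands[0]
                net.remove_segment(mover.id, drop_isolated_nodes=False)
                net.add_segment(new_parent, ch, mover.mean_radius_um,
                                vessel_class=cls)
                handled.update((sid_a, sid_b))
                resolved_any = True
        recompute_radii_murray(net, gamma, r_t)
        if not resolved_any:
            break
    # cleanup: delete anything still crossing
    for sid_a, sid_b in find_crossings(net):
        if sid_a not in net.segments or sid_b not in net.segments:
            continue
        sa, sb = net.segments[sid_a], net.segments[sid_b]
        victim = sa if sa.mean_radius_um <= sb.mean_radius_um else sb
        cls = victim.vessel_class
        t = tree_structure(net, cls)
        pa, ch = victim.nodes
        if t.parent_node.get(ch) != pa:
            pa, ch = ch, pa
        if ch in t.parent_seg:
            _delete_subtree(net, t, ch)
            removed += 1
    if removed:
        log.warning("resolve_self_intersections: removed %d unresolvable "
                    "segments", removed)
        net.metadata["crossings_removed"] = removed
        if params:
            recompute_radii_murray(net, gamma, r_t)
    return net


# -- macula growth ---------------------------------------------------------

def peripheral_terminal_density(net: VascularNetwork,
                                domain: RetinaDomain) -> float:
    """Terminal (leaf) nodes per mm² outside the macula region."""
    term = [n for n in net.nodes.values() if n.kind == "terminal"
            and not domain.in_macula(n.position[None, :])[0]]
    area = math.pi * domain.retina_radius_mm ** 2 \
        - math.pi * (domain.macula_diameter_mm / 2) ** 2
    return len(term) / area if area > 0 else 0.0


def grow_macula(net: VascularNetwork, params: SimulationParameters,
                domain: RetinaDomain, rng: np.random.Generator) -> VascularNetwork:
    """Fill the macula annulus (fovea excluded) with a radial vessel pattern.

    Leaf targets sit on a radial lattice between the fovea radius and the
    macula outer radius at a density of flow-density-factor × the network's
    own peripheral terminal density, jittered by uniform sampling in a disc
    so vessels do not align with the lattice.  Each target, processed from
    the outer rim inward, connects to the nearest existing node whose
    resulting branch angle respects the hard limit; targets are thinned
    i.i.d. with the sparsity probability; no vessel may cross the fovea.
    """
    factor = params["macula_flow_density_factor"]
    sparsity = params["macula_sparsity"]
    angle_limit = math.radians(params["macula_angle_limit_deg"])
    gamma = params["murray_exponent"]
    r_t = params["terminal_radius_um"]
    c = domain.macula_centre[:2]
    r_in = domain.fovea_radius_mm
    r_out = domain.macula_diameter_mm / 2.0

    density = factor * peripheral_terminal_density(net, domain)
    if density <= 0:
        return net
    h = 1.0 / math.sqrt(density)
    targets = []
    n_rings = max(1, int(round((r_out - r_in) / h)))
    for i in range(n_rings):
        ring_r = r_in + (i + 0.5) * (r_out - r_in) / n_rings
        n_spokes = max(3, int(round(2 * math.pi * ring_r / h)))
        phase = rng.uniform(0, 2 * math.pi)
        for k in range(n_spokes):
            ang = phase + 2 * math.pi * k / n_spokes
            p = c + ring_r * np.array([math.cos(ang), math.sin(ang)])
            jr = (h / 2.0) * math.sqrt(rng.uniform())
            ja = rng.uniform(0, 2 * math.pi)
            p = p + jr * np.array([math.cos(ja), math.sin(ja)])
            d = np.linalg.norm(p - c)
            if r_in < d < r_out:
                targets.append(p)
    placed = len(targets)
    keep = rng.uniform(size=placed) >= sparsity
    targets = [t for t, k in zip(targets, keep) if k]
    survived = len(targets)
    targets.sort(key=lambda p: -float(np.linalg.norm(p - c)))

    trees = {cls: tree_structure(net, cls) for cls in TREE_CLASSES}

    def attach(p, leaves_only_parents_excluded=False, want_cls=None,
               max_children: int = 3):
        ids, pos = [], []
        for cls in (TREE_CLASSES if want_cls is None else (want_cls,)):
            t = trees[cls]
            for n in t.parent_seg:
                if leaves_only_parents_excluded and not t.children.get(n):
                    continue
                if len(t.children.get(n, ())) >= max_children:
                    continue
                ids.append((cls, n))
                pos.append(net.nodes[n].position[:2])
        if not ids:
            return False
        kd = cKDTree(np.array(pos))
        _, order = kd.query(p, k=min(8, len(ids)))
        for j in np.atleast_1d(order):
            cls, nid = ids[int(j)]
            t = trees[cls]
            q = net.nodes[nid].position[:2]
            if not _segment_clears_region(q, p, c, r_in):
                continue
            parent = t.parent_node.get(nid)
            if parent is not None:
                u = q - net.nodes[parent].position[:2]
                v = p - q
                nu, nv = np.linalg.norm(u), np.linalg.norm(v)
                if nu > 0 and nv > 0:
                    ang = math.acos(float(np.clip(u @ v / (nu * nv), -1, 1)))
                    if ang > angle_limit:
                        continue
            child = net.add_node(np.array([p[0], p[1], 0.0]), "terminal")
            net.add_segment(nid, child.id, r_t, vessel_class=cls,
                            meta={"macula": True})
            if net.nodes[nid].kind == "terminal":
                net.nodes[nid].kind = "bifurcation"
            t.parent_node[child.id] = nid
            t.parent_seg[child.id] = max(net.segments)
            t.children.setdefault(nid, []).append(child.id)
            t.children[child.id] = []
            return True
        return False

    # alternate arteriole/venule targets: the radial macula pattern
    # interdigitates the two supplies
    for i, p in enumerate(targets):
        attach(p, want_cls=TREE_CLASSES[i % 2])

    # Radial chains turn earlier targets into interior nodes, so the leaf
    # (perfusion-carrying) density ends below the placed-target density.
    # Top up with extra jittered leaves attached below non-leaf nodes until
    # the annulus leaf density reaches the flow-density target.
    def annulus_leaf_count():
        n = 0
        for cls in TREE_CLASSES:
            t = trees[cls]
            for nid in t.parent_seg:
                if t.children.get(nid):
                    continue
                d = np.linalg.norm(net.nodes[nid].position[:2] - c)
                if r_in < d < r_out:
                    n += 1
        return n

    area = math.pi * (r_out ** 2 - r_in ** 2)
    want = int(round(density * (1.0 - sparsity) * area))
    for _ in range(5):
        deficit = want - annulus_leaf_count()
        if deficit <= 0:
            break
        added = 0
        for k in range(3 * deficit):
            if added >= deficit:
                break
            rr = math.sqrt(rng.uniform(r_in ** 2, r_out ** 2))
            aa = rng.uniform(0, 2 * math.pi)
            p = c + rr * np.array([math.cos(aa), math.sin(aa)])
            if attach(p, leaves_only_parents_excluded=True,
                      want_cls=TREE_CLASSES[k % 2]):
                added += 1
        if added == 0:
            break
    recompute_radii_murray(net, gamma, r_t)
    net.metadata["macula_targets_placed"] = placed
    net.metadata["macula_targets_survived"] = survived
    net.metadata["macula_leaves"] = annulus_leaf_count()
    net.metadata["macula_leaf_spacing_mm"] = h
    return net
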