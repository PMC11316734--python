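"""Spatial-graph data model for vascular networks.

A vascular network is a graph embedded in space: nodes carry 3-D positions
(millimetres), segments connect node pairs via polyline paths with a radius
(micrometres) defined at every path point.  A complete retinal network has a
single arterial inlet (central retinal artery) and a single venous outlet
(central retinal vein); before the capillary stage the arterial and venous
components are each a tree rooted at those nodes.

Units are explicit throughout the package: coordinates in mm, radii in µm.
Conversions happen at module boundaries, never implicitly.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

NODE_KINDS = ("inlet-root", "outlet-root", "bifurcation", "terminal", "interior")
VESSEL_CLASSES = ("artery", "vein", "capillary")
_CLASS_CODE = {c: i for i, c in enumerate(VESSEL_CLASSES)}

JSON_SCHEMA_VERSION = 1


class AmiraFormatError(ValueError):
    """Raised when an Amira spatial-graph file cannot be parsed."""


def polyline_length(path: np.ndarray) -> float:
    """Arclength of an (N, 3) polyline, in the units of the coordinates."""
    if len(path) < 2:
        return 0.0
    return float(np.sum(np.linalg.norm(np.diff(path, axis=0), axis=1)))


def resample_path(path: np.ndarray, radii: np.ndarray, max_spacing_mm: float):
    """Linearly re-densify a polyline so inter-point spacing <= max_spacing_mm.

    Radii are interpolated along with the coordinates.  Geometry (the traced
    curve) is preserved exactly; only the sampling changes.
    """
    path = np.asarray(path, dtype=float)
    radii = np.asarray(radii, dtype=float)
    out_p = [path[0]]
    out_r = [radii[0]]
    for i in range(len(path) - 1):
        d = float(np.linalg.norm(path[i + 1] - path[i]))
        n = max(1, int(math.ceil(d / max_spacing_mm)))
        for k in range(1, n + 1):
            t = k / n
            out_p.append(path[i] * (1 - t) + path[i + 1] * t)
            out_r.append(radii[i] * (1 - t) + radii[i + 1] * t)
    return np.array(out_p), np.array(out_r)


def dense_points(path: np.ndarray, spacing_mm: float) -> np.ndarray:
    """Vectorised uniform arclength sampling of a polyline (for geometry
    queries; does not modify the path)."""
    path = np.atleast_2d(np.asarray(path, dtype=float))
    if len(path) == 1:
        return path
    dl = np.linalg.norm(np.diff(path, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(dl)])
    total = s[-1]
    if total == 0:
        return path[:1]
    n = max(2, int(math.ceil(total / spacing_mm)) + 1)
    x = np.linspace(0.0, total, n)
    return np.column_stack([np.interp(x, s, path[:, k])
                            for k in range(path.shape[1])])


@dataclass
class VesselNode:
    id: int
    position: np.ndarray  # (3,) mm
    kind: str = "bifurcation"

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)


@dataclass
class VesselSegment:
    id: int
    nodes: tuple[int, int]
    path: np.ndarray    # (N, 3) mm, includes both endpoints
    radii: np.ndarray   # (N,) µm
    vessel_class: str = "artery"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.path = np.atleast_2d(np.asarray(self.path, dtype=float))
        r = np.asarray(self.radii, dtype=float)
        if r.ndim == 0:
            r = np.full(len(self.path), float(r))
        self.radii = r

    @property
    def length_mm(self) -> float:
        return polyline_length(self.path)

    @property
    def chord_mm(self) -> float:
        return float(np.linalg.norm(self.path[-1] - self.path[0]))

    @property
    def mean_radius_um(self) -> float:
        return float(np.mean(self.radii))

    def volume_um3(self) -> float:
        """Σ π r² dl along the path (frustum approximated by mean r² per step)."""
        if len(self.path) < 2:
            return 0.0
        dl_um = np.linalg.norm(np.diff(self.path, axis=0), axis=1) * 1000.0
        r2 = 0.5 * (self.radii[:-1] ** 2 + self.radii[1:] ** 2)
        return float(np.sum(math.pi * r2 * dl_um))


class VascularNetwork:
    """Nodes + radius-bearing segments with designated inlet and outlet."""

    def __init__(self, metadata: dict | None = None):
        self.nodes: dict[int, VesselNode] = {}
        self.segments: dict[int, VesselSegment] = {}
        self.inlet_id: int | None = None
        self.outlet_id: int | None = None
        self.metadata: dict = dict(metadata or {})
        self._adj: dict[int, set[int]] = {}
        self._next_node = 0
        self._next_seg = 0

    # -- construction -----------------------------------------------------
    def add_node(self, position, kind: str = "bifurcation") -> VesselNode:
        nid = self._next_node
        self._next_node += 1
        node = VesselNode(nid, np.asarray(position, dtype=float), kind)
        self.nodes[nid] = node
        self._adj[nid] = set()
        if kind == "inlet-root":
            self.inlet_id = nid
        elif kind == "outlet-root":
            self.outlet_id = nid
        return node

    def add_segment(self, a: int, b: int, radius, path=None,
                    vessel_class: str = "artery", meta=None) -> VesselSegment:
        sid = self._next_seg
        self._next_seg += 1
        if path is None:
            path = np.array([self.nodes[a].position, self.nodes[b].position])
        seg = VesselSegment(sid, (a, b), path, radius, vessel_class,
                            dict(meta or {}))
        self.segments[sid] = seg
        self._adj[a].add(sid)
        self._adj[b].add(sid)
        return seg

    def remove_segment(self, sid: int, drop_isolated_nodes: bool = True):
        seg = self.segments.pop(sid)
        for nid in seg.nodes:
            self._adj[nid].discard(sid)
            if drop_isolated_nodes and not self._adj[nid] and nid not in (
                    self.inlet_id, self.outlet_id):
                del self._adj[nid]
                del self.nodes[nid]

    # -- queries ----------------------------------------------------------
    def degree(self, nid: int) -> int:
        return len(self._adj.get(nid, ()))

    def segments_at(self, nid: int) -> list[VesselSegment]:
        return [self.segments[s] for s in sorted(self._adj.get(nid, ()))]

    def neighbors(self, nid: int):
        for sid in sorted(self._adj.get(nid, ())):
            a, b = self.segments[sid].nodes
            yield (b if a == nid else a), self.segments[sid]

    def to_networkx(self):
        import networkx as nx
        g = nx.MultiGraph()
        g.add_nodes_from(self.nodes)
        for sid, seg in self.segments.items():
            g.add_edge(*seg.nodes, key=sid, segment=sid)
        return g

    def copy(self) -> "VascularNetwork":
        other = VascularNetwork(metadata=json.loads(json.dumps(self.metadata)))
        for nid in sorted(self.nodes):
            n = self.nodes[nid]
            other.nodes[nid] = VesselNode(nid, n.position.copy(), n.kind)
            other._adj[nid] = set(self._adj[nid])
        for sid in sorted(self.segments):
            s = self.segments[sid]
            other.segments[sid] = VesselSegment(
                sid, s.nodes, s.path.copy(), s.radii.copy(), s.vessel_class,
                dict(s.meta))
        other.inlet_id = self.inlet_id
        other.outlet_id = self.outlet_id
        other._next_node = self._next_node
        other._next_seg = self._next_seg
        return other

    def __len__(self):
        return len(self.segments)


# -- validation -----------------------------------------------------------

def _component_is_tree(net: VascularNetwork, root: int, cls: tuple[str, ...]):
    """BFS over segments of the given classes from root; returns
    (node set, segment count, has_cycle)."""
    seen_nodes = {root}
    seen_segs: set[int] = set()
    cycle = False
    stack = [root]
    while stack:
        nid = stack.pop()
        for sid in net._adj.get(nid, ()):
            seg = net.segments[sid]
            if seg.vessel_class not in cls or sid in seen_segs:
                continue
            seen_segs.add(sid)
            a, b = seg.nodes
            nxt = b if a == nid else a
            if nxt in seen_nodes:
                cycle = True
            else:
                seen_nodes.add(nxt)
                stack.append(nxt)
    return seen_nodes, len(seen_segs), cycle


def validate_network(net: VascularNetwork, stage: str = "connected") -> list[str]:
    """Check stage-appropriate invariants; return a list of violations.

    stage: "seeded" | "grown" (arterial/venous components must each be a
    tree rooted at the inlet/outlet) or "connected" (single component with
    a capillary bed present).  An empty report means the network is valid.
    """
    report: list[str] = []
    if not net.nodes or not net.segments:
        return ["network is empty"]

    inlets = [n for n in net.nodes.values() if n.kind == "inlet-root"]
    outlets = [n for n in net.nodes.values() if n.kind == "outlet-root"]
    if len(inlets) > 1:
        report.append(f"expected at most one inlet-root, found {len(inlets)}")
    if len(outlets) > 1:
        report.append(f"expected at most one outlet-root, found {len(outlets)}")
    if not inlets and not outlets:
        report.append("network has no root node")
    if stage == "connected" and (len(inlets) != 1 or len(outlets) != 1):
        report.append("complete network needs exactly one inlet-root and "
                      "one outlet-root")

    for nid, node in net.nodes.items():
        if not np.all(np.isfinite(node.position)):
            report.append(f"node {nid}: non-finite position")
        if node.kind not in NODE_KINDS:
            report.append(f"node {nid}: unknown kind {node.kind!r}")

    seen_pairs: set[tuple[int, int]] = set()
    for sid, seg in net.segments.items():
        if np.any(seg.radii <= 0):
            report.append(f"segment {sid}: non-positive radius")
        if seg.vessel_class not in VESSEL_CLASSES:
            report.append(f"segment {sid}: unknown class {seg.vessel_class!r}")
        if len(seg.path) < 2:
            report.append(f"segment {sid}: path has fewer than 2 points")
            continue
        if len(seg.radii) != len(seg.path):
            report.append(f"segment {sid}: radii/path length mismatch")
        if seg.length_mm < seg.chord_mm - 1e-9:
            report.append(f"segment {sid}: path shorter than endpoint chord")
        a, b = seg.nodes
        for nid, pt in ((a, seg.path[0]), (b, seg.path[-1])):
            if nid not in net.nodes:
                report.append(f"segment {sid}: references missing node {nid}")
            elif np.linalg.norm(net.nodes[nid].position - pt) > 1e-6:
                report.append(
                    f"segment {sid}: path endpoint does not coincide with node {nid}")
        if (a, b) in seen_pairs:
            report.append(f"segment {sid}: duplicate segment between nodes {a}-{b}")
        seen_pairs.add((a, b))

    if report:
        return report

    if stage in ("seeded", "grown"):
        for root, cls, label in ((net.inlet_id, ("artery",), "arterial"),
                                 (net.outlet_id, ("vein",), "venous")):
            if root is None:
                continue
            nodes, nseg, cycle = _component_is_tree(net, root, cls)
            if cycle or nseg != len(nodes) - 1:
                report.append(f"{label} component not a tree")
        n_art = sum(1 for s in net.segments.values() if s.vessel_class == "artery")
        n_ven = sum(1 for s in net.segments.values() if s.vessel_class == "vein")
        if net.inlet_id is not None and n_art:
            reach, _, _ = _component_is_tree(net, net.inlet_id, ("artery",))
        if stage == "seeded" and any(
                s.vessel_class == "capillary" for s in net.segments.values()):
            report.append("capillaries present before the capillary stage")
    elif stage == "connected":
        if net.inlet_id is not None:
            reach, nseg, _ = _component_is_tree(
                net, net.inlet_id, ("artery", "vein", "capillary"))
            if net.outlet_id not in reach:
                report.append("inlet and outlet not connected")
            if len(reach) != len(net.nodes):
                missing = sorted(set(net.nodes) - reach)[:5]
                report.append(
                    f"network not a single component (e.g. nodes {missing})")
    else:
        report.append(f"unknown validation stage {stage!r}")
    return report


# -- summaries ------------------------------------------------------------

def network_summary(net: VascularNetwork) -> dict:
    """Counts, total length (mm), total vessel volume (µm³), radius range and
    a per-class breakdown.  Totals are plain sums over segments."""
    per_class = {c: {"n_segments": 0, "length_mm": 0.0, "volume_um3": 0.0}
                 for c in VESSEL_CLASSES}
    radii: list[float] = []
    for seg in net.segments.values():
        d = per_class[seg.vessel_class]
        d["n_segments"] += 1
        d["length_mm"] += seg.length_mm
        d["volume_um3"] += seg.volume_um3()
        radii.extend([float(np.min(seg.radii)), float(np.max(seg.radii))])
    return {
        "n_nodes": len(net.nodes),
        "n_segments": len(net.segments),
        "total_length_mm": sum(d["length_mm"] for d in per_class.values()),
        "total_volume_um3": sum(d["volume_um3"] for d in per_class.values()),
        "radius_min_um": min(radii) if radii else 0.0,
        "radius_max_um": max(radii) if radii else 0.0,
        "per_class": per_class,
    }


# -- Amira spatial-graph ASCII I/O ----------------------------------------
#
# Dialect (documented byte-exactly in docs/amira_dialect.md): AmiraMesh 3D
# ASCII header, `define VERTEX/EDGE/POINT` counts, a Parameters block with
# ContentType "HxSpatialGraph" and explicit units, then @-indexed data
# sections.  Node kind and vessel class are integer-coded label fields.

_KIND_CODE = {k: i for i, k in enumerate(NODE_KINDS)}


def write_amira_spatialgraph(net: VascularNetwork, destination) -> None:
    """Write the network as Amira HxSpatialGraph ASCII.

    Refuses to write an empty network.  Coordinates are mm, radii µm,
    both recorded in the Parameters block.
    """
    if not net.nodes or not net.segments:
        raise ValueError("refusing to write an empty network")
    node_ids = sorted(net.nodes)
    index = {nid: i for i, nid in enumerate(node_ids)}
    seg_ids = sorted(net.segments)
    npoints = sum(len(net.segments[s].path) for s in seg_ids)

    meta = dict(net.metadata)
    meta["node_ids"] = node_ids
    meta["segment_ids"] = seg_ids
    meta_json = json.dumps(meta, sort_keys=True).replace('"', '\\"')

    lines = [
        "# AmiraMesh 3D ASCII 3.0",
        "# retvasc spatial graph",
        "",
        f"define VERTEX {len(node_ids)}",
        f"define EDGE {len(seg_ids)}",
        f"define POINT {npoints}",
        "",
        "Parameters {",
        '    ContentType "HxSpatialGraph",',
        '    Units { Coordinates "mm", Radius "um" },',
        f'    RetvascMetadata "{meta_json}"',
        "}",
        "",
        "VERTEX { float[3] VertexCoordinates } @1",
        "VERTEX { int NodeKind } @2",
        "EDGE { int[2] EdgeConnectivity } @3",
        "EDGE { int NumEdgePoints } @4",
        "EDGE { int VesselClass } @5",
        "POINT { float[3] EdgePointCoordinates } @6",
        "POINT { float Radius } @7",
        "",
    ]
    f3 = lambda v: " ".join(f"{x:.9g}" for x in v)
    lines.append("@1")
    lines += [f3(net.nodes[n].position) for n in node_ids]
    lines.append("")
    lines.append("@2")
    lines += [str(_KIND_CODE[net.nodes[n].kind]) for n in node_ids]
    lines.append("")
    lines.append("@3")
    lines += [f"{index[net.segments[s].nodes[0]]} {index[net.segments[s].nodes[1]]}"
              for s in seg_ids]
    lines.append("")
    lines.append("@4")
    lines += [str(len(net.segments[s].path)) for s in seg_ids]
    lines.append("")
    lines.append("@5")
    lines += [str(_CLASS_CODE[net.segments[s].vessel_class]) for s in seg_ids]
    lines.append("")
    lines.append("@6")
    for s in seg_ids:
        lines += [f3(p) for p in net.segments[s].path]
    lines.append("")
    lines.append("@7")
    for s in seg_ids:
        lines += [f"{r:.9g}" for r in net.segments[s].radii]
    lines.append("")
    text = "\n".join(lines)
    if hasattr(destination, "write"):
        destination.write(text)
    else:
        with open(destination, "w") as fh:
            fh.write(text)


_DEF_RE = re.compile(r"^define\s+(\w+)\s+(\d+)\s*$")
_SECT_RE = re.compile(r"^(\w+)\s*\{\s*(\w+)(?:\[(\d+)\])?\s+(\w+)\s*\}\s*@(\d+)\s*$")


def read_amira_spatialgraph(source) -> VascularNetwork:
    """Parse the Amira HxSpatialGraph ASCII dialect written by
    :func:`write_amira_spatialgraph`.

    Unknown data fields are preserved in ``metadata['amira_extra_fields']``.
    Malformed headers, header/body count mismatches and non-numeric payload
    each raise :class:`AmiraFormatError` with a distinct message.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source) as fh:
            text = fh.read()
    lines = text.splitlines()
    if not lines or "AmiraMesh" not in lines[0]:
        raise AmiraFormatError("malformed header: missing AmiraMesh signature")

    counts: dict[str, int] = {}
    sections: dict[int, tuple[str, str, int, str]] = {}  # idx -> (group, dtype, width, name)
    meta: dict = {}
    for ln in lines:
        m = _DEF_RE.match(ln.strip())
        if m:
            counts[m.group(1)] = int(m.group(2))
        m = _SECT_RE.match(ln.strip())
        if m:
            group, dtype, width, name, idx = m.groups()
            sections[int(idx)] = (group, dtype, int(width or 1), name)
        if "RetvascMetadata" in ln:
            raw = ln.split('"', 1)[1].rsplit('"', 1)[0].replace('\\"', '"')
            try:
                meta = json.loads(raw)
            except json.JSONDecodeError:
                meta = {}
    for key in ("VERTEX", "EDGE", "POINT"):
        if key not in counts:
            raise AmiraFormatError(f"malformed header: missing define {key}")
    if not sections:
        raise AmiraFormatError("malformed header: no data sections declared")

    # split body into @-indexed blocks
    blocks: dict[int, list[str]] = {}
    current: list[str] | None = None
    for ln in lines:
        s = ln.strip()
        if re.fullmatch(r"@(\d+)", s):
            current = blocks.setdefault(int(s[1:]), [])
        elif current is not None and s and not s.startswith("#"):
            current.append(s)

    def parse_block(idx: int) -> np.ndarray:
        group, dtype, width, name = sections[idx]
        rows = blocks.get(idx, [])
        expect = counts[group]
        if len(rows) != expect:
            raise AmiraFormatError(
                f"count mismatch in section @{idx} ({name}): header declares "
                f"{expect} {group} rows, body has {len(rows)}")
        try:
            arr = np.array([[float(x) for x in r.split()] for r in rows])
        except ValueError as exc:
            raise AmiraFormatError(
                f"non-numeric payload in section @{idx} ({name})") from exc
        if expect and arr.shape[1] != width:
            raise AmiraFormatError(
                f"width mismatch in section @{idx} ({name})")
        return arr if expect else arr.reshape(0, width)

    known = {"VertexCoordinates": None, "NodeKind": None, "EdgeConnectivity": None,
             "NumEdgePoints": None, "VesselClass": None,
             "EdgePointCoordinates": None, "Radius": None}
    extra: dict[str, list] = {}
    for idx in sorted(sections):
        name = sections[idx][3]
        arr = parse_block(idx)
        if name in known:
            known[name] = arr
        else:
            extra[name] = arr.tolist()

    for req in ("VertexCoordinates", "EdgeConnectivity", "NumEdgePoints",
                "EdgePointCoordinates", "Radius"):
        if known[req] is None:
            raise AmiraFormatError(f"malformed header: missing {req} section")

    nep = known["NumEdgePoints"][:, 0].astype(int)
    if int(nep.sum()) != counts["POINT"]:
        raise AmiraFormatError(
            "count mismatch: NumEdgePoints sum disagrees with define POINT")

    net = VascularNetwork()
    kinds = (known["NodeKind"][:, 0].astype(int)
             if known["NodeKind"] is not None else np.full(counts["VERTEX"], 2))
    for i, pos in enumerate(known["VertexCoordinates"]):
        net.add_node(pos, NODE_KINDS[int(kinds[i])])
    classes = (known["VesselClass"][:, 0].astype(int)
               if known["VesselClass"] is not None
               else np.zeros(counts["EDGE"], dtype=int))
    pts = known["EdgePointCoordinates"]
    rad = known["Radius"][:, 0]
    off = 0
    for e, (a, b) in enumerate(known["EdgeConnectivity"].astype(int)):
        n = nep[e]
        net.add_segment(int(a), int(b), rad[off:off + n], path=pts[off:off + n],
                        vessel_class=VESSEL_CLASSES[int(classes[e])])
        off += n
    if extra:
        meta["amira_extra_fields"] = extra
    meta.pop("node_ids", None)
    meta.pop("segment_ids", None)
    net.metadata.update(meta)
    return net


# -- JSON dialect ----------------------------------------------------------

def write_json_network(net: VascularNetwork, destination) -> None:
    """Versioned JSON export (schema documented in docs/amira_dialect.md)."""
    doc = {
        "schema": "retvasc-network",
        "schema_version": JSON_SCHEMA_VERSION,
        "units": {"coordinates": "mm", "radius": "um"},
        "inlet_id": net.inlet_id,
        "outlet_id": net.outlet_id,
        "metadata": net.metadata,
        "nodes": [{"id": n.id, "position": n.position.tolist(), "kind": n.kind}
                  for n in (net.nodes[i] for i in sorted(net.nodes))],
        "segments": [{"id": s.id, "nodes": list(s.nodes),
                      "path": s.path.tolist(), "radii": s.radii.tolist(),
                      "vessel_class": s.vessel_class}
                     for s in (net.segments[i] for i in sorted(net.segments))],
    }
    if hasattr(destination, "write"):
        json.dump(doc, destination)
    else:
        with open(destination, "w") as fh:
            json.dump(doc, fh)


def read_json_network(source) -> VascularNetwork:
    if hasattr(source, "read"):
        doc = json.load(source)
    else:
        with open(source) as fh:
            doc = json.load(fh)
    if doc.get("schema") != "retvasc-network":
        raise ValueError("not a retvasc network JSON document")
    net = VascularNetwork(metadata=doc.get("metadata", {}))
    for nd in doc["nodes"]:
        node = VesselNode(nd["id"], np.array(nd["position"]), nd["kind"])
        net.nodes[node.id] = node
        net._adj[node.id] = set()
    net._next_node = max(net.nodes, default=-1) + 1
    for sd in doc["segments"]:
        seg = VesselSegment(sd["id"], tuple(sd["nodes"]), np.array(sd["path"]),
                            np.array(sd["radii"]), sd["vessel_class"])
        net.segments[seg.id] = seg
        for nid in seg.nodes:
            net._adj[nid].add(seg.id)
    net._next_seg = max(net.segments, default=-1) + 1
    net.inlet_id = doc.get("inlet_id")
    net.outlet_id = doc.get("outlet_id")
    return net
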