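"""Quantitative network statistics, segmentation scoring and rasterisation.

Branch morphometry (branching angle, inter-branch length, tortuosity,
diameter, vessel volume) is reported per retinal region — macula, optic
disc, periphery — matching how clinical OCT-A segmentations are analysed.
Tortuosity is the path length between branch points divided by their
Euclidean separation.  The Murray exponent of a network is recovered per
bifurcation by solving r_p^x = r_1^x + r_2^x with a bracketed root-finder.
Networks embed into image grids at OCT-A-like resolution (axial 6.3 µm,
lateral 21 µm) for mask generation and en-face projection.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .domain import RetinaDomain
from .growth import TREE_CLASSES, tree_structure
from .hemodynamics import FlowSolution
from .vascular_graph import VascularNetwork

log = logging.getLogger(__name__)

REGIONS = ("macula", "optic-disc", "periphery")


def label_regions(points, domain: RetinaDomain) -> np.ndarray:
    """Region label per point; the optic-disc test takes precedence over the
    macula on (non-physical) overlap, everything else is peripheral."""
    pts = np.atleast_2d(np.asarray(points, float))
    out = np.full(len(pts), "periphery", dtype=object)
    out[domain.in_macula(pts)] = "macula"
    out[domain.in_optic_disc(pts)] = "optic-disc"
    return out


def _direction_along(path: np.ndarray, from_start: bool,
                     probe_mm: float = 0.05) -> np.ndarray:
    """Mean direction over the first (or last) 50 µm of a path."""
    p = path if from_start else path[::-1]
    acc = 0.0
    for i in range(len(p) - 1):
        acc += float(np.linalg.norm(p[i + 1] - p[i]))
        if acc >= probe_mm:
            v = p[i + 1] - p[0]
            break
    else:
        v = p[-1] - p[0]
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


@dataclass
class BranchMetrics:
    branches: pd.DataFrame
    per_region: pd.DataFrame
    total_volume_um3: float


def compute_branch_metrics(net: VascularNetwork,
                           domain: RetinaDomain) -> BranchMetrics:
    """Per-branch geometry table plus per-region aggregates.

    A branch is an inter-bifurcation segment.  Branching angle is measured
    between the two daughter direction vectors (first 50 µm of each path)
    and attributed to both daughters; branches are assigned to the region of
    their midpoint.
    """
    rows = []
    angle_of: dict[int, float] = {}
    for cls in TREE_CLASSES:
        if (net.inlet_id if cls == "artery" else net.outlet_id) is None:
            continue
        t = tree_structure(net, cls)
        for nid in t.order:
            kids = t.children.get(nid, ())
            if len(kids) < 2:
                continue
            segs = [net.segments[t.parent_seg[c]] for c in kids]
            # rounded-radius key: float noise from path resampling must not
            # flip which daughters count as the two largest
            segs.sort(key=lambda s: (-round(s.mean_radius_um, 6), s.id))
            dirs = []
            for s in segs[:2]:
                start = s.nodes[0] == nid
                dirs.append(_direction_along(s.path, from_start=start))
            cosang = float(np.clip(np.dot(dirs[0], dirs[1]), -1.0, 1.0))
            ang = math.degrees(math.acos(cosang))
            for s in segs[:2]:
                angle_of[s.id] = ang
    total_volume = 0.0
    for sid, seg in net.segments.items():
        mid = 0.5 * (seg.path[0] + seg.path[-1])
        chord = seg.chord_mm
        tort = seg.length_mm / chord if chord > 0 else np.nan
        vol = seg.volume_um3()
        total_volume += vol
        rows.append({
            "segment_id": sid,
            "vessel_class": seg.vessel_class,
            "region": label_regions(mid[None, :], domain)[0],
            "length_um": seg.length_mm * 1000.0,
            "tortuosity": tort,
            "mean_diameter_um": 2.0 * seg.mean_radius_um,
            "volume_um3": vol,
            "angle_deg": angle_of.get(sid, np.nan),
        })
    df = pd.DataFrame(rows)
    if len(df):
        agg = df.groupby("region").agg(
            n_branches=("segment_id", "count"),
            length_um=("length_um", "mean"),
            tortuosity=("tortuosity", "mean"),
            mean_diameter_um=("mean_diameter_um", "mean"),
            volume_um3=("volume_um3", "sum"),
            angle_deg=("angle_deg", "mean"),
        ).reindex(REGIONS)
    else:
        agg = pd.DataFrame(index=pd.Index(REGIONS, name="region"))
    return BranchMetrics(df, agg, total_volume)


def fit_murray_exponent(net: VascularNetwork,
                        bracket: tuple = (0.5, 6.0)):
    """Per-bifurcation Murray exponent by bracketed root-finding.

    Solves r_p^x = r_1^x + r_2^x at every two-daughter bifurcation (radii
    taken at the node); returns (median exponent, per-bifurcation values,
    number of degenerate bifurcations skipped).
    """
    estimates = []
    skipped = 0
    for cls in TREE_CLASSES:
        if (net.inlet_id if cls == "artery" else net.outlet_id) is None:
            continue
        t = tree_structure(net, cls)
        for nid in t.order:
            kids = t.children.get(nid, ())
            if len(kids) != 2 or nid not in t.parent_seg:
                continue
            pseg = net.segments[t.parent_seg[nid]]
            rp = pseg.radii[-1] if pseg.nodes[1] == nid else pseg.radii[0]
            r1, r2 = (net.segments[t.parent_seg[c]].radii[
                0 if net.segments[t.parent_seg[c]].nodes[0] == nid else -1]
                for c in kids)
            if min(rp, r1, r2) <= 0 or rp <= max(r1, r2) * (1 + 1e-12):
                skipped += 1
                continue

            def f(x):
                return (r1 / rp) ** x + (r2 / rp) ** x - 1.0

            lo, hi = bracket
            if f(lo) * f(hi) > 0:
                skipped += 1
                continue
            estimates.append(brentq(f, lo, hi, xtol=1e-10))
    if len(estimates) < 1:
        raise ValueError("no usable bifurcations (need parent and two "
                         "daughter radii)")
    return float(np.median(estimates)), estimates, skipped


def dice_score(prediction: np.ndarray, label: np.ndarray) -> float:
    """Binary Dice overlap D = 2|L∩P| / (|P|+|L|); two empty masks score
    1.0 by convention (logged, since the ratio is 0/0 there)."""
    p = np.asarray(prediction).astype(bool)
    l = np.asarray(label).astype(bool)
    if p.shape != l.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {l.shape}")
    denom = int(p.sum()) + int(l.sum())
    if denom == 0:
        log.info("dice_score: both masks empty; returning 1.0 by convention")
        return 1.0
    return 2.0 * int((p & l).sum()) / denom


# -- rasterisation ---------------------------------------------------------

@dataclass
class ImageVolume:
    """Intensity grid with explicit voxel spacing (µm) and origin (mm).

    Axes are (x, y, z) with z the axial (depth) direction.
    """
    data: np.ndarray
    spacing_um: tuple            # (lateral, lateral, axial)
    origin_mm: np.ndarray
    meta: dict = field(default_factory=dict)

    def enface(self) -> np.ndarray:
        """Maximum-intensity projection along the axial direction."""
        return self.data.max(axis=2)

    def save_tiff(self, destination) -> None:
        import tifffile
        tifffile.imwrite(destination, np.moveaxis(self.data, 2, 0),
                         metadata={"spacing_um": list(self.spacing_um),
                                   "origin_mm": self.origin_mm.tolist()})


def rasterize_network(net: VascularNetwork,
                      lateral_um: float = 21.0, axial_um: float = 6.3,
                      bounds_mm: tuple | None = None,
                      weight: dict[int, float] | None = None,
                      max_voxels: int = int(3e8)) -> ImageVolume:
    """Render every segment as a filled tube of its radius.

    A voxel is inside a tube when its centre lies within the local radius of
    the segment axis.  ``weight`` optionally assigns a per-segment intensity
    (e.g. flow, or the bolus signal at a chosen time); otherwise the volume
    is a binary mask.  Networks extending beyond explicit ``bounds_mm`` are
    clipped with a warning.
    """
    if not net.segments:
        shape = (1, 1, 1)
        return ImageVolume(np.zeros(shape, dtype=np.float32),
                           (lateral_um, lateral_um, axial_um), np.zeros(3))
    pts = np.concatenate([s.path for s in net.segments.values()])
    rmax_mm = max(s.radii.max() for s in net.segments.values()) / 1000.0
    if bounds_mm is None:
        lo = pts.min(axis=0) - 2 * rmax_mm
        hi = pts.max(axis=0) + 2 * rmax_mm
    else:
        lo = np.asarray(bounds_mm[0], float)
        hi = np.asarray(bounds_mm[1], float)
        if np.any(pts < lo) or np.any(pts > hi):
            log.warning("rasterize_network: network exceeds bounds; clipping")
    spacing_mm = np.array([lateral_um, lateral_um, axial_um]) / 1000.0
    shape = np.maximum(1, np.ceil((hi - lo) / spacing_mm).astype(int))
    if int(np.prod(shape)) > max_voxels:
        raise ValueError(f"grid of {shape} voxels exceeds the safety limit")
    vol = np.zeros(tuple(shape), dtype=np.float32)

    for sid, seg in net.segments.items():
        value = 1.0 if weight is None else float(weight.get(sid, 0.0))
        if value == 0.0:
            continue
        for i in range(len(seg.path) - 1):
            p0, p1 = seg.path[i], seg.path[i + 1]
            r_mm = max(seg.radii[i], seg.radii[i + 1]) / 1000.0
            blo = np.minimum(p0, p1) - r_mm
            bhi = np.maximum(p0, p1) + r_mm
            i0 = np.maximum(0, np.floor((blo - lo) / spacing_mm).astype(int))
            i1 = np.minimum(shape - 1,
                            np.ceil((bhi - lo) / spacing_mm).astype(int))
            if np.any(i0 > i1):
                continue
            ax = [lo[k] + (np.arange(i0[k], i1[k] + 1) + 0.5) * spacing_mm[k]
                  for k in range(3)]
            gx, gy, gz = np.meshgrid(*ax, indexing="ij")
            centres = np.stack([gx, gy, gz], axis=-1)
            d = p1 - p0
            L2 = float(d @ d)
            if L2 == 0:
                dist = np.linalg.norm(centres - p0, axis=-1)
            else:
                t = np.clip(((centres - p0) @ d) / L2, 0.0, 1.0)
                proj = p0 + t[..., None] * d
                dist = np.linalg.norm(centres - proj, axis=-1)
            mask = dist <= r_mm
            sub = vol[i0[0]:i1[0] + 1, i0[1]:i1[1] + 1, i0[2]:i1[2] + 1]
            sub[mask] = np.maximum(sub[mask], value)
    return ImageVolume(vol, (lateral_um, lateral_um, axial_um), lo)


def enface_projection(vol: ImageVolume) -> np.ndarray:
    return vol.enface()


# -- perfusion density -----------------------------------------------------

def regional_perfusion_density(net: VascularNetwork, sol: FlowSolution,
                               domain: RetinaDomain) -> dict:
    """Flow delivered per unit area, per region (µL/min/mm²).

    Delivery is summed over arterial feeding segments — artery segments
    with a capillary neighbour at an endpoint — assigned to the region of
    their distal endpoint.  The macula density is measured over the annulus
    between the fovea and the macula outer radius; the peripheral density
    over the retina outside the macula and optic-disc regions.  Returns
    densities plus their macula/periphery ratio.
    """
    feed_flow = {r: 0.0 for r in REGIONS}
    for sid, seg in net.segments.items():
        if seg.vessel_class != "artery":
            continue
        has_cap = any(
            s.vessel_class == "capillary"
            for nid in seg.nodes for s in net.segments_at(nid))
        if not has_cap:
            continue
        region = label_regions(seg.path[-1][None, :], domain)[0]
        feed_flow[region] += abs(sol.segment_flow_ul_min.get(sid, 0.0))
    mac_area = math.pi * ((domain.macula_diameter_mm / 2) ** 2
                          - domain.fovea_radius_mm ** 2)
    disc_area = math.pi * (domain.optic_disc_diameter_mm / 2) ** 2
    periph_area = (math.pi * domain.retina_radius_mm ** 2
                   - math.pi * (domain.macula_diameter_mm / 2) ** 2 - disc_area)
    dens = {
        "macula": feed_flow["macula"] / mac_area if mac_area > 0 else 0.0,
        "optic-disc": feed_flow["optic-disc"] / disc_area if disc_area else 0.0,
        "periphery": feed_flow["periphery"] / periph_area if periph_area else 0.0,
    }
    dens["macula_over_periphery"] = (dens["macula"] / dens["periphery"]
                                     if dens["periphery"] > 0 else np.inf)
    return dens
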