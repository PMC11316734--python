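"""Vessel tortuosity and projection onto the curved eye surface.

Growth produces near-straight inter-bifurcation branches; real retinal
vessels, veins especially, undulate.  Each branch is displaced perpendicular
to its axis by the sum of two sinusoids,

    d'(x, r) = d(x, r) + a0·sin(x/τ0 + δ0) + a1·sin(x/τ1 + δ1),

with x the arclength, amplitudes a0 + a1 in multiples of the local radius
(sampled per vessel class) and periods τ0 ∈ [15, 25]·r, τ1 ∈ [30, 50]·r.
Phases are chosen so the displacement vanishes at both branch nodes, which
keeps bifurcation positions exact.  (The printed period ranges make τ0 the
higher-frequency oscillation; the conventional low/high frequency labels are
swapped relative to the ranges, so this module speaks only of periods.)

After the planar simulation the network is projected onto a hemisphere of
diameter 23–25 mm carrying macula-pit and optic-disc relief built from
Gaussian profiles; the azimuthal-equidistant inverse is used so radial arc
lengths from the projection centre are preserved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .domain import RetinaDomain
from .parameters import SimulationParameters
from .vascular_graph import VascularNetwork, resample_path

TREE_CLASSES = ("artery", "vein")


@dataclass
class TortuosityParameters:
    """Sinusoidal displacement parameters, radius-relative."""
    amplitude_total_r: dict = field(
        default_factory=lambda: {"artery": (1.0, 3.5), "vein": (1.0, 7.5)})
    period0_r: tuple = (15.0, 25.0)
    period1_r: tuple = (30.0, 50.0)

    @classmethod
    def from_simulation(cls, params: SimulationParameters) -> "TortuosityParameters":
        return cls(
            amplitude_total_r={
                "artery": (1.0, params["artery_tortuosity_amplitude_r"]),
                "vein": (1.0, params["vein_tortuosity_amplitude_r"])},
            period0_r=(params["tortuosity_period_low_r"],) * 2,
            period1_r=(params["tortuosity_period_high_r"],) * 2)


def apply_tortuosity(net: VascularNetwork, tort: TortuosityParameters,
                     rng: np.random.Generator,
                     amplitude_scale: float = 1.0) -> VascularNetwork:
    """Superimpose the two sinusoidal displacements on every tree branch.

    Displacement is in-plane, normal to the local vessel axis.  Per branch
    the sampled total amplitude is split randomly between the two modes and
    each period is snapped to an integer half-multiple of the branch length
    so both sine terms vanish exactly at the branch nodes.  Paths are
    re-densified after displacement (spacing min(radius, 50 µm)).  Set
    ``amplitude_scale=0`` for a geometric identity.
    """
    for seg in net.segments.values():
        if seg.vessel_class not in TREE_CLASSES:
            continue
        r_um = seg.mean_radius_um
        r_mm = r_um / 1000.0
        lo, hi = tort.amplitude_total_r[seg.vessel_class]
        total = float(rng.uniform(lo, hi)) * r_mm * amplitude_scale
        f = float(rng.uniform())
        a0, a1 = f * total, (1.0 - f) * total
        tau0 = float(rng.uniform(*tort.period0_r)) * r_mm
        tau1 = float(rng.uniform(*tort.period1_r)) * r_mm
        L = seg.length_mm
        if L <= 0:
            continue
        spacing = min(r_um, 50.0) / 1000.0
        path, radii = resample_path(seg.path, seg.radii, spacing)
        x = np.concatenate([[0.0], np.cumsum(
            np.linalg.norm(np.diff(path, axis=0), axis=1))])
        disp = np.zeros(len(path))
        for a, tau in ((a0, tau0), (a1, tau1)):
            if a <= 0 or tau <= 0:
                continue
            # snap the period so an integer number of half-waves fits: the
            # sine is then zero at both endpoints (phase matching at nodes)
            k = max(1, int(round(L / (math.pi * tau))))
            disp += a * np.sin(x * (k * math.pi / L))
        # in-plane normal of the local axis
        tang = np.gradient(path, axis=0)
        t2 = tang[:, :2]
        nrm = np.linalg.norm(t2, axis=1)
        nrm[nrm == 0] = 1.0
        normal = np.column_stack([-t2[:, 1] / nrm, t2[:, 0] / nrm])
        path = path.copy()
        path[:, :2] += normal * disp[:, None]
        path[0] = seg.path[0]
        path[-1] = seg.path[-1]
        seg.path, seg.radii = resample_path(path, radii, spacing)
    net.metadata["tortuosity_applied"] = True
    return net


# -- eye surface -----------------------------------------------------------

@dataclass
class GaussianRelief:
    """Radial relief feature: Σ amplitude·exp(−s²/(2 width²)) at arc
    distance s from the feature centre (amplitudes in mm, widths in mm;
    negative amplitude = pit/cup)."""
    centre_xy: np.ndarray
    amplitudes_mm: tuple
    widths_mm: tuple

    def offset(self, s: np.ndarray) -> np.ndarray:
        out = np.zeros_like(s, dtype=float)
        for a, w in zip(self.amplitudes_mm, self.widths_mm):
            out += a * np.exp(-s ** 2 / (2.0 * w ** 2))
        return out


class EyeSurface:
    """Hemisphere (posterior eye) with macula and optic-disc relief.

    The projection centre (planar origin = optic disc) sits at the posterior
    pole; the sphere centre lies at pole + R ẑ.  A surface point at arc
    distance ρ and azimuth φ from the pole has radius R + relief(ρ, φ).
    """

    def __init__(self, diameter_mm: float, reliefs: list[GaussianRelief],
                 pole_xy=np.zeros(2), mesh_resolution: int = 48):
        self.R = diameter_mm / 2.0
        self.reliefs = reliefs
        self.pole_xy = np.asarray(pole_xy, float)
        self.mesh_resolution = mesh_resolution
        self.centre = np.array([self.pole_xy[0], self.pole_xy[1], self.R])

    def relief_at_planar(self, pts2: np.ndarray) -> np.ndarray:
        """Total radial relief for planar (pre-projection) coordinates.

        Feature distances are measured in the planar chart, which the
        azimuthal-equidistant map renders as arc distances on the sphere.
        """
        pts2 = np.atleast_2d(pts2)
        out = np.zeros(len(pts2))
        for rel in self.reliefs:
            s = np.linalg.norm(pts2 - rel.centre_xy, axis=1)
            out += rel.offset(s)
        return out

    def point(self, pts2: np.ndarray, z_offset=0.0) -> np.ndarray:
        """Map planar points (azimuthal-equidistant chart) to 3-D surface
        points; positive z_offset moves toward the sphere centre (anterior,
        i.e. out-of-plane vessel excursions)."""
        pts2 = np.atleast_2d(np.asarray(pts2, float))
        rel = self.relief_at_planar(pts2)
        d = pts2 - self.pole_xy
        rho = np.linalg.norm(d, axis=1)
        beta = rho / self.R
        with np.errstate(invalid="ignore", divide="ignore"):
            u = np.where(rho[:, None] > 0, d / np.where(rho[:, None] == 0, 1,
                                                        rho[:, None]), 0.0)
        radius = self.R + rel - np.asarray(z_offset)
        sin_b, cos_b = np.sin(beta), np.cos(beta)
        direction = np.column_stack([u[:, 0] * sin_b, u[:, 1] * sin_b, -cos_b])
        return self.centre + radius[:, None] * direction

    def mesh(self):
        """Structured triangulated hemisphere mesh (trimesh.Trimesh)."""
        import trimesh
        n_r, n_a = self.mesh_resolution, self.mesh_resolution * 2
        rho_max = self.R * (math.pi / 2.0)
        verts = [self.point(self.pole_xy[None, :])[0]]
        rows = []
        for i in range(1, n_r + 1):
            rho = rho_max * i / n_r
            row = []
            for j in range(n_a):
                ang = 2 * math.pi * j / n_a
                p2 = self.pole_xy + rho * np.array([math.cos(ang), math.sin(ang)])
                row.append(len(verts))
                verts.append(self.point(p2[None, :])[0])
            rows.append(row)
        faces = []
        for j in range(n_a):
            faces.append([0, rows[0][j], rows[0][(j + 1) % n_a]])
        for i in range(len(rows) - 1):
            for j in range(n_a):
                a, b = rows[i][j], rows[i][(j + 1) % n_a]
                c, d = rows[i + 1][j], rows[i + 1][(j + 1) % n_a]
                faces.append([a, c, d])
                faces.append([a, d, b])
        return trimesh.Trimesh(vertices=np.array(verts),
                               faces=np.array(faces), process=False)


def build_eye_surface(params: SimulationParameters, domain: RetinaDomain,
                      pit_depth_mm: float = 0.15, pit_width_mm: float = 0.4,
                      cup_depth_mm: float = 0.3, cup_width_mm: float = 0.5,
                      rim_height_mm: float = 0.05,
                      rim_width_mm: float = 1.0) -> EyeSurface:
    """Hemisphere of the sampled eye diameter with fovea pit and disc cup.

    With all relief amplitudes zero the surface is an exact hemisphere.  The
    pit is a single negative Gaussian, so the radial offset at the fovea
    centre equals −pit_depth; the optic disc combines a negative cup and a
    shallow positive neuroretinal rim.
    """
    reliefs = []
    if pit_depth_mm or rim_height_mm:
        reliefs.append(GaussianRelief(domain.macula_centre[:2],
                                      (-pit_depth_mm,), (pit_width_mm,)))
    if cup_depth_mm or rim_height_mm:
        reliefs.append(GaussianRelief(domain.optic_disc_centre[:2],
                                      (-cup_depth_mm, rim_height_mm),
                                      (cup_width_mm, rim_width_mm)))
    return EyeSurface(params["eye_diameter_mm"], reliefs,
                      pole_xy=domain.optic_disc_centre[:2])


def project_to_surface(net: VascularNetwork,
                       surface: EyeSurface) -> VascularNetwork:
    """Map the planar network onto the eye surface.

    Planar distance from the projection centre becomes arc length on the
    sphere (azimuthal-equidistant inverse); relief offsets apply along the
    surface normal, and any planar out-of-plane excursion (z ≠ 0) is kept as
    an offset along the same normal.  Topology is unchanged; path lengths
    are those of the mapped polylines.
    """
    max_rho = surface.R * (math.pi / 2.0)
    for node in net.nodes.values():
        rho = np.linalg.norm(node.position[:2] - surface.pole_xy)
        if rho > max_rho + 1e-9:
            raise ValueError(
                f"node {node.id} at planar radius {rho:.2f} mm exceeds the "
                f"hemisphere coverage ({max_rho:.2f} mm)")
    pos_of = {}
    for nid, node in net.nodes.items():
        pos_of[nid] = surface.point(node.position[None, :2],
                                    z_offset=node.position[2])[0]
    for seg in net.segments.values():
        new = surface.point(seg.path[:, :2], z_offset=seg.path[:, 2])
        new[0] = pos_of[seg.nodes[0]]
        new[-1] = pos_of[seg.nodes[1]]
        seg.path = new
    for nid, node in net.nodes.items():
        node.position = pos_of[nid]
    net.metadata["projected"] = True
    return net
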