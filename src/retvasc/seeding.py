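"""L-system seeding of the central retinal artery and vein.

The seed network starts with a central retinal artery and vein at the optic
disc, oriented out-of-plane (parallel to the optic nerve), each branching
in-plane for a fixed number of generations.  Bifurcation geometry follows
Murray-law optimality: daughter radii split the parent under
r_p^γ = r_1^γ + r_2^γ and the daughter deflection angles derive from the
asymmetry ratio α = r_small / r_large:

    cos θ1 = [(1+α³)^{4/3} + α⁴ − 1] / [2 α² (1+α³)^{2/3}]      (small daughter)
    cos θ2 = [(1+α³)^{4/3} + 1 − α⁴] / [2 (1+α³)^{2/3}]          (large daughter)

Branching is asymmetric, with the larger daughter steered toward the macula
to create the characteristic arcades surrounding it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .domain import RetinaDomain
from .parameters import SimulationParameters
from .vascular_graph import VascularNetwork

log = logging.getLogger(__name__)


@dataclass
class BifurcationGeometry:
    """Daughter deflection angles (degrees) for an asymmetry ratio α.

    θ1 belongs to the smaller daughter and exceeds θ2 for α < 1: the
    smaller vessel deflects more from the parent axis.
    """
    alpha: float
    theta1_deg: float
    theta2_deg: float
    clamped: bool = False


def bifurcation_angles(alpha: float) -> BifurcationGeometry:
    """Optimal daughter deflection angles for asymmetry ratio ``alpha``.

    Cosines are clamped to [-1, 1] before arccos; clamping is logged.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    a3 = (1.0 + alpha ** 3)
    cos1 = (a3 ** (4.0 / 3.0) + alpha ** 4 - 1.0) / (2.0 * alpha ** 2 * a3 ** (2.0 / 3.0))
    cos2 = (a3 ** (4.0 / 3.0) + 1.0 - alpha ** 4) / (2.0 * a3 ** (2.0 / 3.0))
    clamped = not (-1.0 <= cos1 <= 1.0 and -1.0 <= cos2 <= 1.0)
    if clamped:
        log.warning("bifurcation_angles: cosine clamped at alpha=%g", alpha)
    t1 = math.degrees(math.acos(min(1.0, max(-1.0, cos1))))
    t2 = math.degrees(math.acos(min(1.0, max(-1.0, cos2))))
    return BifurcationGeometry(alpha, t1, t2, clamped)


def murray_daughter_radii(parent_radius: float, alpha: float,
                          gamma: float) -> tuple[float, float]:
    """Split a parent radius into (large, small) daughters.

    Satisfies r_large^γ + r_small^γ = r_parent^γ with r_small/r_large = α.
    Radii in µm (any consistent unit works: the relation is homogeneous).
    """
    if parent_radius <= 0 or gamma <= 0:
        raise ValueError("parent_radius and gamma must be positive")
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    r_large = parent_radius / (1.0 + alpha ** gamma) ** (1.0 / gamma)
    return r_large, alpha * r_large


def _rot2(v: np.ndarray, deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def _inside(domain: RetinaDomain | None, p2: np.ndarray) -> bool:
    """Inside the retina disc and clear of the (vessel-free) macula."""
    if domain is None:
        return True
    p3 = np.array([[p2[0], p2[1], 0.0]])
    return bool(domain.in_retina(p3)[0]) and not bool(domain.in_macula(p3)[0])


def grow_seed_network(params: SimulationParameters,
                      domain: RetinaDomain | None,
                      rng: np.random.Generator) -> VascularNetwork:
    """Grow the arterial and venous seed trees.

    Each tree's first segment points out of the retinal plane (the vessel
    arriving through the optic nerve head); the first bifurcation places one
    branch above and one below the retinal midline.  Subsequent branching is
    stochastic: inter-bifurcation length = factor × local calibre, asymmetry
    α ~ U(0.4, 0.9), per-angle Gaussian noise (sd from parameters), larger
    daughter steered toward the macula.  Branching stops after the configured
    generation count or on breaching the retina boundary.

    Pass ``domain=None`` for an unbounded plane (each tree then terminates
    with exactly 2^generations leaves).
    """
    gamma = params["murray_exponent"]
    factor = params["interbif_length_factor"]
    noise_sd = params["branch_angle_noise_sd_deg"]
    generations = int(params["seed_generations"])

    if domain is not None:
        disc = domain.optic_disc_centre[:2]
        macula = domain.macula_centre[:2]
        if domain.retina_radius_mm < domain.optic_disc_diameter_mm:
            raise ValueError("domain too small to place roots")
    else:
        disc = np.zeros(2)
        macula = np.array([4.5, 0.0])

    net = VascularNetwork(metadata={"stage": "seeded"})

    def seg_length_mm(radius_um: float) -> float:
        return factor * (2.0 * radius_um) / 1000.0

    for vessel_class, root_kind, y_off in (("artery", "inlet-root", -0.15),
                                           ("vein", "outlet-root", 0.15)):
        r_root = params.root_radius_um(vessel_class)
        surf = np.array([disc[0], disc[1] + y_off, 0.0])
        root = net.add_node(surf - np.array([0.0, 0.0, 0.5]), root_kind)
        top = net.add_node(surf, "bifurcation")
        net.add_segment(root.id, top.id, r_root, vessel_class=vessel_class,
                        meta={"generation": 0})

        # first bifurcation: one branch above, one below the retinal midline
        alpha = float(rng.uniform(0.4, 0.9))
        r_big, r_small = murray_daughter_radii(r_root, alpha, gamma)
        geo = bifurcation_angles(alpha)
        to_mac = macula - surf[:2]
        to_mac = to_mac / (np.linalg.norm(to_mac) or 1.0)
        base = math.degrees(math.atan2(to_mac[1], to_mac[0]))
        big_up = bool(rng.integers(2))
        branches = []  # (node, direction2d, radius, generation)
        for radius, theta, up in ((r_big, geo.theta2_deg, big_up),
                                  (r_small, geo.theta1_deg, not big_up)):
            ang = base + (60.0 if up else -60.0) + float(rng.normal(0, noise_sd))
            # keep the stated sides: above (+y) and below (-y) the midline
            d = _rot2(np.array([1.0, 0.0]), ang)
            if (d[1] > 0) != up:
                d = np.array([d[0], -d[1]])
            L = seg_length_mm(radius)
            end2 = surf[:2] + d * L
            node = net.add_node(np.array([end2[0], end2[1], 0.0]), "terminal")
            net.add_segment(top.id, node.id, radius, vessel_class=vessel_class,
                            meta={"generation": 1, "alpha": alpha})
            branches.append((node, d, radius, 1))

        # stochastic generations 2..N
        frontier = branches
        while frontier:
            node, u, r_parent, gen = frontier.pop(0)
            if gen >= generations:
                continue
            alpha = float(rng.uniform(0.4, 0.9))
            r_big, r_small = murray_daughter_radii(r_parent, alpha, gamma)
            geo = bifurcation_angles(alpha)
            pos = net.nodes[node.id].position
            to_mac = macula - pos[:2]
            nm = np.linalg.norm(to_mac)
            to_mac = to_mac / nm if nm > 0 else u
            # steer the larger daughter toward the macula: pick the rotation
            # sign that brings it closer to the macula bearing
            s = 1.0 if (u[0] * to_mac[1] - u[1] * to_mac[0]) >= 0 else -1.0
            grew = False
            for radius, theta, sign in ((r_big, geo.theta2_deg, s),
                                        (r_small, geo.theta1_deg, -s)):
                ang = sign * (theta + float(rng.normal(0, noise_sd)))
                d = _rot2(u, ang)
                L = seg_length_mm(radius)
                end2 = pos[:2] + d * L
                mid2 = pos[:2] + d * (L / 2.0)
                if not (_inside(domain, end2) and _inside(domain, mid2)):
                    continue
                child = net.add_node(np.array([end2[0], end2[1], 0.0]),
                                     "terminal")
                net.add_segment(node.id, child.id, radius,
                                vessel_class=vessel_class,
                                meta={"generation": gen + 1, "alpha": alpha})
                frontier.append((child, d, radius, gen + 1))
                grew = True
            if grew:
                net.nodes[node.id].kind = "bifurcation"
    net.metadata["parameters_seed"] = params.seed
    return net
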