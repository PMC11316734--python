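"""End-to-end orchestration: generate → flow → fluorescein → pathology →
stats → rasterise, with a replayable run manifest and toy fixtures used
throughout the test-suite."""

from __future__ import annotations

import json
import math
import time
from dataclasses import dataclass, field

import numpy as np

from . import analysis, augmentation, growth, hemodynamics, microvasculature
from .domain import RetinaDomain
from .parameters import (MICRO_RETINA_OVERRIDES, MINI_RETINA_OVERRIDES,
                         SimulationParameters, sample_parameters, stage_rng)
from .seeding import grow_seed_network
from .vascular_graph import VascularNetwork

DEFAULT_STAGES = ("seed", "leaves", "growth", "optimize", "trim",
                  "topology", "intersections", "macula", "tortuosity",
                  "capillaries", "av_crossings")


@dataclass
class RunManifest:
    seed: int
    parameters: dict
    stages: list = field(default_factory=list)

    def record(self, name: str, t0: float, status: str = "ok",
               warnings: list | None = None, **info):
        self.stages.append({"stage": name, "status": status,
                            "wall_s": round(time.perf_counter() - t0, 3),
                            "warnings": warnings or [], **info})

    def to_json(self, destination=None):
        doc = {"seed": self.seed, "parameters": self.parameters,
               "stages": self.stages}
        if destination is None:
            return json.dumps(doc, indent=2, default=str)
        with open(destination, "w") as fh:
            json.dump(doc, fh, indent=2, default=str)


def generate_retina(seed: int,
                    params: SimulationParameters | None = None,
                    overrides: dict | None = None,
                    stages=DEFAULT_STAGES,
                    preset: str | None = None):
    """Run the procedural generation pipeline.

    Returns (network, domain, parameters, manifest).  ``preset`` may be
    "mini" or "micro" for the reduced desk-scale configurations; explicit
    ``overrides`` apply on top.  Re-running with the same seed and
    configuration reproduces the network exactly.
    """
    if params is None:
        params = sample_parameters(seed)
        if preset == "mini":
            params = params.override(MINI_RETINA_OVERRIDES)
        elif preset == "micro":
            params = params.override(MICRO_RETINA_OVERRIDES)
        if overrides:
            params = params.override(overrides)
    domain = RetinaDomain.from_parameters(params)
    manifest = RunManifest(seed, dict(params.values))
    net = VascularNetwork()

    mac_c = domain.macula_centre[:2]
    mac_r = domain.macula_diameter_mm / 2.0
    ret_c = domain.disc_centre[:2]

    def keep_out_macula(p2):
        return (np.linalg.norm(p2 - mac_c) < mac_r
                or np.linalg.norm(p2 - ret_c) > domain.retina_radius_mm)

    def keep_out_fovea(p2):
        return (np.linalg.norm(p2 - mac_c) < domain.fovea_radius_mm
                or np.linalg.norm(p2 - ret_c) > domain.retina_radius_mm)

    def crosses_macula(p0, p1):
        return not growth._segment_clears_region(p0, p1, mac_c, mac_r)

    def crosses_fovea(p0, p1):
        return not growth._segment_clears_region(p0, p1, mac_c,
                                                 domain.fovea_radius_mm)

    for stage in stages:
        t0 = time.perf_counter()
        if stage == "seed":
            net = grow_seed_network(params, domain, stage_rng(seed, "seeding"))
        elif stage == "leaves":
            leaves = growth.distribute_leaf_nodes(
                domain, params["leaf_spacing_mm"], stage_rng(seed, "leaves"))
            growth.attach_leaf_nodes(net, leaves, stage_rng(seed, "leaves"),
                                     domain=domain)
        elif stage == "growth":
            growth.lattice_growth(net, params, domain,
                                  stage_rng(seed, "growth"))
        elif stage == "optimize":
            growth.optimize_geometry(net, params, keep_out=keep_out_macula,
                                     keep_out_segment=crosses_macula)
        elif stage == "trim":
            growth.trim_and_regrow(net, params, domain,
                                   stage_rng(seed, "growth"))
        elif stage == "topology":
            growth.topological_optimize(net, params, domain)
        elif stage == "intersections":
            growth.resolve_self_intersections(net, params, domain)
        elif stage == "macula":
            growth.grow_macula(net, params, domain, stage_rng(seed, "macula"))
            growth.optimize_geometry(
                net, params, keep_out=keep_out_fovea,
                keep_out_segment=crosses_fovea,
                movable_nodes={n for n in net.nodes
                               if domain.in_macula(
                                   net.nodes[n].position[None, :])[0]},
                pin_mm=params["pinning_distance_fraction"]
                * net.metadata.get("macula_leaf_spacing_mm", 0.3))
            growth.rescale_radii_to_root(net, params)
        elif stage == "tortuosity":
            tort = augmentation.TortuosityParameters.from_simulation(params)
            augmentation.apply_tortuosity(net, tort,
                                          stage_rng(seed, "tortuosity"))
        elif stage == "capillaries":
            spec = microvasculature.CapillaryBedSpec(
                capillary_radius_um=params["capillary_radius_um"],
                seed_density_mm2=params["capillary_seed_density_mm2"])
            microvasculature.build_capillary_bed_voronoi(
                net, domain, spec, stage_rng(seed, "capillaries"))
            net.metadata["stage"] = "connected"
        elif stage == "av_crossings":
            microvasculature.resolve_av_crossings(net)
        elif stage == "project":
            surface = augmentation.build_eye_surface(params, domain)
            augmentation.project_to_surface(net, surface)
        else:
            raise ValueError(f"unknown stage {stage!r}")
        manifest.record(stage, t0, n_nodes=len(net.nodes),
                        n_segments=len(net.segments))
    net.metadata["seed"] = seed
    return net, domain, params, manifest


def solve_flow(net, params):
    bc = hemodynamics.FlowBoundaryConditions.from_parameters(params)
    sol = hemodynamics.solve_poiseuille(net, bc)
    return bc, sol


# -- toy fixtures ----------------------------------------------------------

def make_toy_fixture(kind: str, seed: int = 0) -> VascularNetwork:
    """Deterministic minimal networks with analytically known cost, flow and
    metrics: single-vessel, Y-bifurcation, series-pair, parallel-pair,
    crossing-pair, mini-retina."""
    net = VascularNetwork(metadata={"fixture": kind})
    if kind == "single-vessel":
        a = net.add_node([0, 0, 0], "inlet-root")
        b = net.add_node([1.0, 0, 0], "outlet-root")
        net.add_segment(a.id, b.id, 50.0, vessel_class="artery")
    elif kind == "Y-bifurcation":
        a = net.add_node([0, 0, 0], "inlet-root")
        j = net.add_node([1.0, 0, 0], "bifurcation")
        c = net.add_node([1.8, 0.6, 0], "terminal")
        d = net.add_node([1.8, -0.6, 0], "terminal")
        r_d = 100.0 / 2.0 ** (1.0 / 3.0)     # exact Murray split at γ = 3
        net.add_segment(a.id, j.id, 100.0, vessel_class="artery")
        net.add_segment(j.id, c.id, r_d, vessel_class="artery")
        net.add_segment(j.id, d.id, r_d, vessel_class="artery")
    elif kind == "series-pair":
        a = net.add_node([0, 0, 0], "inlet-root")
        m = net.add_node([1.0, 0, 0], "interior")
        b = net.add_node([2.5, 0, 0], "outlet-root")
        net.add_segment(a.id, m.id, 60.0, vessel_class="artery")
        net.add_segment(m.id, b.id, 40.0, vessel_class="vein")
    elif kind == "parallel-pair":
        a = net.add_node([0, 0, 0], "inlet-root")
        u = net.add_node([1.0, 0.5, 0], "interior")
        v = net.add_node([1.0, -0.5, 0], "interior")
        b = net.add_node([2.0, 0, 0], "outlet-root")
        for mid in (u, v):
            net.add_segment(a.id, mid.id, 50.0, vessel_class="artery")
            net.add_segment(mid.id, b.id, 50.0, vessel_class="vein")
    elif kind == "crossing-pair":
        a = net.add_node([-1.0, 0, 0], "inlet-root")
        b = net.add_node([1.0, 0, 0], "terminal")
        c = net.add_node([0, -1.0, 0], "outlet-root")
        d = net.add_node([0, 1.0, 0], "terminal")
        net.add_segment(a.id, b.id, 60.0, vessel_class="artery")
        net.add_segment(c.id, d.id, 80.0, vessel_class="vein")
    elif kind == "mini-retina":
        net, _, _, _ = generate_retina(seed, preset="micro")
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return net
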