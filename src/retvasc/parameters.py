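"""The simulation parameter registry: definition, sampling and persistence.

Every tunable of the generator is declared once in :data:`PARAMETER_SPECS`
with its sampling distribution (normal / uniform / fixed), units and the
pipeline stage it governs.  A run samples one value per spec from a single
root random generator; sub-stages receive named substreams so stage-level
reproducibility survives reordering of stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import yaml


@dataclass(frozen=True)
class ParameterSpec:
    name: str
    distribution: str            # "normal" | "uniform" | "fixed"
    args: tuple                  # (mean, sd) | (lo, hi) | (value,)
    units: str = ""
    stage: str = ""
    positive: bool = True        # resample until > 0 (numeric only)

    def __post_init__(self):
        if self.distribution == "normal" and self.args[1] < 0:
            raise ValueError(f"{self.name}: sd must be >= 0")
        if self.distribution == "uniform" and self.args[0] > self.args[1]:
            raise ValueError(f"{self.name}: lo must be <= hi")

    def sample(self, rng: np.random.Generator):
        if self.distribution == "fixed":
            return self.args[0]
        for _ in range(1000):
            if self.distribution == "normal":
                v = float(rng.normal(*self.args))
            else:
                v = float(rng.uniform(*self.args))
            if not self.positive or v > 0:
                return v
        raise RuntimeError(f"could not sample positive value for {self.name}")


def _n(name, mean, sd, units="", stage=""):
    return ParameterSpec(name, "normal", (mean, sd), units, stage)


def _u(name, lo, hi, units="", stage=""):
    return ParameterSpec(name, "uniform", (lo, hi), units, stage)


def _f(name, value, units="", stage=""):
    return ParameterSpec(name, "fixed", (value,), units, stage, positive=False)


#: The full parameter registry.  Values named in the source physiology
#: (root calibres, Murray exponent, pressures, region sizes, ...) carry
#: their literature distributions; the remainder are documented defaults.
PARAMETER_SPECS: tuple[ParameterSpec, ...] = (
    _n("root_artery_calibre_um", 135.0, 15.0, "um", "seeding"),
    _n("root_vein_calibre_um", 151.0, 15.0, "um", "seeding"),
    _n("murray_exponent", 2.4, 0.11, "", "seeding"),
    _n("interbif_length_factor", 18.0, 3.0, "x calibre", "seeding"),
    _f("branch_angle_noise_sd_deg", 5.0, "deg", "seeding"),
    _f("seed_generations", 5, "", "seeding"),
    _f("calibre_interpretation", "diameter", "", "seeding"),
    _f("leaf_spacing_mm", 3.0, "mm", "growth"),
    _f("lattice_stride_max_um", 3000.0, "um", "growth"),
    _f("lattice_stride_min_um", 150.0, "um", "growth"),
    _f("lattice_iterations", 5, "", "growth"),
    _f("terminal_radius_um", 8.0, "um", "growth"),
    _f("pinning_distance_fraction", 0.5, "x leaf spacing", "growth"),
    _f("trim_alpha_threshold", 0.2, "", "growth"),
    _f("wbe_short_fraction", 0.5, "", "growth"),
    _f("cost_exponent_rho", 1.0, "", "growth"),
    _f("cost_exponent_lambda", 1.0, "", "growth"),
    _f("retina_radius_mm", 12.5, "mm", "domain"),
    _f("macula_offset_mm", 4.5, "mm", "domain"),
    _f("macula_diameter_mm", 5.5, "mm", "domain"),
    _f("optic_disc_diameter_mm", 3.6, "mm", "domain"),
    _f("fovea_radius_mm", 0.3, "mm", "domain"),
    _u("eye_diameter_mm", 23.0, 25.0, "mm", "projection"),
    _u("macula_flow_density_factor", 1.5, 2.0, "", "macula"),
    _f("macula_sparsity", 0.3, "", "macula"),
    _f("macula_angle_limit_deg", 90.0, "deg", "macula"),
    _f("capillary_radius_um", 4.0, "um", "capillaries"),
    _f("capillary_seed_density_mm2", 25.0, "1/mm^2", "capillaries"),
    _f("interleave_radius_threshold_um", 5.0, "um", "capillaries"),
    _u("artery_tortuosity_amplitude_r", 1.0, 3.5, "x r", "tortuosity"),
    _u("vein_tortuosity_amplitude_r", 1.0, 7.5, "x r", "tortuosity"),
    _u("tortuosity_period_low_r", 15.0, 25.0, "x r", "tortuosity"),
    _u("tortuosity_period_high_r", 30.0, 50.0, "x r", "tortuosity"),
    _n("arterial_inlet_pressure_mmhg", 56.2, 14.0, "mmHg", "flow"),
    _n("venous_outlet_pressure_mmhg", 20.0, 10.0, "mmHg", "flow"),
    _f("viscosity_mpa_s", 3.5, "mPa s", "flow"),
    _f("dr_occlusion_radius_um", 35.0, "um", "pathology"),
    _f("rvo_reduction_fraction", 0.8, "", "pathology"),
)

SPEC_BY_NAME = {s.name: s for s in PARAMETER_SPECS}

#: Named substreams handed to the pipeline stages.
STAGES = ("sampling", "seeding", "leaves", "growth", "macula", "capillaries",
          "tortuosity", "surface", "flow", "pathology", "misc")


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage generator derived from the run seed."""
    if stage not in STAGES:
        raise KeyError(f"unknown stage {stage!r}")
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(STAGES.index(stage),)))


@dataclass
class SimulationParameters:
    """One sampled value per registry entry, plus run provenance."""

    values: dict[str, Any]
    seed: int | None = None
    metadata: dict = field(default_factory=dict)

    def __getitem__(self, key):
        return self.values[key]

    def get(self, key, default=None):
        return self.values.get(key, default)

    def __contains__(self, key):
        return key in self.values

    def override(self, overrides: dict) -> "SimulationParameters":
        unknown = sorted(set(overrides) - set(SPEC_BY_NAME))
        if unknown:
            raise KeyError(f"unknown parameter name(s): {', '.join(unknown)}")
        values = dict(self.values)
        values.update(overrides)
        _check_support(values)
        return SimulationParameters(values, self.seed,
                                    {**self.metadata, "overrides": sorted(overrides)})

    def root_radius_um(self, vessel_class: str) -> float:
        """Root radius in µm, honouring the calibre interpretation switch."""
        cal = self.values[f"root_{vessel_class}_calibre_um"]
        if self.values.get("calibre_interpretation", "diameter") == "diameter":
            return cal / 2.0
        return cal


def _check_support(values: dict) -> None:
    for name, v in values.items():
        spec = SPEC_BY_NAME[name]
        if spec.distribution == "uniform":
            lo, hi = spec.args
            if not (lo <= float(v) <= hi):
                raise ValueError(
                    f"{name}={v} outside its support [{lo}, {hi}]")
        if spec.distribution == "normal" and float(v) <= 0:
            raise ValueError(f"{name}={v} must be strictly positive")
    if values["arterial_inlet_pressure_mmhg"] <= values["venous_outlet_pressure_mmhg"]:
        raise ValueError("arterial pressure must exceed venous pressure")


def sample_parameters(seed: int) -> SimulationParameters:
    """Draw a full parameter set; deterministic given ``seed``.

    Sampling that violates a joint invariant (arterial pressure must exceed
    venous pressure) is retried and the retry count recorded in metadata.
    """
    if seed < 0:
        raise ValueError("seed must be a non-negative integer")
    rng = stage_rng(seed, "sampling")
    values = {s.name: s.sample(rng) for s in PARAMETER_SPECS}
    resamples = 0
    while values["arterial_inlet_pressure_mmhg"] <= values["venous_outlet_pressure_mmhg"]:
        values["arterial_inlet_pressure_mmhg"] = SPEC_BY_NAME[
            "arterial_inlet_pressure_mmhg"].sample(rng)
        values["venous_outlet_pressure_mmhg"] = SPEC_BY_NAME[
            "venous_outlet_pressure_mmhg"].sample(rng)
        resamples += 1
    return SimulationParameters(values, seed, {"seed": seed,
                                               "pressure_resamples": resamples})


def save_parameters(params: SimulationParameters, destination) -> None:
    doc = {"seed": params.seed, "parameters": dict(params.values)}
    if hasattr(destination, "write"):
        yaml.safe_dump(doc, destination, sort_keys=True)
    else:
        with open(destination, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)


def load_parameters(source, seed: int | None = None) -> SimulationParameters:
    """Load a YAML config: ``seed`` plus any subset of parameter overrides.

    Parameters absent from the file are sampled from their distributions at
    the configured seed; unknown keys are rejected by name.
    """
    if hasattr(source, "read"):
        doc = yaml.safe_load(source)
    else:
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    doc = doc or {}
    if seed is None:
        seed = doc.get("seed", 0)
    overrides = doc.get("parameters", {})
    base = sample_parameters(int(seed))
    return base.override(overrides) if overrides else base


# -- desk-scale presets ----------------------------------------------------
#
# Reduced-domain configurations used by the examples, the test-suite and the
# result-reproduction script.  They shrink the domain and lattice schedule
# (fewer, coarser strides; shallower seed trees) so a network grows in
# seconds instead of hours; all physiology distributions are untouched.

MINI_RETINA_OVERRIDES: dict[str, Any] = {
    "retina_radius_mm": 5.0,
    "macula_offset_mm": 2.6,
    "macula_diameter_mm": 2.4,
    "optic_disc_diameter_mm": 1.4,
    "fovea_radius_mm": 0.25,
    "leaf_spacing_mm": 1.6,
    "lattice_stride_max_um": 1500.0,
    "lattice_stride_min_um": 350.0,
    "lattice_iterations": 3,
    "seed_generations": 4,
    "capillary_seed_density_mm2": 8.0,
}

MICRO_RETINA_OVERRIDES: dict[str, Any] = {
    "retina_radius_mm": 3.2,
    "macula_offset_mm": 1.9,
    "macula_diameter_mm": 1.6,
    "optic_disc_diameter_mm": 1.0,
    "fovea_radius_mm": 0.2,
    "leaf_spacing_mm": 1.2,
    "lattice_stride_max_um": 1000.0,
    "lattice_stride_min_um": 400.0,
    "lattice_iterations": 2,
    "seed_generations": 3,
    "capillary_seed_density_mm2": 6.0,
}
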