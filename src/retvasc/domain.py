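"""Geometric description of the eye used by the growth algorithms.

The simulation runs in a 2-D plane (z = 0) before projection onto the
hemispherical eye surface.  The optic disc sits at the planar origin; the
macula centre lies a fixed distance along +x (temporal direction).  All
coordinates in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class RetinaDomain:
    """Retina disc plus optic-disc / macula / fovea regions.

    The macula is a circular region centred on the fovea (clinical default
    5.5 mm diameter); the optic-disc region is a 3.6 mm diameter circle at
    the disc centre; the fovea proper is avascular.
    """

    retina_radius_mm: float = 12.5
    optic_disc_centre: np.ndarray = field(
        default_factory=lambda: np.zeros(3))
    optic_disc_diameter_mm: float = 3.6
    macula_centre: np.ndarray = field(
        default_factory=lambda: np.array([4.5, 0.0, 0.0]))
    macula_diameter_mm: float = 5.5
    fovea_radius_mm: float = 0.3
    eye_diameter_mm: float = 24.0
    # centre of the planar retina disc (optic disc by default)
    disc_centre: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.optic_disc_centre = np.asarray(self.optic_disc_centre, float)
        self.macula_centre = np.asarray(self.macula_centre, float)
        self.disc_centre = np.asarray(self.disc_centre, float)

    # -- region predicates (xy-plane tests) -------------------------------
    def _d2(self, points, centre) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, float))
        return np.linalg.norm(p[:, :2] - centre[:2], axis=1)

    def in_retina(self, points) -> np.ndarray:
        return self._d2(points, self.disc_centre) <= self.retina_radius_mm

    def in_macula(self, points) -> np.ndarray:
        return self._d2(points, self.macula_centre) <= self.macula_diameter_mm / 2

    def in_fovea(self, points) -> np.ndarray:
        return self._d2(points, self.macula_centre) <= self.fovea_radius_mm

    def in_optic_disc(self, points) -> np.ndarray:
        return self._d2(points, self.optic_disc_centre) <= self.optic_disc_diameter_mm / 2

    def validate(self) -> list[str]:
        report = []
        if self.fovea_radius_mm >= self.macula_diameter_mm / 2:
            report.append("fovea not strictly inside macula region")
        gap = np.linalg.norm(
            (self.macula_centre - self.optic_disc_centre)[:2])
        if gap < (self.macula_diameter_mm + self.optic_disc_diameter_mm) / 2:
            report.append("optic-disc and macula regions overlap")
        if (np.linalg.norm((self.macula_centre - self.disc_centre)[:2])
                + self.macula_diameter_mm / 2) > self.retina_radius_mm:
            report.append("macula region not inside retina disc")
        return report

    @classmethod
    def from_parameters(cls, params) -> "RetinaDomain":
        """Build a domain from a :class:`SimulationParameters` mapping."""
        macula_x = params.get("macula_offset_mm", 4.5)
        return cls(
            retina_radius_mm=params.get("retina_radius_mm", 12.5),
            optic_disc_diameter_mm=params["optic_disc_diameter_mm"],
            macula_centre=np.array([macula_x, 0.0, 0.0]),
            macula_diameter_mm=params["macula_diameter_mm"],
            fovea_radius_mm=params.get("fovea_radius_mm", 0.3),
            eye_diameter_mm=params["eye_diameter_mm"],
        )
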