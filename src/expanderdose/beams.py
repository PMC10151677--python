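"""Beam, arc and calibration specifications, and gantry geometry.

Gantry angle g (degrees) rotates the source in the axial (x-y) plane about
the isocenter: the beam unit vector is (sin g, cos g, 0), so g = 0 is the
anterior (AP) beam travelling along +y, g = 90 enters from +x.  SAD is
fixed at 100 cm; fields are defined at the isocenter plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .materials import SpectrumModel, build_spectrum_6mv

SAD_CM = 100.0


@dataclass
class BeamSpec:
    """A static photon beam."""

    spectrum: SpectrumModel
    field_x_cm: float  # aperture extent along e1 at isocenter
    field_z_cm: float  # aperture extent along z
    ssd_cm: float = 100.0
    gantry_deg: float = 0.0
    mu: float = 100.0
    isocenter_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.field_x_cm <= 0 or self.field_z_cm <= 0:
            raise ValueError("field sizes must be positive")
        if self.ssd_cm <= 0:
            raise ValueError("SSD must be positive")

    def geometry(self):
        """(source, iso, beam, e1, e2) in cm, world frame."""
        g = math.radians(self.gantry_deg)
        b = np.array([math.sin(g), math.cos(g), 0.0])
        e1 = np.array([math.cos(g), -math.sin(g), 0.0])
        e2 = np.array([0.0, 0.0, 1.0])
        iso = np.asarray(self.isocenter_mm, float) / 10.0
        src = iso - SAD_CM * b
        return src, iso, b, e1, e2


@dataclass
class ArcSpec:
    """A partial arc delivered as equally weighted control-point beams."""

    start_deg: float
    stop_deg: float
    direction: str = "ccw"  # ccw decreases the gantry angle (through 0)
    cp_spacing_deg: float = 2.0
    field_x_cm: float = 3.0
    field_z_cm: float = 3.0
    mu: float = 355.0
    isocenter_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.direction not in ("cw", "ccw"):
            raise ValueError("direction must be 'cw' or 'ccw'")
        span = self.span_deg
        if span > 360.0:
            raise ValueError("arc span exceeds 360 degrees")
        n = span / self.cp_spacing_deg
        if abs(n - round(n)) > 1e-9:
            raise ValueError("control-point spacing must divide the arc span")

    @property
    def span_deg(self) -> float:
        raw = (self.start_deg - self.stop_deg) if self.direction == "ccw" else (self.stop_deg - self.start_deg)
        span = raw % 360.0
        if span == 0.0 and raw != 0.0:
            span = 360.0  # full rotation
        return span

    def control_angles(self) -> np.ndarray:
        n = int(round(self.span_deg / self.cp_spacing_deg))
        sgn = -1.0 if self.direction == "ccw" else 1.0
        ang = (self.start_deg + sgn * self.cp_spacing_deg * np.arange(n + 1)) % 360.0
        if self.span_deg == 360.0:
            ang = ang[:-1]  # the closing point duplicates the start
        return ang


@dataclass
class CalibrationModel:
    """Machine calibration: 1 cGy/MU at dmax, 10x10 cm^2, SSD 100, water.

    ``output_factor`` converts the engine's native dose unit (per MU) to
    cGy so that the reference geometry delivers 1 cGy/MU at dmax.
    """

    output_factor: float  # cGy per engine-unit per MU
    engine: str
    reference: str = "10x10 cm^2, SSD 100 cm, water, dmax"

    def __post_init__(self) -> None:
        if self.output_factor <= 0:
            raise ValueError("output factor must be positive")


def default_ap_beam(model_spectrum: SpectrumModel | None = None, mu: float = 500.0) -> BeamSpec:
    """The slab-setup beam: 6 MV, 15 x 10 cm^2 at 100 SSD, AP, 500 MU."""
    return BeamSpec(
        spectrum=model_spectrum or build_spectrum_6mv(),
        field_x_cm=15.0,
        field_z_cm=10.0,
        ssd_cm=100.0,
        gantry_deg=0.0,
        mu=mu,
        isocenter_mm=(0.0, 0.0, 0.0),
    )


def default_partial_arc(mu: float = 355.0) -> ArcSpec:
    """The breast-setup arc: 6 MV 3x3 cm^2 conformal arc, 90 -> 270 ccw."""
    return ArcSpec(start_deg=90.0, stop_deg=270.0, direction="ccw", mu=mu)
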