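"""Dose containers and calibration to cGy."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .beams import CalibrationModel


@dataclass
class DoseGrid:
    """Per-voxel dose on the density-grid lattice.

    ``dose`` is in engine units (MeV/g per MU-weighted history batch mean)
    until calibrated, then cGy.  ``rel_uncertainty`` is the batch-based
    relative statistical uncertainty (1 sigma of the mean), defined where
    dose > 0; zero for the deterministic raytracer.
    """

    origin: np.ndarray
    spacing: np.ndarray
    dose: np.ndarray
    rel_uncertainty: np.ndarray
    engine: str
    histories: int = 0
    seed: int | None = None
    batches: int = 1
    mu: float = 1.0
    calibrated: bool = False

    def __post_init__(self) -> None:
        if np.any(self.dose < 0):
            raise ValueError("dose must be non-negative")

    @property
    def shape(self):
        return self.dose.shape

    def centers(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def world_to_index(self, point):
        idx = np.round((np.asarray(point, float) - self.origin) / self.spacing).astype(int)
        return tuple(idx)

    def metadata(self) -> dict:
        return dict(
            engine=self.engine, histories=int(self.histories),
            seed=self.seed, batches=int(self.batches), mu=float(self.mu),
            calibrated=bool(self.calibrated),
        )


def calibrate(dose: DoseGrid, cal: CalibrationModel) -> DoseGrid:
    """Scale an engine-unit DoseGrid to cGy via the reference output factor."""
    if cal.engine != dose.engine:
        raise ValueError(f"calibration is for engine {cal.engine!r}, dose from {dose.engine!r}")
    out = DoseGrid(
        dose.origin.copy(), dose.spacing.copy(),
        dose.dose * cal.output_factor, dose.rel_uncertainty.copy(),
        dose.engine, dose.histories, dose.seed, dose.batches, dose.mu, True,
    )
    return out
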