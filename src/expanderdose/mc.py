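"""Voxel Monte Carlo photon dose engine (driver).

Wraps the numba kernels in :mod:`.kernels`: builds per-material attenuation
tables on a log-energy grid, runs batched transport for statistical
uncertainty, and assembles a :class:`~expanderdose.dosegrid.DoseGrid` in
engine units of MeV/g per history, scaled by the beam MU.

Two modes: ``"vr"`` (default; expected-value march with sampled scatter,
low-discrepancy source sampling) and ``"analog"`` (plain Woodcock delta
tracking, used by the transport oracles).  Runs are deterministic for a
fixed seed, batch count and thread count (the kernels are single-threaded).
"""

from __future__ import annotations

import numpy as np

from . import kernels
from .artifacts import DensityGrid
from .beams import ArcSpec, BeamSpec, CalibrationModel
from .dosegrid import DoseGrid
from .materials import (
    MATERIALS,
    SpectrumModel,
    build_spectrum_6mv,
    energy_transfer_fraction,
    mixture_mass_attenuation,
)

NE = 96
E_MIN, E_MAX = 0.01, 10.0


def _material_tables(materials):
    """(mu, ftr, cum-PE, cum-PE+Compton) tables, shape (n_mat, NE)."""
    e = np.geomspace(E_MIN, E_MAX, NE)
    n = len(materials)
    mu = np.zeros((n, NE))
    ftr = np.zeros((n, NE))
    ppe = np.zeros((n, NE))
    ppc = np.zeros((n, NE))
    for i, name in enumerate(materials):
        m = MATERIALS[name]
        pe = np.asarray(mixture_mass_attenuation(m, e, "photoelectric"))
        co = np.asarray(mixture_mass_attenuation(m, e, "compton"))
        pp = np.asarray(mixture_mass_attenuation(m, e, "pair"))
        tot = pe + co + pp
        mu[i] = tot
        ftr[i] = np.asarray(energy_transfer_fraction(m, e))
        ppe[i] = pe / tot
        ppc[i] = (pe + co) / tot
    loge0 = np.log(E_MIN)
    invd = (NE - 1) / (np.log(E_MAX) - np.log(E_MIN))
    return e, mu, ftr, ppe, ppc, loge0, invd


def _grid_geometry(grid: DensityGrid):
    lo = (grid.origin - grid.spacing / 2.0) / 10.0  # cm, lower corner
    sp = grid.spacing / 10.0
    nx, ny, nz = grid.density.shape
    return lo, sp, nx, ny, nz


def _beam_arrays(beam: BeamSpec):
    src, iso, b, e1, e2 = beam.geometry()
    return src, iso, e1, e2, beam.field_x_cm / 2.0, beam.field_z_cm / 2.0


def mc_dose(
    grid: DensityGrid,
    beam: BeamSpec,
    histories: int,
    seed: int,
    batches: int = 10,
    mode: str = "vr",
) -> DoseGrid:
    """Monte Carlo dose for a static beam; engine units MeV/g x MU."""
    if histories < 1:
        raise ValueError("histories must be >= 1")
    if grid.density.size == 0:
        raise ValueError("empty grid")
    acc = _McAccumulator(grid, mode)
    acc.run_beam(beam, histories, seed, batches)
    return acc.finalize(beam.mu, histories, seed, batches)


def arc_dose(
    grid: DensityGrid,
    arc: ArcSpec,
    histories: int,
    seed: int,
    batches: int = 10,
    mode: str = "vr",
    spectrum: SpectrumModel | None = None,
    engine: str = "mc",
) -> DoseGrid:
    """Superpose equally weighted control-point beams along the arc.

    The history budget is split evenly across control points within each
    batch, so batch-to-batch scatter still estimates the uncertainty of the
    full arc dose.
    """
    spectrum = spectrum or build_spectrum_6mv()
    angles = arc.control_angles()
    mu_cp = arc.mu / len(angles)
    if engine == "raytrace":
        from .raytrace import raytrace_dose

        total = None
        for g in angles:
            beam = BeamSpec(spectrum, arc.field_x_cm, arc.field_z_cm, 100.0, g, mu_cp, arc.isocenter_mm)
            d = raytrace_dose(grid, beam)
            total = d if total is None else _add_dose(total, d)
        return total
    if histories < len(angles) * batches:
        raise ValueError("history budget smaller than batches x control points")
    acc = _McAccumulator(grid, mode)
    n_cp = max(1, histories // (batches * len(angles)))
    ss = np.random.SeedSequence(seed)
    states = ss.generate_state(batches * len(angles) * 4).astype(np.int64) % (2**31 - 1)
    k = 0
    for b in range(batches):
        for g in angles:
            beam = BeamSpec(spectrum, arc.field_x_cm, arc.field_z_cm, 100.0, g, mu_cp, arc.isocenter_mm)
            acc.run_single(beam, n_cp, int(states[k]), batch_index=b,
                           offsets=(states[k + 1] / 2**31, states[k + 2] / 2**31, states[k + 3] / 2**31))
            k += 4
    return acc.finalize(arc.mu, n_cp * batches * len(angles), seed, batches)


def _add_dose(a: DoseGrid, b: DoseGrid) -> DoseGrid:
    dose = a.dose + b.dose
    with np.errstate(invalid="ignore", divide="ignore"):
        unc = np.sqrt((a.rel_uncertainty * a.dose) ** 2 + (b.rel_uncertainty * b.dose) ** 2)
        rel = np.where(dose > 0, unc / np.where(dose > 0, dose, 1.0), 0.0)
    return DoseGrid(a.origin, a.spacing, dose, rel, a.engine, a.histories + b.histories,
                    a.seed, a.batches, a.mu + b.mu, a.calibrated)


N_SPLIT = 1  # first-scatter splitting factor of the vr engine (1 = no splitting)


class _McAccumulator:
    """Batched kernel runs on one lattice, merged into mean + uncertainty."""

    def __init__(self, grid: DensityGrid, mode: str):
        if mode not in ("vr", "analog"):
            raise ValueError("mode must be 'vr' or 'analog'")
        self.grid = grid
        self.mode = mode
        self.lo, self.sp, self.nx, self.ny, self.nz = _grid_geometry(grid)
        self.rho = np.ascontiguousarray(grid.density, dtype=np.float32).ravel()
        self.mat = np.ascontiguousarray(grid.labels, dtype=np.uint8).ravel()
        (self.e_grid, self.mu_tab, self.ftr_tab, self.ppe_tab, self.ppc_tab,
         self.loge0, self.invd) = _material_tables(grid.materials)
        # energy-dependent majorant: max over materials of mu/rho * max density
        maj = np.zeros(NE)
        for i, name in enumerate(grid.materials):
            sel = grid.labels == i
            if not sel.any():
                continue
            maj = np.maximum(maj, self.mu_tab[i] * float(grid.density[sel].max()))
        self.mumaj = np.maximum(maj, 1e-12)
        nvox = self.rho.size
        self.batch_doses: dict[int, np.ndarray] = {}
        self.batch_hist: dict[int, int] = {}
        self.ledger = np.zeros(3)

    def run_beam(self, beam: BeamSpec, histories: int, seed: int, batches: int):
        ss = np.random.SeedSequence(seed)
        states = ss.generate_state(batches * 4).astype(np.int64) % (2**31 - 1)
        n_b = max(1, histories // batches)
        for b in range(batches):
            self.run_single(
                beam, n_b, int(states[4 * b]), batch_index=b,
                offsets=(states[4 * b + 1] / 2**31, states[4 * b + 2] / 2**31, states[4 * b + 3] / 2**31),
            )

    def run_single(self, beam: BeamSpec, n: int, kernel_seed: int, batch_index: int, offsets):
        src, iso, e1, e2, h1, h2 = _beam_arrays(beam)
        dose = self.batch_doses.setdefault(batch_index, np.zeros(self.rho.size))
        self.batch_hist[batch_index] = self.batch_hist.get(batch_index, 0) + n
        ledger = np.zeros(3)
        sp_cdf = self.spectrum_cdf(beam.spectrum)
        args_geo = (self.loge0, self.invd, NE,
                    self.lo[0], self.lo[1], self.lo[2],
                    self.sp[0], self.sp[1], self.sp[2],
                    self.nx, self.ny, self.nz)
        if self.mode == "vr":
            kernels.run_batch_vr(
                n, kernel_seed, offsets[0], offsets[1], offsets[2],
                src[0], src[1], src[2], iso[0], iso[1], iso[2],
                e1[0], e1[1], e1[2], e2[0], e2[1], e2[2], h1, h2,
                beam.spectrum.energies, sp_cdf,
                self.rho, self.mat, self.mu_tab, self.ftr_tab, self.ppe_tab, self.ppc_tab,
                *args_geo, dose, ledger, N_SPLIT,
            )
        else:
            kernels.run_batch_analog(
                n, kernel_seed,
                src[0], src[1], src[2], iso[0], iso[1], iso[2],
                e1[0], e1[1], e1[2], e2[0], e2[1], e2[2], h1, h2,
                beam.spectrum.energies, sp_cdf,
                self.rho, self.mat, self.mu_tab, self.ppe_tab, self.ppc_tab, self.mumaj,
                *args_geo, dose, ledger,
            )
        self.ledger += ledger

    @staticmethod
    def spectrum_cdf(spectrum: SpectrumModel) -> np.ndarray:
        return np.cumsum(spectrum.weights)

    def finalize(self, mu: float, histories: int, seed, batches: int) -> DoseGrid:
        shape = (self.nx, self.ny, self.nz)
        bkeys = sorted(self.batch_doses)
        means = np.stack([self.batch_doses[b] / self.batch_hist[b] for b in bkeys])
        mean = means.mean(axis=0)
        if len(bkeys) > 1:
            sem = means.std(axis=0, ddof=1) / np.sqrt(len(bkeys))
        else:
            sem = np.zeros_like(mean)
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = np.where(mean > 0, sem / np.where(mean > 0, mean, 1.0), 0.0)
        voxel_cc = float(np.prod(self.sp))  # cm^3
        mass = self.rho * voxel_cc  # g
        dose = np.where(mass > 0, mean / mass, 0.0) * mu
        grid = DoseGrid(
            self.grid.origin.copy(), self.grid.spacing.copy(),
            dose.reshape(shape), rel.reshape(shape),
            engine=f"mc-{self.mode}", histories=histories, seed=seed,
            batches=len(bkeys), mu=mu,
        )
        grid.energy_ledger = dict(
            launched=float(self.ledger[0]), deposited=float(self.ledger[1]),
            escaped=float(self.ledger[2]),
        )
        return grid


# ---------------------------------------------------------------------------
# calibration & reference geometry
# ---------------------------------------------------------------------------
def water_reference_grid(spacing_mm=(4.0, 2.0, 4.0), lateral_cm: float = 24.0, depth_cm: float = 32.0) -> DensityGrid:
    """Homogeneous water phantom for the 10x10 reference conditions."""
    sp = np.asarray(spacing_mm, float)
    nx = int(lateral_cm * 10 / sp[0])
    ny = int(depth_cm * 10 / sp[1])
    nz = int(lateral_cm * 10 / sp[2])
    origin = np.array([-lateral_cm * 5 + sp[0] / 2, sp[1] / 2, -lateral_cm * 5 + sp[2] / 2])
    density = np.ones((nx, ny, nz), dtype=np.float32)
    labels = np.zeros((nx, ny, nz), dtype=np.uint8)
    return DensityGrid(origin, sp, density, labels, ("water",), "truth")


def central_axis_pdd(dose: DoseGrid, radius_mm: float = 10.0):
    """(depths_mm, dose) averaged over a small central-axis region."""
    xs = dose.centers(0)
    zs = dose.centers(2)
    selx = np.abs(xs) <= radius_mm
    selz = np.abs(zs) <= radius_mm
    prof = dose.dose[selx][:, :, selz].mean(axis=(0, 2))
    return dose.centers(1), prof


def calibrate_engine(
    engine: str = "mc-vr",
    spectrum: SpectrumModel | None = None,
    histories: int = 200_000,
    seed: int = 12345,
) -> CalibrationModel:
    """Build the 1 cGy/MU reference output factor for an engine.

    Runs the reference geometry (10x10 cm^2, SSD 100, water) with MU=1 and
    scales so the central-axis dmax dose is 1 cGy.
    """
    spectrum = spectrum or build_spectrum_6mv()
    grid = water_reference_grid()
    beam = BeamSpec(spectrum, 10.0, 10.0, 100.0, 0.0, 1.0, (0.0, 0.0, 0.0))
    if engine == "raytrace":
        from .raytrace import raytrace_dose

        dose = raytrace_dose(grid, beam)
    elif engine in ("mc-vr", "mc-analog"):
        dose = mc_dose(grid, beam, histories, seed, mode=engine.split("-")[1])
    else:
        raise ValueError(f"unknown engine {engine!r}")
    _, pdd = central_axis_pdd(dose)
    dmax_val = float(pdd.max())
    if dmax_val <= 0:
        raise RuntimeError("reference run produced no dose")
    return CalibrationModel(output_factor=1.0 / dmax_val, engine=dose.engine)
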