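"""Dose-comparison machinery: profiles, gamma index, DVH parameters,
port-effect differencing and the strategy-comparison report.

Sign convention throughout: positive percentage differences mean the
first-named run is hotter; port-effect differences are
100 (D_ref - D_test) / D_ref at matched voxels, so a positive value is an
underdose of the test run relative to the reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dosegrid import DoseGrid
from .phantoms import ContourMask


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------
@dataclass
class Profile:
    positions_mm: np.ndarray
    dose: np.ndarray
    rel_uncertainty: np.ndarray
    axis: int
    through_mm: tuple[float, float, float]

    def normalized(self, at_mm: float | None = None) -> "Profile":
        ref = self.dose.max() if at_mm is None else self.dose[np.argmin(np.abs(self.positions_mm - at_mm))]
        return Profile(self.positions_mm, self.dose / ref, self.rel_uncertainty, self.axis, self.through_mm)


def extract_profile(dose: DoseGrid, axis: int, through_mm, average_mm: float = 0.0) -> Profile:
    """1-D dose vs position along ``axis`` through a world point.

    ``average_mm`` averages laterally over a +/- window around the point
    (a film-sized probe: 5 mm reproduces a 1 x 1 cm^2 film patch), which
    suppresses single-voxel Monte Carlo noise.
    """
    idx = list(dose.world_to_index(through_mm))
    for a, i in enumerate(idx):
        if a != axis and not (0 <= i < dose.shape[a]):
            raise ValueError(f"point {through_mm} outside grid on axis {a}")
    if average_mm <= 0:
        sl = [slice(None) if a == axis else idx[a] for a in range(3)]
        return Profile(
            dose.centers(axis),
            dose.dose[tuple(sl)].astype(float),
            dose.rel_uncertainty[tuple(sl)].astype(float),
            axis,
            tuple(np.asarray(through_mm, float)),
        )
    sels = []
    for a in range(3):
        if a == axis:
            sels.append(slice(None))
        else:
            pos = dose.centers(a)
            sel = np.abs(pos - np.asarray(through_mm, float)[a]) <= average_mm + 1e-9
            sels.append(sel)
    sub = dose.dose[sels[0]][:, sels[1], :][:, :, sels[2]].astype(float)
    unc = dose.rel_uncertainty[sels[0]][:, sels[1], :][:, :, sels[2]].astype(float)
    lat_axes = tuple(a for a in range(3) if a != axis)
    mean = sub.mean(axis=lat_axes)
    n = sub.size / sub.shape[axis]
    abs_unc = np.sqrt(((unc * sub) ** 2).sum(axis=lat_axes)) / n
    rel = np.where(mean > 0, abs_unc / np.where(mean > 0, mean, 1.0), 0.0)
    return Profile(dose.centers(axis), mean, rel, axis, tuple(np.asarray(through_mm, float)))


# ---------------------------------------------------------------------------
# gamma index
# ---------------------------------------------------------------------------
@dataclass
class GammaResult:
    gamma: np.ndarray
    pass_rate: float
    dose_criterion_pct: float
    distance_criterion_mm: float
    local: bool = False


def gamma_index(
    reference: np.ndarray,
    evaluated: np.ndarray,
    spacing_mm,
    dose_criterion_pct: float,
    distance_criterion_mm: float,
    local: bool = False,
    subdivisions: int = 3,
    search_factor: float = 3.0,
) -> GammaResult:
    """Brute-force gamma between commensurable 1-D curves or 3-D volumes.

    Global normalization scales dose differences to the reference maximum
    (``local=True`` switches to point-local normalization).  The minimum is
    taken over evaluated positions within ``search_factor`` x the distance
    criterion, with the evaluated dose linearly interpolated at
    ``subdivisions`` points per voxel.  No shortcuts: every reference point
    searches its full neighbourhood.
    """
    ref = np.asarray(reference, float)
    ev = np.asarray(evaluated, float)
    if ref.shape != ev.shape:
        raise ValueError("reference and evaluated lattices differ")
    if ref.max() <= 0:
        raise ValueError("reference maximum must be positive")
    spacing = np.atleast_1d(np.asarray(spacing_mm, float))
    nd = ref.ndim
    if spacing.size == 1:
        spacing = np.repeat(spacing, nd)
    norm = ref.max()
    radius = search_factor * distance_criterion_mm

    # displacement stencil (in mm) on the subdivided lattice
    axes_offsets = []
    for a in range(nd):
        step = spacing[a] / subdivisions
        n = int(np.floor(radius / step))
        axes_offsets.append(np.arange(-n, n + 1) * step)
    grids = np.meshgrid(*axes_offsets, indexing="ij")
    disp = np.stack([g.ravel() for g in grids], axis=-1)
    dist2 = (disp**2).sum(axis=1)
    keep = dist2 <= radius**2
    disp = disp[keep]
    dist2 = dist2[keep]

    coords = np.meshgrid(*[np.arange(s) * spacing[a] for a, s in enumerate(ref.shape)], indexing="ij")
    points = np.stack([c.ravel() for c in coords], axis=-1)  # (npts, nd)
    gamma2 = np.full(points.shape[0], np.inf)
    axes_pos = [np.arange(s) * spacing[a] for a, s in enumerate(ref.shape)]
    ref_flat = ref.ravel()
    denom_dose = (dose_criterion_pct / 100.0) * (ref_flat if local else norm)
    denom_dose = np.where(denom_dose <= 0, np.inf, denom_dose)
    for k in range(disp.shape[0]):
        q = points + disp[k]
        ev_q = _interp_nd(ev, axes_pos, q)
        valid = ~np.isnan(ev_q)
        dd = (ev_q - ref_flat) / denom_dose
        g2 = dd**2 + dist2[k] / distance_criterion_mm**2
        g2 = np.where(valid, g2, np.inf)
        gamma2 = np.minimum(gamma2, g2)
    gamma = np.sqrt(gamma2).reshape(ref.shape)
    return GammaResult(gamma, float((gamma <= 1.0).mean()), dose_criterion_pct, distance_criterion_mm, local)


def _interp_nd(values: np.ndarray, axes_pos, query: np.ndarray) -> np.ndarray:
    """Multilinear interpolation; NaN outside the domain."""
    nd = values.ndim
    if nd == 1:
        x = query[:, 0]
        lo, hi = axes_pos[0][0], axes_pos[0][-1]
        out = np.interp(x, axes_pos[0], values)
        out = np.where((x < lo) | (x > hi), np.nan, out)
        return out
    # general multilinear
    idx_f = []
    for a in range(nd):
        pos = axes_pos[a]
        step = pos[1] - pos[0] if len(pos) > 1 else 1.0
        f = (query[:, a] - pos[0]) / step
        idx_f.append(f)
    out = np.zeros(query.shape[0])
    valid = np.ones(query.shape[0], bool)
    for a in range(nd):
        valid &= (idx_f[a] >= 0) & (idx_f[a] <= values.shape[a] - 1)
    base = [np.clip(np.floor(f).astype(int), 0, values.shape[a] - 2 if values.shape[a] > 1 else 0)
            for a, f in enumerate(idx_f)]
    frac = [f - b for f, b in zip(idx_f, base)]
    for corner in range(2**nd):
        w = np.ones(query.shape[0])
        idx = []
        for a in range(nd):
            bit = (corner >> a) & 1
            idx.append(np.minimum(base[a] + bit, values.shape[a] - 1))
            w = w * (frac[a] if bit else (1.0 - frac[a]))
        out += w * values[tuple(idx)]
    return np.where(valid, out, np.nan)


# ---------------------------------------------------------------------------
# DVH
# ---------------------------------------------------------------------------
@dataclass
class DVHResult:
    contour: str
    d1: float
    d10: float
    mean: float
    volume_cc: float

    def __post_init__(self) -> None:
        if not (self.d1 >= self.d10 >= 0):
            raise ValueError("DVH ordering violated: D1 >= D10 >= 0")


def dvh_parameters(dose: DoseGrid, mask: ContourMask) -> DVHResult:
    """D1, D10 (interpolated quantiles of the voxel-dose distribution:
    minimum dose to the hottest x% of the volume) and the mean dose."""
    if not mask.mask.any():
        raise ValueError("empty contour mask")
    vals = dose.dose[mask.mask].astype(float)
    d1, d10 = dose_at_volume(vals, 1.0), dose_at_volume(vals, 10.0)
    return DVHResult(mask.name, d1, d10, float(vals.mean()), mask.volume_cc)


def dose_at_volume(doses: np.ndarray, volume_pct: float) -> float:
    """Dx: linear-interpolated (1 - x/100) quantile of the voxel doses."""
    return float(np.quantile(np.asarray(doses, float), 1.0 - volume_pct / 100.0, method="linear"))


# ---------------------------------------------------------------------------
# port effect
# ---------------------------------------------------------------------------
@dataclass
class PortEffectProfile:
    positions_mm: np.ndarray
    difference_pct: np.ndarray  # 100 (D_ref - D_test) / D_ref
    uncertainty_pct: np.ndarray  # quadrature-propagated, 1 sigma
    axis: int
    max_underdose_pct: float
    max_underdose_position_mm: float
    max_overdose_pct: float
    max_overdose_position_mm: float


def port_effect(
    dose_with: DoseGrid,
    dose_without: DoseGrid,
    axis: int = 1,
    through_mm=(0.0, 0.0, 0.0),
    region_mm: tuple[float, float] | None = None,
    average_mm: float = 5.0,
) -> PortEffectProfile:
    """Percentage dose difference (no-port minus port) along a profile.

    ``region_mm`` restricts the reported extrema to a position window
    (e.g. the distal falloff); the profile is averaged laterally over a
    film-sized +/- ``average_mm`` patch.  Uncertainties of both runs
    propagate in quadrature onto the difference.
    """
    if dose_with.shape != dose_without.shape or not np.allclose(dose_with.spacing, dose_without.spacing):
        raise ValueError("dose lattices do not match")
    p_with = extract_profile(dose_with, axis, through_mm, average_mm)
    p_wo = extract_profile(dose_without, axis, through_mm, average_mm)
    ref = p_wo.dose
    ok = ref > 0
    diff = np.where(ok, 100.0 * (ref - p_with.dose) / np.where(ok, ref, 1.0), 0.0)
    unc = 100.0 * np.sqrt(
        (p_with.rel_uncertainty * np.where(ok, p_with.dose / np.where(ok, ref, 1.0), 0.0)) ** 2
        + (p_wo.rel_uncertainty * np.where(ok, p_with.dose / np.where(ok, ref, 1.0), 0.0)) ** 2
    )
    pos = p_with.positions_mm
    sel = ok.copy()
    if region_mm is not None:
        sel &= (pos >= region_mm[0]) & (pos <= region_mm[1])
    if not sel.any():
        raise ValueError("empty analysis region")
    i_under = np.argmax(np.where(sel, diff, -np.inf))
    i_over = np.argmin(np.where(sel, diff, np.inf))
    return PortEffectProfile(
        pos, diff, unc, axis,
        float(diff[i_under]), float(pos[i_under]),
        float(-diff[i_over]), float(pos[i_over]),
    )


# ---------------------------------------------------------------------------
# DVH difference report (strategy comparison tables)
# ---------------------------------------------------------------------------
def dvh_difference_report(
    runs: dict[str, DoseGrid],
    contours: dict[str, ContourMask],
    pairs=(("no-port", "RS1"), ("no-port", "RS2"), ("RS1", "RS2")),
    normalize_to: str = "first",
) -> pd.DataFrame:
    """Percentage DVH differences between strategy runs per contour.

    For each pair (A, B) and each of D1/D10/mean the entry is
    100 (A - B) / N with N the first-named run's value (``normalize_to
    = 'first'``); positive entries mean A is hotter.  The combined
    statistical uncertainty (quadrature of the contour-mean relative
    uncertainties of both runs) is included per pair.
    """
    for _, pair in enumerate(pairs):
        for r in pair:
            if r not in runs:
                raise ValueError(f"missing run {r!r}")
    shapes = {r.shape for r in runs.values()}
    if len(shapes) != 1:
        raise ValueError("runs are on different lattices")
    rows = []
    for cname, cmask in contours.items():
        dvh = {k: dvh_parameters(v, cmask) for k, v in runs.items()}
        unc = {k: _contour_mean_rel_unc(v, cmask) for k, v in runs.items()}
        row = {"contour": cname, "volume_cc": round(cmask.volume_cc, 2)}
        for a, b in pairs:
            for metric in ("d1", "d10", "mean"):
                va, vb = getattr(dvh[a], metric), getattr(dvh[b], metric)
                norm = va if normalize_to == "first" else runs[a].dose.max()
                row[f"{a}-{b} {metric.upper()} (%)"] = 100.0 * (va - vb) / norm
            row[f"{a}-{b} unc (%)"] = 100.0 * float(np.hypot(unc[a], unc[b]))
        rows.append(row)
    return pd.DataFrame(rows)


def _contour_mean_rel_unc(dose: DoseGrid, mask: ContourMask) -> float:
    """Dose-weighted mean relative uncertainty inside a contour.

    Dose weighting keeps cold, high-relative-noise voxels (which do not
    influence D1/D10/mean materially) from inflating the estimate.
    """
    vals = dose.rel_uncertainty[mask.mask]
    w = dose.dose[mask.mask]
    if vals.size == 0 or w.sum() <= 0:
        return 0.0
    return float(np.average(vals, weights=w))
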