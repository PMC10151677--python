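"""End-to-end study workflows.

Two studies mirror the irradiation setups: the wax-slab AP-field study
(port effect and RS1-vs-RS2 distal comparison) and the breast partial-arc
study (DVH strategy comparison on the shell contours).  These functions
are the single implementation used by both the command line and the
acceptance script.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import analysis, artifacts, io, mc, phantoms
from .beams import default_ap_beam, default_partial_arc
from .dosegrid import DoseGrid

#: world-y extent of the region distal to the wax slab (mm): between the
#: slab exit and the end of the downstream water stack
DISTAL_REGION_MM = (34.0, 130.0)


def wax_profile_point(model: str) -> tuple[float, float, float]:
    """Analysis profile: central axis, except through the AlloX2
    injection port (+x port of the dual-port assembly)."""
    if model == "AlloX2":
        return (phantoms.PORT_SPECS["AlloX2"]["port_separation"] / 2.0, 0.0, 0.0)
    return (0.0, 0.0, 0.0)


def build_wax_grids(model: str, bloom: bool = True, seed: int = 0):
    """Scene + truth/no-port/RS1/RS2 density grids for the slab setup."""
    scene = phantoms.build_wax_slab_scene(model)
    phantom = phantoms.voxelize(scene)
    ct = phantoms.synthesize_ct(phantom, bloom=bloom, seed=seed)
    truth = artifacts.DensityGrid.from_phantom(phantom)
    no_port = artifacts.no_port_grid(phantom)
    region = artifacts.default_override_region(ct)
    rs1 = artifacts.rs1_override(ct, override_region=region)
    rs2, pose = artifacts.rs2_register(ct, scene.template, override_region=region)
    return dict(scene=scene, phantom=phantom, ct=ct, truth=truth,
                no_port=no_port, rs1=rs1, rs2=rs2, rs2_pose=pose)


def run_wax_port_effect(
    model: str,
    histories: int,
    seed: int,
    outdir: Path | None = None,
    histories_without: int | None = None,
) -> dict:
    """Port effect in the slab setup: MC dose with the true port geometry
    vs the port substituted by wax; distal underdose and (for the PEEK
    port) the proximal backscatter overdose."""
    grids = build_wax_grids(model)
    beam = default_ap_beam()
    d_with = mc.mc_dose(grids["truth"], beam, histories, seed)
    d_without = mc.mc_dose(grids["no_port"], beam, histories_without or histories, seed + 1)
    through = wax_profile_point(model)
    prof = analysis.port_effect(d_with, d_without, axis=1, through_mm=through,
                                region_mm=DISTAL_REGION_MM)
    # proximal window: upstream of the port assembly, inside the stack
    # (the deepest port housing face sits at y ~ 18.4 mm)
    upstream = analysis.port_effect(d_with, d_without, axis=1, through_mm=through,
                                    region_mm=(8.0, 18.0))
    hi = d_with.dose > 0.5 * d_with.dose.max()
    out = dict(
        model=model,
        dose_with=d_with,
        dose_without=d_without,
        port_effect=prof,
        proximal=upstream,
        max_underdose_pct=prof.max_underdose_pct,
        backscatter_peak_pct=upstream.max_overdose_pct,
        median_rel_unc_high_dose_pct=100.0 * float(np.median(d_with.rel_uncertainty[hi])),
    )
    if outdir is not None:
        _write_wax(outdir, model, grids, out)
    return out


def run_wax_strategy_comparison(model: str, histories: int, seed: int) -> dict:
    """RS1-vs-RS2 distal-falloff dose difference in the slab setup.

    Both strategies run with the same engine, MU and seed; reported as the
    central-axis percentage difference 100 (RS1 - RS2)/RS2 averaged over
    the distal region beyond the slab.
    """
    grids = build_wax_grids(model)
    beam = default_ap_beam()
    d_rs1 = mc.mc_dose(grids["rs1"], beam, histories, seed)
    d_rs2 = mc.mc_dose(grids["rs2"], beam, histories, seed)
    through = wax_profile_point(model)
    p1 = analysis.extract_profile(d_rs1, 1, through, average_mm=5.0)
    p2 = analysis.extract_profile(d_rs2, 1, through, average_mm=5.0)
    sel = (p1.positions_mm >= DISTAL_REGION_MM[0]) & (p1.positions_mm <= DISTAL_REGION_MM[1])
    diff = 100.0 * (p1.dose[sel] - p2.dose[sel]) / p2.dose[sel]
    return dict(
        model=model, dose_rs1=d_rs1, dose_rs2=d_rs2,
        distal_diff_pct=float(diff.mean()),
        distal_diff_profile=diff,
        rs2_pose=grids["rs2_pose"],
    )


def run_wax_study(model: str, histories: int, seed: int, outdir: Path | None = None) -> dict:
    """Port effect + strategy comparison for one model (CLI entry)."""
    out = run_wax_port_effect(model, histories, seed, outdir=outdir)
    out.update(run_wax_strategy_comparison(model, histories, seed + 100))
    return out


def run_breast_study(
    model: str,
    histories: int,
    seed: int,
    outdir: Path | None = None,
    batches: int = 10,
) -> dict:
    """Partial-arc DVH comparison on the breast phantom.

    Runs the no-port, RS1 and RS2 density grids under the 90->270 ccw
    3x3 cm^2 conformal arc and tabulates the percentage DVH differences on
    the four 3-mm shell contours.
    """
    scene = phantoms.build_breast_scene(model)
    phantom = phantoms.voxelize(scene)
    ct = phantoms.synthesize_ct(phantom, bloom=True, seed=0)
    region = artifacts.default_override_region(ct)
    runs_grids = {
        "no-port": artifacts.no_port_grid(phantom),
        "RS1": artifacts.rs1_override(ct, override_region=region),
        "RS2": artifacts.rs2_register(ct, scene.template, override_region=region)[0],
    }
    arc = default_partial_arc()
    doses = {
        name: mc.arc_dose(grid, arc, histories, seed, batches=batches)
        for name, grid in runs_grids.items()
    }
    bag, contours = phantoms.make_shell_contours(phantom)
    report = analysis.dvh_difference_report(doses, contours)
    out = dict(model=model, doses=doses, contours=contours, bag=bag, report=report)
    if outdir is not None:
        io.write_table(Path(outdir) / f"dvh_differences_{model}.csv", report, {"model": model})
        for name, d in doses.items():
            io.write_dose_grid(Path(outdir) / f"arc_dose_{model}_{name}.mha", d)
    return out


def report_entry(report, contour: str, pair: str, metric: str) -> float:
    """Read one percentage entry from the DVH difference table."""
    row = report[report["contour"] == contour]
    if row.empty:
        raise KeyError(contour)
    return float(row[f"{pair} {metric.upper()} (%)"].iloc[0])


def _write_wax(outdir: Path, model: str, grids: dict, result: dict) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_phantom(outdir / f"phantom_{model}.mha", grids["phantom"])
    io.write_ct(outdir / f"ct_{model}.mha", grids["ct"])
    for tag in ("rs1", "rs2", "no_port"):
        io.write_density_grid(outdir / f"grid_{model}_{tag}.mha", grids[tag])
    io.write_dose_grid(outdir / f"dose_{model}_port.mha", result["dose_with"])
    io.write_dose_grid(outdir / f"dose_{model}_noport.mha", result["dose_without"])
    prof = result["port_effect"]
    import pandas as pd

    io.write_table(outdir / f"port_effect_{model}.csv", pd.DataFrame({
        "position_mm": prof.positions_mm,
        "difference_pct": prof.difference_pct,
        "uncertainty_pct": prof.uncertainty_pct,
    }), {"max_underdose_pct": prof.max_underdose_pct,
         "max_underdose_position_mm": prof.max_underdose_position_mm})
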