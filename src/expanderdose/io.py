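"""File formats and provenance.

Volumes are MetaImage (.mha via SimpleITK, lossless round trip); every
grid-like object gets a JSON sidecar with its lattice, provenance (config
hash, seed, package version) and object-specific metadata.  Arrays are
stored (x, y, z) in world axes; SimpleITK's (z, y, x) buffer order is
handled here.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dataclasses_field
from pathlib import Path

import numpy as np
import SimpleITK as sitk
import yaml

from . import __version__
from .artifacts import DensityGrid
from .dosegrid import DoseGrid
from .phantoms import DensityCurve, SyntheticCT, VoxelPhantom


@dataclass
class RunConfig:
    """Fully serializable pipeline configuration.

    Every stochastic stage carries an explicit seed; the config hash is
    recorded in all output sidecars so a result can be traced back to the
    exact settings that produced it.
    """

    scene: dict = dataclasses_field(default_factory=lambda: dict(
        model="DermaSpan", scene="wax", spacing_mm=None, seed=0, bloom=True))
    strategy: dict = dataclasses_field(default_factory=lambda: dict(
        rs1_threshold_density=2.0, rs2_search_voxels=3, rs2_search_rot_deg=10.0))
    engine: dict = dataclasses_field(default_factory=lambda: dict(
        type="mc", mode="vr", histories=2_000_000, batches=10, seed=1,
        cp_spacing_deg=2.0))
    analysis: dict = dataclasses_field(default_factory=lambda: dict(
        gamma_dose_pct=2.0, gamma_dta_mm=1.0, normalization="first"))

    def to_dict(self) -> dict:
        return {"scene": self.scene, "strategy": self.strategy,
                "engine": self.engine, "analysis": self.analysis}

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = load_config(path) or {}
        cfg = cls()
        for key in ("scene", "strategy", "engine", "analysis"):
            getattr(cfg, key).update(data.get(key, {}))
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @property
    def hash(self) -> str:
        return config_hash(self.to_dict())


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _provenance(extra: dict | None = None) -> dict:
    out = {"package": "expanderdose", "version": __version__}
    if extra:
        out.update(extra)
    return out


def write_volume(path, array: np.ndarray, origin, spacing) -> None:
    img = sitk.GetImageFromArray(np.ascontiguousarray(array.transpose(2, 1, 0)))
    img.SetOrigin(tuple(float(v) for v in origin))
    img.SetSpacing(tuple(float(v) for v in spacing))
    sitk.WriteImage(img, str(path), useCompression=False)


def read_volume(path):
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return arr, np.array(img.GetOrigin()), np.array(img.GetSpacing())


def _sidecar(path) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".json")


def write_density_grid(path, grid: DensityGrid, extra: dict | None = None) -> None:
    write_volume(path, grid.density.astype(np.float32), grid.origin, grid.spacing)
    label_path = str(path).replace(".mha", "_labels.mha")
    write_volume(label_path, grid.labels.astype(np.uint8), grid.origin, grid.spacing)
    meta = _provenance(extra)
    meta.update({"tag": grid.tag, "materials": list(grid.materials), "labels_file": Path(label_path).name})
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_density_grid(path) -> DensityGrid:
    density, origin, spacing = read_volume(path)
    meta = json.loads(_sidecar(path).read_text())
    labels, _, _ = read_volume(Path(path).parent / meta["labels_file"])
    return DensityGrid(origin, spacing, density, labels.astype(np.uint8),
                       tuple(meta["materials"]), meta["tag"])


def write_dose_grid(path, dose: DoseGrid, extra: dict | None = None) -> None:
    write_volume(path, dose.dose.astype(np.float64), dose.origin, dose.spacing)
    unc_path = str(path).replace(".mha", "_unc.mha")
    write_volume(unc_path, dose.rel_uncertainty.astype(np.float32), dose.origin, dose.spacing)
    meta = _provenance(extra)
    meta.update(dose.metadata())
    meta["uncertainty_file"] = Path(unc_path).name
    hi = dose.dose > 0.5 * dose.dose.max() if dose.dose.size and dose.dose.max() > 0 else None
    if hi is not None and hi.any():
        meta["median_rel_uncertainty_high_dose"] = float(np.median(dose.rel_uncertainty[hi]))
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_dose_grid(path) -> DoseGrid:
    dose, origin, spacing = read_volume(path)
    meta = json.loads(_sidecar(path).read_text())
    unc, _, _ = read_volume(Path(path).parent / meta["uncertainty_file"])
    return DoseGrid(origin, spacing, dose, unc.astype(float), meta["engine"],
                    meta["histories"], meta["seed"], meta["batches"], meta["mu"],
                    meta["calibrated"])


def write_ct(path, ct: SyntheticCT, extra: dict | None = None) -> None:
    write_volume(path, ct.hu.astype(np.int16), ct.origin, ct.spacing)
    meta = _provenance(extra)
    meta.update({"saturation_g_cm3": ct.curve.saturation})
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_ct(path) -> SyntheticCT:
    hu, origin, spacing = read_volume(path)
    meta = json.loads(_sidecar(path).read_text())
    return SyntheticCT(origin, spacing, hu.astype(np.int16), DensityCurve(meta["saturation_g_cm3"]))


def write_phantom(path, phantom: VoxelPhantom, extra: dict | None = None) -> None:
    write_volume(path, phantom.density.astype(np.float32), phantom.origin, phantom.spacing)
    label_path = str(path).replace(".mha", "_labels.mha")
    write_volume(label_path, phantom.labels.astype(np.uint8), phantom.origin, phantom.spacing)
    meta = _provenance(extra)
    meta.update({
        "materials": list(phantom.materials),
        "labels_file": Path(label_path).name,
        "scene": phantom.scene.name if phantom.scene else None,
        "model": phantom.scene.model if phantom.scene else None,
    })
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def write_table(path, frame, extra: dict | None = None) -> None:
    """CSV with a small JSON header block in '#' comments (provenance)."""
    meta = _provenance(extra)
    with open(path, "w", newline="") as fh:
        fh.write("# " + json.dumps(meta) + "\n")
        frame.to_csv(fh, index=False)
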