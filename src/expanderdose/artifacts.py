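"""CT metal-artifact handling: the RS1 and RS2 density-override strategies
and the no-port ground truth.

RS1 keeps the saturated CT density inside the bright artifact (the
window-level threshold region) and sets every other voxel of the override
contour to unit density.  RS2 rigidly registers the vendor port template to
the artifact and paints the true materials and densities at the recovered
pose, again with unit density elsewhere in the override contour.  Outside
the override contour both strategies keep the CT-converted densities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .materials import MATERIALS
from .phantoms import (
    ContourMask,
    PortTemplate,
    Scene,
    SyntheticCT,
    VoxelPhantom,
    port_mask,
)


@dataclass
class DensityGrid:
    """Densities (and material labels for the physics) on the CT lattice."""

    origin: np.ndarray
    spacing: np.ndarray
    density: np.ndarray  # g/cm^3
    labels: np.ndarray  # uint8 codes into ``materials`` (composition lookup)
    materials: tuple[str, ...]
    tag: str  # RS1 | RS2 | truth | no-port

    def __post_init__(self) -> None:
        if np.any(self.density <= 0):
            raise ValueError("densities must be positive")

    @classmethod
    def from_phantom(cls, phantom: VoxelPhantom, tag: str = "truth") -> "DensityGrid":
        return cls(
            phantom.origin.copy(), phantom.spacing.copy(),
            phantom.density.astype(np.float32).copy(), phantom.labels.copy(),
            phantom.materials, tag,
        )


@dataclass
class RigidPose:
    """Axial-plane rigid pose: translation (mm) and z rotation (rad)."""

    translation: tuple[float, float, float]
    rotation: float = 0.0

    def __post_init__(self) -> None:
        r = (self.rotation + math.pi) % (2 * math.pi) - math.pi
        self.rotation = math.pi if r == -math.pi else r


class RegistrationError(RuntimeError):
    pass


def default_override_region(ct: SyntheticCT, margin_mm: float = 10.0) -> ContourMask:
    """Default override contour: the bag (breast scene) or the bright
    artifact's bounding box (slab scene), expanded by a 1 cm margin."""
    phantom = ct.phantom
    if phantom is not None and phantom.scene is not None and phantom.scene.name == "breast":
        codes = [phantom.material_code(m) for m in ("water", "silicone")]
        base = np.isin(phantom.labels, codes) | port_mask(phantom)
    else:
        base = ct.hu >= ct.curve.hu_max
        if not base.any():
            raise ValueError("no bright artifact to build an override region around")
        idx = np.array(np.nonzero(base))
        lo, hi = idx.min(axis=1), idx.max(axis=1)
        box = np.zeros_like(base)
        box[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1] = True
        base = box
    n = np.maximum(np.round(margin_mm / ct.spacing).astype(int), 1)
    region = base
    for ax, ni in enumerate(n):  # separable box dilation
        size = [1, 1, 1]
        size[ax] = 2 * int(ni) + 1
        region = ndimage.maximum_filter(region, size=tuple(size))
    return ContourMask("override_region", region, ct.spacing)


def artifact_mask(ct: SyntheticCT, threshold_hu: float, n_components: int) -> np.ndarray:
    """Bright-artifact voxels: >= threshold, largest connected components."""
    hu = ct.hu
    if threshold_hu > hu.max():
        raise ValueError(f"threshold {threshold_hu} HU above image maximum {hu.max()}")
    mask = hu >= threshold_hu
    lab, n = ndimage.label(mask)
    if n == 0:
        raise ValueError("empty artifact mask at threshold")
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    keep = np.argsort(sizes)[::-1][:n_components] + 1
    return np.isin(lab, keep)


def _threshold_for(ct: SyntheticCT, density: float = 2.0) -> float:
    """HU corresponding to a density on the conversion curve (RS1 default)."""
    return float(ct.curve.density_to_hu(np.array([density]))[0])


def rs1_override(
    ct: SyntheticCT,
    threshold_hu: float | None = None,
    override_region: ContourMask | None = None,
    n_components: int | None = None,
) -> DensityGrid:
    """RS1: window-level artifact + unit-density surround.

    The artifact keeps its (saturated) CT density and a water-equivalent
    composition; all other voxels inside the override contour are set to
    1.0 g/cm^3.
    """
    phantom = ct.phantom
    if threshold_hu is None:
        threshold_hu = _threshold_for(ct)
    if override_region is None:
        override_region = default_override_region(ct)
    if n_components is None:
        n_components = phantom.scene.port_count if phantom is not None and phantom.scene else 1
    art = artifact_mask(ct, threshold_hu, n_components)
    density = ct.density().astype(np.float32)
    materials = ("water", "air")
    labels = np.where(density < 0.3, 1, 0).astype(np.uint8)  # water-equivalent physics
    region = override_region.mask
    density = np.where(region & ~art, np.float32(1.0), density)
    labels[region] = 0
    return DensityGrid(ct.origin.copy(), ct.spacing.copy(), density, labels, materials, "RS1")


def _voxelize_template_masks(template: PortTemplate, grid_like, pose: RigidPose):
    """Labels of the template solids at a pose on the given lattice.

    Returns (labels int8 with -1 outside, material name list) restricted to
    the template bbox for speed.
    """
    origin, spacing, shape = grid_like
    placed = template.transformed(translation=pose.translation, rotation_z=pose.rotation)
    labels = np.full(shape, -1, dtype=np.int16)
    mats = [s.material for s in placed.solids]
    xs = origin[0] + spacing[0] * np.arange(shape[0])
    ys = origin[1] + spacing[1] * np.arange(shape[1])
    zs = origin[2] + spacing[2] * np.arange(shape[2])
    for si, solid in enumerate(placed.solids):
        lo, hi = solid.bbox()
        i0 = np.maximum(np.floor((lo - origin) / spacing).astype(int) - 1, 0)
        i1 = np.minimum(np.ceil((hi - origin) / spacing).astype(int) + 2, shape)
        if np.any(i0 >= i1):
            continue
        gx, gy, gz = np.meshgrid(xs[i0[0]:i1[0]], ys[i0[1]:i1[1]], zs[i0[2]:i1[2]], indexing="ij")
        inside = solid.contains(gx, gy, gz)
        sub = labels[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]]
        sub[inside] = si
        labels[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]] = sub
    return labels, mats


def _dice(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.logical_and(a, b).sum()
    s = a.sum() + b.sum()
    return 2.0 * inter / s if s else 0.0


def rs2_register(
    ct: SyntheticCT,
    template: PortTemplate,
    override_region: ContourMask | None = None,
    threshold_hu: float | None = None,
    search_voxels: int = 3,
    search_rot_deg: float = 10.0,
    rot_step_deg: float = 1.0,
    min_dice: float = 0.2,
) -> tuple[DensityGrid, RigidPose]:
    """RS2: rigid template registration + true-material override.

    The pose is initialized by matching the centroid of the bright-artifact
    mask with the centroid of the template's high-density footprint, then
    refined by an exhaustive local search (translation +/-``search_voxels``
    voxels per axis, axial rotation +/-10 deg in 1 deg steps) maximizing the
    Dice overlap between the voxelized template footprint and the artifact.
    Deterministic; ties break toward the smallest translation then rotation.
    """
    phantom = ct.phantom
    if threshold_hu is None:
        threshold_hu = _threshold_for(ct)
    if override_region is None:
        override_region = default_override_region(ct)
    n_comp = phantom.scene.port_count if phantom is not None and phantom.scene else 1
    art = artifact_mask(ct, threshold_hu, n_comp)
    grid_like = (ct.origin, ct.spacing, ct.hu.shape)

    # footprint = solids that saturate CT (density > curve saturation)
    dense_mats = {m for m in {s.material for s in template.solids} if MATERIALS[m].density > ct.curve.saturation}
    if not dense_mats:
        dense_mats = {template.solids[template.magnet_ids[0]].material}

    from .phantoms import solid_occupancy

    def footprint(pose: RigidPose) -> np.ndarray:
        """High-density template footprint: occupancy of the dense solids
        above the fraction at which a mixed voxel saturates the CT curve."""
        placed = template.transformed(translation=pose.translation, rotation_z=pose.rotation)
        origin, spacing, shape = grid_like
        frac = np.zeros(shape)
        xs = origin[0] + spacing[0] * np.arange(shape[0])
        ys = origin[1] + spacing[1] * np.arange(shape[1])
        zs = origin[2] + spacing[2] * np.arange(shape[2])
        for solid in placed.solids:
            if solid.material not in dense_mats:
                continue
            lo, hi = solid.bbox()
            i0 = np.maximum(np.floor((lo - origin) / spacing).astype(int) - 1, 0)
            i1 = np.minimum(np.ceil((hi - origin) / spacing).astype(int) + 2, shape)
            if np.any(i0 >= i1):
                continue
            sl = (slice(i0[0], i1[0]), slice(i0[1], i1[1]), slice(i0[2], i1[2]))
            frac[sl] += solid_occupancy(solid, xs[sl[0]], ys[sl[1]], zs[sl[2]], spacing)
        return frac >= 0.25

    art_com_idx = np.array(ndimage.center_of_mass(art))
    art_com = ct.origin + art_com_idx * ct.spacing
    fp0 = footprint(RigidPose((0.0, 0.0, 0.0)))
    if not fp0.any():
        raise RegistrationError("template footprint does not intersect the grid")
    fp_com = ct.origin + np.array(ndimage.center_of_mass(fp0)) * ct.spacing
    t0 = art_com - fp_com

    # evaluate Dice on a window around the artifact (search is local)
    idx = np.array(np.nonzero(art))
    pad = search_voxels + 4
    lo = np.maximum(idx.min(axis=1) - pad, 0)
    hi = np.minimum(idx.max(axis=1) + pad + 1, np.array(art.shape))
    win = tuple(slice(a, b) for a, b in zip(lo, hi))
    art_w = art[win]

    rots = np.deg2rad(np.arange(-search_rot_deg, search_rot_deg + rot_step_deg / 2, rot_step_deg))
    shifts = range(-search_voxels, search_voxels + 1)
    best = None
    for rot in sorted(rots, key=abs):
        base_fp = footprint(RigidPose(tuple(t0), rot))[win]
        for ix in shifts:
            for iy in shifts:
                for iz in shifts:
                    fp = np.roll(base_fp, (ix, iy, iz), axis=(0, 1, 2))
                    d = _dice(fp, art_w)
                    t = t0 + np.array([ix, iy, iz]) * ct.spacing
                    key = (-d, float(np.linalg.norm(t)), abs(rot))
                    if best is None or key < best[0]:
                        best = (key, RigidPose(tuple(t), rot))
    dice = -best[0][0]
    if dice < min_dice:
        raise RegistrationError(f"registration failed: best Dice {dice:.3f} < {min_dice}")
    pose = best[1]

    lab, mats = _voxelize_template_masks(template, grid_like, pose)
    density = ct.density().astype(np.float32)
    out_mats = ["water", "air"] + mats
    labels = np.where(density < 0.3, 1, 0).astype(np.uint8)
    region = override_region.mask
    density = np.where(region, np.float32(1.0), density)
    labels[region] = 0
    # paint the template with partial-volume densities (thin casing walls
    # and the magnet slab keep their areal density on the coarse lattice)
    placed = template.transformed(translation=pose.translation, rotation_z=pose.rotation)
    xs = ct.origin[0] + ct.spacing[0] * np.arange(ct.hu.shape[0])
    ys = ct.origin[1] + ct.spacing[1] * np.arange(ct.hu.shape[1])
    zs = ct.origin[2] + ct.spacing[2] * np.arange(ct.hu.shape[2])
    from .phantoms import solid_occupancy

    for solid in placed.solids:
        lo, hi = solid.bbox()
        i0 = np.maximum(np.floor((lo - ct.origin) / ct.spacing).astype(int) - 1, 0)
        i1 = np.minimum(np.ceil((hi - ct.origin) / ct.spacing).astype(int) + 2, ct.hu.shape)
        if np.any(i0 >= i1):
            continue
        frac = solid_occupancy(solid, xs[i0[0]:i1[0]], ys[i0[1]:i1[1]], zs[i0[2]:i1[2]], ct.spacing)
        sl = (slice(i0[0], i1[0]), slice(i0[1], i1[1]), slice(i0[2], i1[2]))
        density[sl] = (frac * MATERIALS[solid.material].density + (1.0 - frac) * density[sl]).astype(np.float32)
    in_tpl = lab >= 0
    labels[in_tpl] = (lab[in_tpl] + 2).astype(np.uint8)
    grid = DensityGrid(ct.origin.copy(), ct.spacing.copy(), density, labels, tuple(out_mats), "RS2")
    return grid, pose


def no_port_grid(phantom: VoxelPhantom) -> DensityGrid:
    """Ground truth with the port replaced by the enclosing medium.

    Re-voxelizes the scene without the port solids so that partial-volume
    halo voxels are also restored to the enclosing medium; the grids are
    identical outside the port footprint.
    """
    from dataclasses import replace as _replace

    from .phantoms import voxelize

    scene = phantom.scene
    if scene is None or not port_mask(phantom).any():
        raise ValueError("phantom contains no port")
    bare = _replace_solids(scene)
    ph2 = voxelize(bare, phantom.spacing)
    labels = ph2.labels.copy()
    # keep the original material table so label codes stay comparable
    remap = np.array([phantom.materials.index(m) if m in phantom.materials else 0
                      for m in ph2.materials], dtype=np.uint8)
    labels = remap[labels]
    return DensityGrid(phantom.origin.copy(), phantom.spacing.copy(),
                       ph2.density.astype(np.float32), labels, phantom.materials, "no-port")


def _replace_solids(scene: Scene) -> Scene:
    from dataclasses import replace as _replace

    solids = [s for s in scene.solids if s.name not in scene.port_solid_names]
    return _replace(scene, solids=solids)
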