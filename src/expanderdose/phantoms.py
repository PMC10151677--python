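"""Synthetic-data generator: port templates, irradiation scenes, voxel
phantoms, synthetic CT with metal artifacts, and analysis contours.

Geometry convention
-------------------
Patient-style axes in mm: x lateral (+x = left), y anterior-posterior with
the gantry-0 beam travelling along +y (anterior surface at small y), z
superior-inferior.  Voxel indices are 0-based; world coordinates refer to
voxel centers.  Densities are g/cm^3.

The port casing outer dimensions are canonical package defaults (the
vendor drawings are not public): they honour the printed magnet
thicknesses (2.41 / 2.50 / 7.14 mm), the printed 10.4 mm maximum lateral
extent of the AlloX2-Pro magnet, and the stated ~3x lateral-extent ratio
between the Ti-encased magnets and the PEEK-encased one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .materials import MATERIALS

MODELS = ("DermaSpan", "AlloX2", "AlloX2-Pro")

#: frozen default port dimensions, mm
PORT_SPECS = {
    "DermaSpan": dict(magnet_thickness=2.41, magnet_radius=15.6, casing_wall=0.6, casing_lateral_wall=1.4, casing="titanium"),
    "AlloX2": dict(magnet_thickness=2.50, magnet_radius=15.6, casing_wall=0.5, casing_lateral_wall=1.4, casing="titanium", port_separation=40.0),
    "AlloX2-Pro": dict(magnet_thickness=7.14, magnet_radius=5.2, casing_wall=1.5, casing_lateral_wall=1.5, casing="peek", port_separation=40.0),
}


# ---------------------------------------------------------------------------
# solids
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class Solid:
    """Analytic primitive: disc (finite cylinder), box, ellipsoid or
    ellipsoid shell, with an optional y <= clip plane (truncation)."""

    kind: str  # disc | box | ellipsoid | ellipsoid_shell
    center: tuple[float, float, float]
    params: dict
    material: str
    name: str = ""

    def translated(self, offset) -> "Solid":
        c = tuple(np.asarray(self.center, float) + np.asarray(offset, float))
        return replace(self, center=c)

    def rotated_z(self, angle_rad: float, about) -> "Solid":
        """Rigidly rotate about the z axis through ``about`` (axial plane)."""
        ca, sa = math.cos(angle_rad), math.sin(angle_rad)
        about = np.asarray(about, float)
        rel = np.asarray(self.center, float) - about
        c = about + np.array([ca * rel[0] - sa * rel[1], sa * rel[0] + ca * rel[1], rel[2]])
        params = dict(self.params)
        if "axis" in params:
            ax = np.asarray(params["axis"], float)
            params["axis"] = (ca * ax[0] - sa * ax[1], sa * ax[0] + ca * ax[1], ax[2])
        return replace(self, center=tuple(c), params=params)

    def contains(self, x, y, z) -> np.ndarray:
        cx, cy, cz = self.center
        dx, dy, dz = x - cx, y - cy, z - cz
        k = self.params
        if self.kind == "disc":
            ax = np.asarray(k.get("axis", (0.0, 1.0, 0.0)), float)
            ax = ax / np.linalg.norm(ax)
            h = dx * ax[0] + dy * ax[1] + dz * ax[2]
            r2 = dx * dx + dy * dy + dz * dz - h * h
            inside = (np.abs(h) <= k["half_height"]) & (r2 <= k["radius"] ** 2)
        elif self.kind == "box":
            hx, hy, hz = k["half_sizes"]
            inside = (np.abs(dx) <= hx) & (np.abs(dy) <= hy) & (np.abs(dz) <= hz)
        elif self.kind == "ellipsoid":
            a, b, c = k["half_axes"]
            inside = (dx / a) ** 2 + (dy / b) ** 2 + (dz / c) ** 2 <= 1.0
        elif self.kind == "ellipsoid_shell":
            a, b, c = k["outer"]
            ai, bi, ci = k["inner"]
            ro = (dx / a) ** 2 + (dy / b) ** 2 + (dz / c) ** 2
            ri = (dx / ai) ** 2 + (dy / bi) ** 2 + (dz / ci) ** 2
            inside = (ro <= 1.0) & (ri > 1.0)
        else:  # pragma: no cover
            raise ValueError(f"unknown solid kind {self.kind}")
        if "clip_ymax" in k:
            inside &= y <= k["clip_ymax"]
        return inside

    def bbox(self) -> tuple[np.ndarray, np.ndarray]:
        c = np.asarray(self.center, float)
        k = self.params
        if self.kind == "disc":
            r = math.hypot(k["radius"], k["half_height"])
            half = np.array([r, r, r])
        elif self.kind == "box":
            half = np.asarray(k["half_sizes"], float)
        elif self.kind == "ellipsoid":
            half = np.asarray(k["half_axes"], float)
        else:
            half = np.asarray(k["outer"], float)
        return c - half, c + half


# ---------------------------------------------------------------------------
# port templates
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class PortTemplate:
    """Parametric solids of one expander's port assembly, in a local frame
    whose origin is the registration reference point (assembly centroid).

    ``solids`` are ordered lowest-priority first; magnets override casings
    when voxelized.  ``magnet_ids`` index into ``solids``.
    """

    model: str
    solids: tuple[Solid, ...]
    reference_point: tuple[float, float, float]
    magnet_ids: tuple[int, ...]

    @property
    def magnet_thickness(self) -> float:
        return 2 * self.solids[self.magnet_ids[0]].params["half_height"]

    @property
    def magnet_lateral_extent(self) -> float:
        """Maximum extent perpendicular to the port axis (diameter), mm."""
        return 2 * self.solids[self.magnet_ids[0]].params["radius"]

    def transformed(self, translation=(0.0, 0.0, 0.0), rotation_z: float = 0.0) -> "PortTemplate":
        about = np.asarray(self.reference_point, float)
        solids = tuple(s.rotated_z(rotation_z, about).translated(translation) for s in self.solids)
        ref = tuple(about + np.asarray(translation, float))
        return replace(self, solids=solids, reference_point=ref)


def build_port_template(model: str) -> PortTemplate:
    """Construct the port assembly for one expander model.

    DermaSpan: one Ti casing disc with one NdFeB magnet.  AlloX2: two Ti
    ports, one magnet each.  AlloX2-Pro: two PEEK ports with a single
    narrow, thick magnet (10.4 mm diameter, 7.14 mm) between them in a PEEK
    housing.  The port axis is y (beam axis at gantry 0).
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    spec = PORT_SPECS[model]
    t, r = spec["magnet_thickness"], spec["magnet_radius"]
    wall, lwall = spec["casing_wall"], spec["casing_lateral_wall"]
    cas_mat = spec["casing"]

    def port(center, with_magnet=True):
        casing = Solid(
            "disc", center,
            dict(axis=(0, 1, 0), radius=r + lwall, half_height=t / 2 + wall),
            cas_mat, name="casing",
        )
        magnet = Solid("disc", center, dict(axis=(0, 1, 0), radius=r, half_height=t / 2), "ndfeb", name="magnet")
        return ([casing, magnet] if with_magnet else [casing])

    if model == "DermaSpan":
        solids = port((0.0, 0.0, 0.0))
        magnet_ids = (1,)
    elif model == "AlloX2":
        sep = spec["port_separation"]
        solids = port((-sep / 2, 0.0, 0.0)) + port((sep / 2, 0.0, 0.0))
        magnet_ids = (1, 3)
    else:  # AlloX2-Pro: two PEEK ports, single central magnet in PEEK housing
        sep = spec["port_separation"]
        ports = [
            Solid("disc", (-sep / 2, 0.0, 0.0), dict(axis=(0, 1, 0), radius=15.0, half_height=4.0), "peek", name="port"),
            Solid("disc", (sep / 2, 0.0, 0.0), dict(axis=(0, 1, 0), radius=15.0, half_height=4.0), "peek", name="port"),
        ]
        housing = Solid("disc", (0.0, 0.0, 0.0), dict(axis=(0, 1, 0), radius=r + lwall, half_height=t / 2 + wall), "peek", name="housing")
        magnet = Solid("disc", (0.0, 0.0, 0.0), dict(axis=(0, 1, 0), radius=r, half_height=t / 2), "ndfeb", name="magnet")
        solids = ports + [housing, magnet]
        magnet_ids = (len(solids) - 1,)
    return PortTemplate(model, tuple(solids), (0.0, 0.0, 0.0), magnet_ids)


# ---------------------------------------------------------------------------
# scenes
# ---------------------------------------------------------------------------
@dataclass
class Scene:
    """An irradiation scene: ordered solids (low priority first) over a
    background material, plus beam-relevant metadata."""

    name: str
    model: str
    solids: list[Solid]
    background: str
    bounds: tuple[tuple[float, float], tuple[float, float], tuple[float, float]]  # mm
    medium: str  # enclosing medium that replaces the port in the no-port grid
    isocenter: tuple[float, float, float]
    port_solid_names: tuple[str, ...] = ("casing", "magnet", "housing", "port")
    probe_planes_y: tuple[float, ...] = ()
    default_spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    port_count: int = 1
    template: PortTemplate | None = None


def build_wax_slab_scene(model: str) -> Scene:
    """Wax slab setup: 30x30x1.7 cm wax slab carrying the port, between
    1.5 cm water-equivalent upstream and 10 cm downstream; AP beam enters
    at y=0 (SSD 100 surface).  Probe planes sit at the film positions:
    upstream surface, slab interfaces and the distal falloff."""
    template = build_port_template(model)
    lat = 150.0
    upstream = Solid("box", (0, 7.5, 0), dict(half_sizes=(lat, 7.5, lat)), "water", name="plastic_water_up")
    slab = Solid("box", (0, 15 + 8.5, 0), dict(half_sizes=(lat, 8.5, lat)), "wax", name="wax_slab")
    downstream = Solid("box", (0, 32 + 50, 0), dict(half_sizes=(lat, 50.0, lat)), "water", name="plastic_water_down")
    port_center = (0.0, 23.5, 0.0)  # wax slab center
    placed = template.transformed(translation=port_center)
    solids = [upstream, slab, downstream, *placed.solids]
    # the voxel grid covers the 15x10 field plus margin; the slab solids
    # keep their full 30x30 cm extent (the far-out-of-field slab regions
    # contribute negligibly to central-axis scatter)
    return Scene(
        name="wax_slab",
        model=model,
        solids=solids,
        background="air",
        bounds=((-84.0, 84.0), (-6.0, 138.0), (-62.0, 62.0)),
        medium="wax",
        isocenter=(0.0, 0.0, 0.0),
        probe_planes_y=(0.0, 15.0, 32.0, 52.0),
        default_spacing=(2.0, 2.0, 2.0),
        port_count=1 if model == "DermaSpan" else 2,
        template=replace(placed, model=model),
    )


#: breast balloon half-axes (mm), frozen so the four 3-mm shell-contour
#: volumes match the reported contour volumes (~15-18 cc) within 20%
BALLOON_HALF_AXES = (46.0, 40.0, 46.0)
BALLOON_CUT_Y = 28.0  # posterior truncation plane (rests on the wax holder)


def build_breast_scene(model: str) -> Scene:
    """Breast phantom: water-filled balloon with ~1 mm silicone shell,
    truncated posteriorly where it rests in a wax holder, port assembly at
    the anterior apex region, 5 mm wax bolus wrapping the anterior surface.
    Only the dual-port models are used under the partial arc."""
    if model not in ("AlloX2", "AlloX2-Pro"):
        raise ValueError("breast scene supports AlloX2 and AlloX2-Pro only")
    template = build_port_template(model)
    a, b, c = BALLOON_HALF_AXES
    cut = dict(clip_ymax=BALLOON_CUT_Y)
    holder = Solid("box", (0, (BALLOON_CUT_Y + 70) / 2, 0), dict(half_sizes=(70.0, (70 - BALLOON_CUT_Y) / 2, 70.0)), "wax", name="holder")
    bolus = Solid(
        "ellipsoid_shell", (0, 0, 0),
        dict(outer=(a + 6, b + 6, c + 6), inner=(a + 1, b + 1, c + 1), clip_ymax=0.0),
        "wax", name="bolus",
    )
    shell = Solid("ellipsoid_shell", (0, 0, 0), dict(outer=(a + 1, b + 1, c + 1), inner=(a, b, c), **cut), "silicone", name="bag_shell")
    interior = Solid("ellipsoid", (0, 0, 0), dict(half_axes=(a, b, c), **cut), "water", name="bag_water")
    port_center = (0.0, -b + 22.0, 0.0)  # just inside the anterior apex
    placed = template.transformed(translation=port_center)
    solids = [holder, bolus, shell, interior, *placed.solids]
    return Scene(
        name="breast",
        model=model,
        solids=solids,
        background="air",
        bounds=((-72.0, 72.0), (-56.0, 72.0), (-72.0, 72.0)),
        medium="water",
        isocenter=(0.0, 0.0, 0.0),
        probe_planes_y=(-b - 6, 0.0, BALLOON_CUT_Y),
        default_spacing=(2.0, 2.0, 2.0),
        port_count=2,
        template=replace(placed, model=model),
    )


# ---------------------------------------------------------------------------
# voxelization
# ---------------------------------------------------------------------------
@dataclass
class VoxelPhantom:
    """Gridded density + material labels; the geometric ground truth."""

    origin: np.ndarray  # mm, center of voxel (0,0,0)
    spacing: np.ndarray  # mm
    density: np.ndarray  # g/cm^3, shape (nx, ny, nz)
    labels: np.ndarray  # uint8 material codes
    materials: tuple[str, ...]  # code -> material name
    scene: Scene | None = None

    @property
    def shape(self):
        return self.density.shape

    def voxel_volume_cc(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def centers(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def material_code(self, name: str) -> int:
        return self.materials.index(name)

    def world_to_index(self, point) -> tuple[int, ...]:
        idx = np.round((np.asarray(point, float) - self.origin) / self.spacing).astype(int)
        return tuple(idx)


#: solids with a bounding box smaller than this (mm^3) are rasterized with
#: supersampled partial-volume densities; larger slabs use center sampling
#: (their faces are grid-aligned).  Thin magnet/casing layers would
#: otherwise alias their areal density by tens of percent.
_SUPERSAMPLE_BBOX_MM3 = 1.5e6
_SUPERSAMPLE_N = 3  # subsamples per axis


def solid_occupancy(solid: Solid, xs, ys, zs, spacing, subdiv: int = _SUPERSAMPLE_N) -> np.ndarray:
    """Volume fraction of each voxel covered by the solid (supersampled)."""
    frac = np.zeros((len(xs), len(ys), len(zs)))
    offs = [(np.arange(subdiv) + 0.5) / subdiv - 0.5 for _ in range(3)]
    for ox in offs[0] * spacing[0]:
        for oy in offs[1] * spacing[1]:
            for oz in offs[2] * spacing[2]:
                gx, gy, gz = np.meshgrid(xs + ox, ys + oy, zs + oz, indexing="ij")
                frac += solid.contains(gx, gy, gz)
    return frac / subdiv**3


def voxelize(scene: Scene, spacing=None) -> VoxelPhantom:
    """Rasterize a scene onto a regular grid by priority overlay.

    Solids are painted in list order, so later solids (the port casing and
    the magnet, listed last) override earlier ones -- the layered-geometry
    rule.  Labels are resolved by majority-at-center sampling; densities of
    small solids (ports, shells) are partial-volume mixtures from
    supersampled occupancy so that thin layers keep their areal density.
    """
    if not scene.solids:
        raise ValueError("scene has no solids")
    spacing = np.asarray(spacing if spacing is not None else scene.default_spacing, float)
    if np.any(spacing <= 0):
        raise ValueError("spacing must be positive")
    (x0, x1), (y0, y1), (z0, z1) = scene.bounds
    shape = tuple(int(math.ceil((hi - lo) / sp)) for (lo, hi), sp in zip(scene.bounds, spacing))
    origin = np.array([x0, y0, z0]) + spacing / 2.0
    mat_names = [scene.background] + [s.material for s in scene.solids]
    # unique, order-preserving material table
    materials: list[str] = []
    for m in mat_names:
        if m not in materials:
            materials.append(m)
    labels = np.zeros(shape, dtype=np.uint8)
    density = np.full(shape, MATERIALS[scene.background].density)
    xs = origin[0] + spacing[0] * np.arange(shape[0])
    ys = origin[1] + spacing[1] * np.arange(shape[1])
    zs = origin[2] + spacing[2] * np.arange(shape[2])
    for solid in scene.solids:
        lo, hi = solid.bbox()
        i0 = np.maximum(np.floor((lo - origin) / spacing).astype(int) - 1, 0)
        i1 = np.minimum(np.ceil((hi - origin) / spacing).astype(int) + 2, shape)
        if np.any(i0 >= i1):
            continue
        sx, sy, szs = xs[i0[0]:i1[0]], ys[i0[1]:i1[1]], zs[i0[2]:i1[2]]
        gx, gy, gz = np.meshgrid(sx, sy, szs, indexing="ij")
        inside = solid.contains(gx, gy, gz)
        vol = float(np.prod(hi - lo))
        rho_s = MATERIALS[solid.material].density
        dsub = density[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]]
        if vol < _SUPERSAMPLE_BBOX_MM3:
            frac = solid_occupancy(solid, sx, sy, szs, spacing)
            dsub = frac * rho_s + (1.0 - frac) * dsub
        else:
            dsub = np.where(inside, rho_s, dsub)
        density[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]] = dsub
        lsub = labels[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]]
        lsub[inside] = materials.index(solid.material)
        labels[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]] = lsub
    return VoxelPhantom(origin, spacing, density, labels, tuple(materials), scene)


def port_mask(phantom: VoxelPhantom) -> np.ndarray:
    """Voxels belonging to the port assembly (casing + magnet + housing)."""
    scene = phantom.scene
    port_mats = {s.material for s in scene.solids if s.name in scene.port_solid_names}
    port_mats |= {"ndfeb"}
    codes = [i for i, m in enumerate(phantom.materials) if m in port_mats and m not in (scene.medium, scene.background)]
    return np.isin(phantom.labels, codes)


def magnet_mask(phantom: VoxelPhantom) -> np.ndarray:
    return phantom.labels == phantom.material_code("ndfeb")


# ---------------------------------------------------------------------------
# synthetic CT
# ---------------------------------------------------------------------------
@dataclass
class DensityCurve:
    """Piecewise-linear HU <-> density conversion with saturation.

    HU = 1000 (rho - 1) through (air, -1000), (water, 0); densities above
    ``saturation`` (CT table maximum, default 2.5 g/cm^3) are clipped to the
    saturated HU value, so metal maps back to the saturation density.
    """

    saturation: float = 2.5

    @property
    def hu_max(self) -> int:
        return int(round(1000.0 * (self.saturation - 1.0)))

    def density_to_hu(self, density) -> np.ndarray:
        hu = 1000.0 * (np.asarray(density, float) - 1.0)
        return np.clip(np.rint(hu), -1000, self.hu_max).astype(np.int16)

    def hu_to_density(self, hu) -> np.ndarray:
        return np.clip(np.asarray(hu, float) / 1000.0 + 1.0, 1e-3, self.saturation)


@dataclass
class SyntheticCT:
    origin: np.ndarray
    spacing: np.ndarray
    hu: np.ndarray  # int16
    curve: DensityCurve
    phantom: VoxelPhantom | None = None

    def density(self) -> np.ndarray:
        return self.curve.hu_to_density(self.hu)


def synthesize_ct(
    phantom: VoxelPhantom,
    saturation: float = 2.5,
    bloom: bool = True,
    streaks: bool = False,
    seed: int = 0,
    bloom_factor: float = 3.0,
) -> SyntheticCT:
    """Emulate the CT of a phantom with metal-artifact handling residue.

    Densities convert to HU through a saturating curve; with ``bloom`` on,
    the bright footprint of Ti-encased ports is dilated along the port axis
    until its thickness is ~``bloom_factor`` x the magnet thickness (the
    residual blooming after metal-artifact reduction).  The PEEK-encased
    AlloX2-Pro magnet shows no casing bloom: its bright footprint stays at
    ~1x the magnet dimensions.  Optional seeded low-amplitude streaks can be
    added outside the port (off by default).
    """
    if saturation <= 0:
        raise ValueError("saturation must be positive")
    curve = DensityCurve(saturation)
    hu = curve.density_to_hu(phantom.density)
    if bloom:
        bright = phantom.density > saturation  # Ti + magnet saturate; PEEK does not
        if bright.any():
            model = phantom.scene.model if phantom.scene else "DermaSpan"
            t_mag = (phantom.scene.template.magnet_thickness if phantom.scene and phantom.scene.template
                     else 2.5)
            ys = np.where(bright.any(axis=(0, 2)))[0]
            t_bright = (ys.max() - ys.min() + 1) * phantom.spacing[1]
            target = bloom_factor * t_mag if PORT_SPECS[model]["casing"] == "titanium" else t_bright
            pad_mm = max(0.0, (target - t_bright) / 2.0)
            ny = int(round(pad_mm / phantom.spacing[1]))
            nx = max(1, int(round(2.0 / phantom.spacing[0])))
            nz = max(1, int(round(2.0 / phantom.spacing[2])))
            if ny > 0:
                struct = np.zeros((2 * nx + 1, 2 * ny + 1, 2 * nz + 1), bool)
                cx, cy, cz = nx, ny, nz
                ii, jj, kk = np.indices(struct.shape)
                struct = ((ii - cx) / max(nx, 1e-9)) ** 2 + ((jj - cy) / max(ny, 1e-9)) ** 2 + ((kk - cz) / max(nz, 1e-9)) ** 2 <= 1.0
                bloomed = ndimage.binary_dilation(bright, structure=struct)
            else:
                bloomed = bright
            hu = np.where(bloomed, np.int16(curve.hu_max), hu)
    if streaks:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, 15.0, size=hu.shape)
        noise = ndimage.gaussian_filter(noise, sigma=2.0)
        inside = phantom.labels != phantom.material_code(phantom.scene.background) if phantom.scene else np.ones_like(hu, bool)
        hu = np.clip(hu + np.where(inside, noise, 0.0), -1000, curve.hu_max).astype(np.int16)
    return SyntheticCT(phantom.origin.copy(), phantom.spacing.copy(), hu.astype(np.int16), curve, phantom)


# ---------------------------------------------------------------------------
# contours
# ---------------------------------------------------------------------------
@dataclass
class ContourMask:
    name: str
    mask: np.ndarray
    spacing: np.ndarray

    @property
    def volume_cc(self) -> float:
        return float(self.mask.sum()) * float(np.prod(self.spacing)) / 1000.0


def make_shell_contours(phantom: VoxelPhantom, thickness_mm: float = 3.0):
    """Bag mask plus the 3-mm outward shell split into four 90-degree
    azimuthal sectors about the bag centroid in the axial (x-y) plane.

    Anterior faces the gantry-0 source (-y), posterior the holder (+y).
    Returns (bag ContourMask, dict of four sector ContourMasks).
    """
    scene = phantom.scene
    if scene is None or scene.name != "breast":
        raise ValueError("shell contours are defined for the breast scene")
    bag_codes = [phantom.material_code(m) for m in ("water", "silicone")]
    bag = np.isin(phantom.labels, bag_codes)
    # restrict to the balloon region (water also fills nothing else here)
    if not bag.any():
        raise ValueError("no bag found in phantom")
    dist = ndimage.distance_transform_edt(~bag, sampling=phantom.spacing)
    shell = (dist > 0) & (dist <= thickness_mm)
    com = np.array(ndimage.center_of_mass(bag))
    xs = np.arange(phantom.shape[0])[:, None, None] - com[0]
    ys = np.arange(phantom.shape[1])[None, :, None] - com[1]
    phi = np.arctan2(xs * phantom.spacing[0], -ys * phantom.spacing[1])  # 0 = anterior (-y)
    phi = np.broadcast_to(phi, phantom.shape)
    sectors = {
        "C_Anterior": np.abs(phi) <= np.pi / 4,
        "C_Left": (phi > np.pi / 4) & (phi <= 3 * np.pi / 4),
        "C_Posterior": np.abs(phi) > 3 * np.pi / 4,
        "C_Right": (phi < -np.pi / 4) & (phi >= -3 * np.pi / 4),
    }
    masks = {name: ContourMask(name, shell & sec, phantom.spacing) for name, sec in sectors.items()}
    bag_mask = ContourMask("bag", bag, phantom.spacing)
    return bag_mask, masks
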