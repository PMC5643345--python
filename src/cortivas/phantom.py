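"""Synthetic cortical-bone phantoms with exactly known morphometry.

The phantom is an annular cortex aligned with the z (rotation) axis that
contains straight, gently tilted tubular canals, thin-walled coaxial vessels
inside a configurable fraction of those canals, and ellipsoidal lacunae
embedded in the mineralised tissue.  Every structure is rasterised from its
analytic solid (a voxel belongs to a structure when its centre lies inside),
so the generator doubles as the ground-truth oracle for the full pipeline.

Coordinates are voxel-centre, 0-based, axis order ``(z, y, x)`` with z the
rotation axis; physical positions are ``index * voxel_size`` in micrometres.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import MappingError, SizingError, UndefinedResultError
from .morphometry import MorphometryIndices

# Label codes (uint8).
BACKGROUND = 0
BONE = 1
CANAL_LUMEN = 2
VESSEL_WALL = 3
VESSEL_LUMEN = 4
LACUNA = 5

LABEL_NAMES = {
    BACKGROUND: "background",
    BONE: "bone",
    CANAL_LUMEN: "canal_lumen",
    VESSEL_WALL: "vessel_wall",
    VESSEL_LUMEN: "vessel_lumen",
    LACUNA: "lacuna",
}

#: Label codes that make up a canal structure (the full pore, vessel included).
CANAL_CODES = (CANAL_LUMEN, VESSEL_WALL, VESSEL_LUMEN)
#: Label codes that make up the vessel (soft tissue) inside a canal.
VESSEL_CODES = (VESSEL_WALL, VESSEL_LUMEN)
#: All pore codes (non-mineralised space inside the cortex).
PORE_CODES = (CANAL_LUMEN, VESSEL_WALL, VESSEL_LUMEN, LACUNA)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic cortex. Lengths in µm, densities per mm³."""

    grid_shape: tuple[int, int, int] = (96, 128, 128)
    voxel_size: float = 1.0
    cortex_outer_radius: float = 58.0
    cortex_inner_radius: float = 26.0
    n_canals: int = 8
    canal_diameter_mean: float = 8.0
    canal_diameter_sd: float = 0.7
    canal_orientation_jitter: float = 2.0  # degrees from the z axis
    occupancy_fraction: float = 0.95
    vessel_fill_fraction: float = 0.85
    vessel_wall_thickness: float = 1.0
    lacunar_density: float = 4.0e4  # per mm³ of mineralised bone
    lacuna_semi_axes: tuple[float, float, float] = (4.5, 2.0, 2.0)
    rng_seed: int = 0

    def validate(self) -> None:
        nz, ny, nx = self.grid_shape
        if min(nz, ny, nx) < 8:
            raise SizingError(f"grid {self.grid_shape} too small")
        if self.voxel_size <= 0:
            raise SizingError("voxel_size must be positive")
        if not self.cortex_inner_radius < self.cortex_outer_radius:
            raise SizingError("cortex_inner_radius must be < cortex_outer_radius")
        half_extent = (min(ny, nx) - 1) / 2.0 * self.voxel_size
        if self.cortex_outer_radius > half_extent:
            raise SizingError(
                f"cortex_outer_radius {self.cortex_outer_radius} µm exceeds the "
                f"grid half-extent {half_extent:.2f} µm"
            )
        if self.n_canals > 0 and self.canal_diameter_mean < 2 * self.voxel_size:
            raise SizingError("canal_diameter_mean must be ≥ 2 voxels to be resolvable")
        if not 0.0 <= self.occupancy_fraction <= 1.0:
            raise SizingError("occupancy_fraction must lie in [0, 1]")
        if not 0.0 < self.vessel_fill_fraction < 1.0:
            raise SizingError("vessel_fill_fraction must lie in (0, 1)")
        if self.lacunar_density < 0:
            raise SizingError("lacunar_density must be ≥ 0")


@dataclass
class CanalRecord:
    """Registry entry for one canal: analytic centreline and true diameter."""

    id: int
    point: tuple[float, float, float]  # a point on the axis, (z, y, x) µm
    direction: tuple[float, float, float]  # unit vector, (z, y, x)
    diameter: float  # µm
    has_vessel: bool


@dataclass
class LabelledPhantom:
    labels: np.ndarray  # uint8, (z, y, x)
    voxel_size: float  # µm
    registry: list[CanalRecord]
    spec: PhantomSpec | None = None

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape


@dataclass(frozen=True)
class MaterialTable:
    """δ/β of each label code at the working energy.

    The default values are plausible magnitudes for dissected, unperfused
    bone at 21 keV (mineralised tissue, soft tissue, air-filled pores); they
    are configuration defaults, not measured constants.
    """

    energy_kev: float = 21.0
    delta: dict[int, float] = field(
        default_factory=lambda: {
            BACKGROUND: 0.0,
            BONE: 1.06e-6,
            CANAL_LUMEN: 0.0,  # air in the dissected specimen
            VESSEL_WALL: 6.0e-7,  # soft tissue
            VESSEL_LUMEN: 5.0e-7,  # residual blood/plasma
            LACUNA: 0.0,
        }
    )
    beta: dict[int, float] = field(
        default_factory=lambda: {
            BACKGROUND: 0.0,
            BONE: 5.0e-9,
            CANAL_LUMEN: 0.0,
            VESSEL_WALL: 3.5e-10,
            VESSEL_LUMEN: 3.0e-10,
            LACUNA: 0.0,
        }
    )

    def validate(self) -> None:
        for table in (self.delta, self.beta):
            for code, value in table.items():
                if value < 0:
                    raise ValueError(f"negative optical constant for label {code}")
        if BONE in self.delta and VESSEL_WALL in self.delta:
            if not self.delta[BONE] > self.delta[VESSEL_WALL] >= 0:
                raise ValueError("bone delta must exceed soft-tissue delta")
        if BONE in self.beta and VESSEL_WALL in self.beta:
            if not self.beta[BONE] > self.beta[VESSEL_WALL] >= 0:
                raise ValueError("bone beta must exceed soft-tissue beta")


@dataclass
class MaterialVolume:
    delta_map: np.ndarray
    beta_map: np.ndarray
    voxel_size: float  # µm
    energy_kev: float


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lower: float, size: int) -> np.ndarray:
    """Normal(mean, sd) truncated at `lower` by rejection."""
    if size == 0:
        return np.empty(0)
    if sd <= 0:
        vals = np.full(size, mean)
        if np.any(vals < lower):
            raise SizingError("canal diameter mean below the 2-voxel floor")
        return vals
    out = np.empty(size)
    filled = 0
    for _ in range(1000):
        draw = rng.normal(mean, sd, size=2 * (size - filled) + 8)
        draw = draw[draw >= lower]
        take = min(draw.size, size - filled)
        out[filled:filled + take] = draw[:take]
        filled += take
        if filled == size:
            return out
    raise SizingError("truncated-normal rejection failed; check diameter bounds")


def _canal_axis(rng: np.random.Generator, jitter_deg: float) -> np.ndarray:
    """Unit direction (z, y, x): tilt from z uniform in [0, jitter]."""
    tilt = math.radians(rng.uniform(0.0, max(jitter_deg, 0.0)))
    azim = rng.uniform(0.0, 2.0 * math.pi)
    return np.array([math.cos(tilt),
                     math.sin(tilt) * math.sin(azim),
                     math.sin(tilt) * math.cos(azim)])


def build_phantom(spec: PhantomSpec) -> LabelledPhantom:
    """Rasterise the annular cortex, canals, vessels and lacunae.

    Deterministic for a fixed ``spec`` (including ``rng_seed``).  Raises
    :class:`SizingError` when the requested structures cannot be placed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    nz, ny, nx = spec.grid_shape
    s = spec.voxel_size
    cy = (ny - 1) / 2.0 * s
    cx = (nx - 1) / 2.0 * s

    yy, xx = np.meshgrid(np.arange(ny) * s - cy, np.arange(nx) * s - cx,
                         indexing="ij")
    r2 = yy * yy + xx * xx
    annulus = (r2 >= spec.cortex_inner_radius ** 2) & (r2 <= spec.cortex_outer_radius ** 2)

    labels = np.zeros(spec.grid_shape, dtype=np.uint8)
    labels[:, annulus] = BONE

    diameters = _truncated_normal(rng, spec.canal_diameter_mean,
                                  spec.canal_diameter_sd, 2.0 * s, spec.n_canals)
    has_vessel = rng.random(spec.n_canals) < spec.occupancy_fraction

    # Place canal axes by rejection so tubes stay inside the bone wall and
    # do not merge with each other (2-voxel clearance).
    zmid = (nz - 1) / 2.0 * s
    length = nz * s
    registry: list[CanalRecord] = []
    placed: list[tuple[float, float, float]] = []  # (y, x, radius+drift)
    for i in range(spec.n_canals):
        radius = diameters[i] / 2.0
        drift = length / 2.0 * math.tan(math.radians(spec.canal_orientation_jitter))
        margin = radius + drift + 2.0 * s
        lo = spec.cortex_inner_radius + margin
        hi = spec.cortex_outer_radius - margin
        if lo >= hi:
            raise SizingError(
                "cortical wall too thin for the requested canal diameter/jitter"
            )
        for attempt in range(2000):
            rho = math.sqrt(rng.uniform(lo ** 2, hi ** 2))
            phi = rng.uniform(0.0, 2.0 * math.pi)
            y0, x0 = rho * math.sin(phi), rho * math.cos(phi)
            clearance = radius + drift + 2.0 * s
            if all((y0 - py) ** 2 + (x0 - px) ** 2 >= (clearance + pr) ** 2
                   for py, px, pr in placed):
                break
        else:
            raise SizingError(f"could not place canal {i} without overlap")
        placed.append((y0, x0, radius + drift))
        axis = _canal_axis(rng, spec.canal_orientation_jitter)
        registry.append(CanalRecord(
            id=i + 1,
            point=(zmid, y0 + cy, x0 + cx),
            direction=tuple(axis),
            diameter=diameters[i],
            has_vessel=bool(has_vessel[i]),
        ))

    zs = np.arange(nz) * s
    for rec in registry:
        _paint_canal(labels, rec, spec, zs, yy, xx, cy, cx, annulus)

    _place_lacunae(labels, spec, rng)

    return LabelledPhantom(labels=labels, voxel_size=s, registry=registry,
                           spec=spec)


def _paint_canal(labels: np.ndarray, rec: CanalRecord, spec: PhantomSpec,
                 zs: np.ndarray, yy: np.ndarray, xx: np.ndarray,
                 cy: float, cx: float, annulus: np.ndarray) -> None:
    """Rasterise one tube (and its vessel) slice by slice.

    With near-longitudinal axes the per-slice cross-section is computed from
    the distance to the 3D line, restricted to a small bounding window.
    """
    s = spec.voxel_size
    pz, py, px = rec.point
    dz, dy, dx = rec.direction
    radius = rec.diameter / 2.0
    rv = spec.vessel_fill_fraction * radius
    wall = max(spec.vessel_wall_thickness, s)  # at least one voxel thick
    r_lumen = max(rv - wall, 0.0)

    ny, nx_ = labels.shape[1], labels.shape[2]
    for iz, z in enumerate(zs):
        # Axis position in this slice (dz > 0 for small jitter).
        t = (z - pz) / dz
        ay = (py - cy) + t * dy
        ax = (px - cx) + t * dx
        # In-plane radius of the tilted circular tube is radius / |dz| to
        # first order; for jitter ≤ a few degrees the correction is < 0.4 %.
        j0 = max(int((ay + cy - radius - 2 * s) / s), 0)
        j1 = min(int((ay + cy + radius + 2 * s) / s) + 1, ny)
        i0 = max(int((ax + cx - radius - 2 * s) / s), 0)
        i1 = min(int((ax + cx + radius + 2 * s) / s) + 1, nx_)
        if j0 >= j1 or i0 >= i1:
            continue
        wy = yy[j0:j1, i0:i1] - ay
        wx = xx[j0:j1, i0:i1] - ax
        d2 = (wy * wy + wx * wx) * (dz * dz)  # distance to 3D line, squared
        window = labels[iz, j0:j1, i0:i1]
        inside = (d2 <= radius ** 2) & annulus[j0:j1, i0:i1]
        window[inside] = CANAL_LUMEN
        if rec.has_vessel:
            window[inside & (d2 <= rv ** 2)] = VESSEL_WALL
            if r_lumen > 0:
                window[inside & (d2 <= r_lumen ** 2)] = VESSEL_LUMEN


def _place_lacunae(labels: np.ndarray, spec: PhantomSpec,
                   rng: np.random.Generator) -> None:
    """Embed ellipsoidal lacunae in bone, disjoint from every other pore."""
    s = spec.voxel_size
    bone_voxels = int(np.count_nonzero(labels == BONE))
    bone_mm3 = bone_voxels * (s ** 3) * 1e-9
    target = int(round(spec.lacunar_density * bone_mm3))
    if target == 0:
        return
    a, b, c = spec.lacuna_semi_axes
    nz, ny, nx = labels.shape
    half = np.array([a, max(a, b, c), max(a, b, c)]) / s + 1  # bbox half-size, voxels

    offsets = None
    placed = 0
    for _ in range(200 * target):
        if placed >= target:
            break
        # Random centre and random rotation of the ellipsoid.
        centre = rng.uniform([half[0] + 1, half[1] + 1, half[2] + 1],
                             [nz - half[0] - 2, ny - half[1] - 2, nx - half[2] - 2])
        ci = np.round(centre).astype(int)
        if labels[ci[0], ci[1], ci[2]] != BONE:
            continue
        rot = _random_rotation(rng)
        h = int(math.ceil(max(a, b, c) / s)) + 1
        z0, y0, x0 = ci - h
        z1, y1, x1 = ci + h + 1
        if z0 < 0 or y0 < 0 or x0 < 0 or z1 > nz or y1 > ny or x1 > nx:
            continue
        box = labels[z0:z1, y0:y1, x0:x1]
        gz, gy, gx = np.meshgrid(
            (np.arange(z0, z1) - centre[0]) * s,
            (np.arange(y0, y1) - centre[1]) * s,
            (np.arange(x0, x1) - centre[2]) * s,
            indexing="ij",
        )
        pts = np.stack([gz, gy, gx], axis=-1) @ rot.T
        inside = ((pts[..., 0] / a) ** 2 + (pts[..., 1] / b) ** 2
                  + (pts[..., 2] / c) ** 2) <= 1.0
        if not inside.any():
            continue
        # Demand bone in the whole box so lacunae never touch other pores.
        if not np.all(box == BONE):
            continue
        box[inside] = LACUNA
        placed += 1


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3D rotation matrix (QR of a Gaussian matrix)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def ground_truth_indices(phantom: LabelledPhantom,
                         dataset_id: str = "ground_truth") -> MorphometryIndices:
    """Morphometric indices by direct voxel counting on the true labels.

    This is the oracle against which the imaging/segmentation pipeline is
    validated: canal volume density over the whole cortical volume, occupancy
    from the registry flags, lacunar density per mm³ of mineralised bone,
    mean canal diameter from the registry's analytic diameters, and vascular
    space as the voxel-count ratio of vessel to canal space.
    """
    labels = phantom.labels
    s = phantom.voxel_size
    bone = int(np.count_nonzero(labels == BONE))
    if bone == 0:
        raise UndefinedResultError("phantom has no bone voxels")
    lacuna_mask = labels == LACUNA
    canal = int(np.count_nonzero(np.isin(labels, CANAL_CODES)))
    vessel = int(np.count_nonzero(np.isin(labels, VESSEL_CODES)))
    cortical = bone + canal + int(np.count_nonzero(lacuna_mask))

    import scipy.ndimage as ndi

    n_lacunae = int(ndi.label(lacuna_mask, structure=np.ones((3, 3, 3)))[1])
    bone_mm3 = bone * (s ** 3) * 1e-9

    n = len(phantom.registry)
    occupancy = (100.0 * sum(r.has_vessel for r in phantom.registry) / n
                 if n else float("nan"))
    diameter = (float(np.mean([r.diameter for r in phantom.registry]))
                if n else float("nan"))
    vascular = 100.0 * vessel / canal if canal else float("nan")

    return MorphometryIndices(
        canal_volume_pct=100.0 * canal / cortical,
        canal_diameter_um=diameter,
        lacunar_density_per_mm3=n_lacunae / bone_mm3,
        canal_occupancy_pct=occupancy,
        vascular_space_pct=vascular,
        n_slices_sampled=labels.shape[0],
        dataset_id=dataset_id,
    )


def labels_to_materials(phantom: LabelledPhantom,
                        table: MaterialTable | None = None) -> MaterialVolume:
    """Pure per-voxel lookup of (δ, β) from the label volume."""
    table = table or MaterialTable()
    table.validate()
    codes = np.unique(phantom.labels)
    missing = [int(c) for c in codes if int(c) not in table.delta
               or int(c) not in table.beta]
    if missing:
        raise MappingError(f"material table missing label codes {missing}")
    lut_d = np.zeros(int(codes.max()) + 1, dtype=np.float32)
    lut_b = np.zeros(int(codes.max()) + 1, dtype=np.float32)
    for c in codes:
        lut_d[c] = table.delta[int(c)]
        lut_b[c] = table.beta[int(c)]
    return MaterialVolume(
        delta_map=lut_d[phantom.labels],
        beta_map=lut_b[phantom.labels],
        voxel_size=phantom.voxel_size,
        energy_kev=table.energy_kev,
    )


# ---------------------------------------------------------------------------
# Serialisation

def save_phantom(phantom: LabelledPhantom, out_dir: str | Path) -> None:
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / "labels.tif", phantom.labels,
                     photometric="minisblack")
    sidecar = {
        "voxel_size_um": phantom.voxel_size,
        "label_names": {str(k): v for k, v in LABEL_NAMES.items()},
        "spec": dataclasses.asdict(phantom.spec) if phantom.spec else None,
        "registry": [dataclasses.asdict(r) for r in phantom.registry],
    }
    (out / "phantom.json").write_text(json.dumps(sidecar, indent=2))


def load_phantom(in_dir: str | Path) -> LabelledPhantom:
    import tifffile

    src = Path(in_dir)
    labels = tifffile.imread(src / "labels.tif")
    meta = json.loads((src / "phantom.json").read_text())
    registry = [CanalRecord(
        id=r["id"], point=tuple(r["point"]), direction=tuple(r["direction"]),
        diameter=r["diameter"], has_vessel=r["has_vessel"],
    ) for r in meta["registry"]]
    spec = None
    if meta.get("spec"):
        d = dict(meta["spec"])
        d["grid_shape"] = tuple(d["grid_shape"])
        d["lacuna_semi_axes"] = tuple(d["lacuna_semi_axes"])
        spec = PhantomSpec(**d)
    return LabelledPhantom(labels=labels, voxel_size=meta["voxel_size_um"],
                           registry=registry, spec=spec)
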