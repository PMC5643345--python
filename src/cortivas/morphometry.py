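"""Quantitative indices of the cortical canal network and lacunae.

Five indices are computed from a pore classification, a bone mask and a
vessel mask: canal volume density, mean canal diameter (model-independent
local thickness), osteocyte lacunar density, canal occupancy and vascular
space.  Occupancy and vascular space are evaluated on a fixed number of
evenly spaced cross-sectional slices (default 60), mirroring slice-wise
visual inspection; the other three use the full volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import ndimage as ndi

from .errors import UndefinedResultError


@dataclass
class MorphometryIndices:
    canal_volume_pct: float
    canal_diameter_um: float
    lacunar_density_per_mm3: float
    canal_occupancy_pct: float
    vascular_space_pct: float
    n_slices_sampled: int
    dataset_id: str = ""

    FIELDS = (
        "canal_volume_pct",
        "canal_diameter_um",
        "lacunar_density_per_mm3",
        "canal_occupancy_pct",
        "vascular_space_pct",
    )

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in self.FIELDS}


def canal_volume_density(classification, bone) -> float:
    """Canal voxels (vessel included) as % of the total cortical volume.

    The cortical volume is mineralised bone plus all pore space.
    """
    canal = classification.class_mask("canal")
    n_canal = int(np.count_nonzero(canal))
    n_pores = int(np.count_nonzero(classification.component_labels))
    n_cortex = int(np.count_nonzero(bone.mask)) + n_pores
    if n_cortex == 0:
        raise UndefinedResultError("zero cortical volume")
    return 100.0 * n_canal / n_cortex


def mean_canal_diameter(classification) -> float:
    """Mean local thickness over canal voxels, in µm."""
    canal = classification.class_mask("canal")
    if not canal.any():
        raise UndefinedResultError("no canal components")
    lt = local_thickness(canal, classification.voxel_size)
    return float(lt[canal].mean())


def lacunar_density(classification, bone) -> float:
    """Lacuna component count per mm³ of mineralised bone."""
    n_bone = int(np.count_nonzero(bone.mask))
    if n_bone == 0:
        raise UndefinedResultError("zero bone volume")
    n_lac = sum(1 for r in classification.components if r.klass == "lacuna")
    bone_mm3 = n_bone * (bone.voxel_size ** 3) * 1e-9
    return n_lac / bone_mm3


def _sample_slices(canal: np.ndarray, n_slices: int) -> np.ndarray:
    """Evenly spaced slice indices spanning the canal-bearing z range."""
    zs = np.flatnonzero(canal.reshape(canal.shape[0], -1).any(axis=1))
    if zs.size == 0:
        raise UndefinedResultError("no canal cross-sections present")
    return np.unique(np.round(np.linspace(zs[0], zs[-1], n_slices)).astype(int))


def canal_occupancy(classification, vessels, n_slices: int = 60) -> float:
    """% of canal cross-sections containing at least one vessel voxel.

    Each (canal component, sampled slice) pair counts as one cross-section.
    """
    if n_slices < 1:
        raise ValueError("n_slices must be ≥ 1")
    labels = classification.component_labels
    canal = classification.class_mask("canal")
    occupied = 0
    total = 0
    for z in _sample_slices(canal, n_slices):
        sl = labels[z] * canal[z]
        vz = vessels.mask[z]
        for cid in np.unique(sl):
            if cid == 0:
                continue
            total += 1
            if np.any(vz & (sl == cid)):
                occupied += 1
    if total == 0:
        raise UndefinedResultError("no canal cross-sections in sampled slices")
    return 100.0 * occupied / total


def vascular_space(classification, vessels, n_slices: int = 60) -> float:
    """Vessel area as % of canal area over the sampled slices."""
    if n_slices < 1:
        raise ValueError("n_slices must be ≥ 1")
    canal = classification.class_mask("canal")
    zs = _sample_slices(canal, n_slices)
    n_canal = int(np.count_nonzero(canal[zs]))
    if n_canal == 0:
        raise UndefinedResultError("zero canal area in sampled slices")
    n_vessel = int(np.count_nonzero(vessels.mask[zs] & canal[zs]))
    return 100.0 * n_vessel / n_canal


def compute_indices(classification, bone, vessels, n_slices: int = 60,
                    dataset_id: str = "") -> MorphometryIndices:
    """All five indices in one record."""
    return MorphometryIndices(
        canal_volume_pct=canal_volume_density(classification, bone),
        canal_diameter_um=mean_canal_diameter(classification),
        lacunar_density_per_mm3=lacunar_density(classification, bone),
        canal_occupancy_pct=canal_occupancy(classification, vessels, n_slices),
        vascular_space_pct=vascular_space(classification, vessels, n_slices),
        n_slices_sampled=n_slices,
        dataset_id=dataset_id,
    )


# ---------------------------------------------------------------------------
# Local thickness

def local_thickness(mask: np.ndarray, voxel_size: float = 1.0) -> np.ndarray:
    """Diameter of the largest inscribed sphere covering each object voxel.

    Computed as 2·max{r(y) : |x−y| ≤ r(y)} with r the Euclidean distance
    transform, by painting spheres in order of decreasing radius.  Returns a
    float volume in µm (0 outside the mask).
    """
    mask = np.ascontiguousarray(mask, dtype=bool)
    out = np.zeros(mask.shape, dtype=np.float64)
    if not mask.any():
        return out
    radii = ndi.distance_transform_edt(mask, sampling=voxel_size)
    zz, yy, xx = np.nonzero(mask)
    order = np.argsort(radii[zz, yy, xx])[::-1]
    _paint_spheres(out, radii,
                   zz[order].astype(np.int64), yy[order].astype(np.int64),
                   xx[order].astype(np.int64), float(voxel_size))
    return out


@njit(cache=True)
def _paint_spheres(out, radii, zz, yy, xx, s):
    nz, ny, nx = out.shape
    for k in range(zz.size):
        z, y, x = zz[k], yy[k], xx[k]
        r = radii[z, y, x]
        d = 2.0 * r
        rv = int(r / s)  # sphere radius in voxels
        r2 = (r / s) * (r / s)
        for dz in range(-rv, rv + 1):
            pz = z + dz
            if pz < 0 or pz >= nz:
                continue
            for dy in range(-rv, rv + 1):
                py = y + dy
                if py < 0 or py >= ny:
                    continue
                for dx in range(-rv, rv + 1):
                    px = x + dx
                    if px < 0 or px >= nx:
                        continue
                    if dz * dz + dy * dy + dx * dx <= r2 and d > out[pz, py, px]:
                        out[pz, py, px] = d
    return out
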