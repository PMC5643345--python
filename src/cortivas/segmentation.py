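"""Bone segmentation, pore extraction/classification and vessel detection.

The mineralised tissue is thresholded automatically (Otsu) on the
near-absorption reconstruction; the pore space is its negative imprint
inside the morphologically closed cortex; connected pores are classified
into tubular canals and small lacunae by volume and elongation; the soft
tissue comprising the vessel inside each canal is detected from the
interference-fringe amplitude on the phase-sensitive reconstruction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from .errors import DegenerateInputError
from .pci_sim import ReconVolume

log = logging.getLogger(__name__)

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class BoneMask:
    mask: np.ndarray  # bool, (z, y, x)
    voxel_size: float  # µm
    threshold_used: float


@dataclass
class PoreComponent:
    id: int
    n_voxels: int
    volume_um3: float
    klass: str  # "canal" | "lacuna"
    elongation: float
    equivalent_size_um: float  # equivalent-sphere diameter


@dataclass
class PoreClassification:
    component_labels: np.ndarray  # int32, 0 = not a pore
    components: list[PoreComponent]
    voxel_size: float
    volume_cutoff_um3: float
    elongation_cutoff: float
    _masks: dict = field(default_factory=dict, repr=False)

    def class_mask(self, klass: str) -> np.ndarray:
        """Boolean volume of all components of one class (cached)."""
        if klass not in self._masks:
            ids = [c.id for c in self.components if c.klass == klass]
            self._masks[klass] = np.isin(self.component_labels, ids)
        return self._masks[klass]


@dataclass
class VesselMask:
    mask: np.ndarray  # bool, vessel soft tissue inside canal lumina
    k_sigma: float
    min_extent_px: int
    #: (canal component id, slice index) -> vessel found in that cross-section
    occupancy_flags: dict = field(default_factory=dict)


@dataclass
class LineProfile:
    values: np.ndarray
    step_um: float
    points_um: tuple


# ---------------------------------------------------------------------------

def segment_bone(recon: ReconVolume, smooth_sigma_um: float = 0.0) -> BoneMask:
    """Otsu threshold, then keep the largest connected component as cortex.

    ``smooth_sigma_um`` applies an isotropic Gaussian before thresholding;
    it suppresses reconstruction noise at the price of sub-voxel boundary
    blur (leave at 0 for noiseless input).
    """
    values = recon.values
    if smooth_sigma_um > 0:
        values = ndi.gaussian_filter(values, smooth_sigma_um / recon.voxel_size)
    if not np.all(np.isfinite(values)):
        raise DegenerateInputError("reconstruction contains non-finite values")
    vmin, vmax = float(values.min()), float(values.max())
    if vmax - vmin < 1e-12:
        raise DegenerateInputError("constant volume: no bone/background contrast")
    thr = float(threshold_otsu(values))
    mask = values > thr
    if not mask.any() or mask.all():
        raise DegenerateInputError("threshold produced an empty class")
    labels, n = ndi.label(mask, structure=_CONN26)
    if n > 1:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        mask = labels == int(counts.argmax())
    return BoneMask(mask=mask, voxel_size=recon.voxel_size, threshold_used=thr)


def _ball_closing(mask: np.ndarray, radius_um: float,
                  voxel_size: float) -> np.ndarray:
    """Morphological closing with a Euclidean ball, via distance transforms."""
    if radius_um <= 0:
        return mask.copy()
    dilated = ndi.distance_transform_edt(~mask, sampling=voxel_size) <= radius_um
    closed = ndi.distance_transform_edt(dilated, sampling=voxel_size) > radius_um
    return closed


def extract_pores(bone: BoneMask, closing_radius_um: float,
                  return_details: bool = False):
    """Pore space as the negative imprint of bone inside the closed cortex.

    Closing the bone mask with a ball of ``closing_radius_um`` defines the
    solid cortex; pores are closed-cortex voxels that are not bone.  Pore
    components still touching the non-cortical space after closing (leaks)
    are discarded and their count logged.
    """
    if not bone.mask.any():
        raise DegenerateInputError("empty bone mask")
    closed = _ball_closing(bone.mask, closing_radius_um, bone.voxel_size)
    pores = closed & ~bone.mask
    n_discarded = 0
    if pores.any():
        outside = ~closed
        touching = ndi.binary_dilation(outside, structure=_CONN26) & pores
        if touching.any():
            labels, _ = ndi.label(pores, structure=_CONN26)
            bad = np.unique(labels[touching])
            bad = bad[bad > 0]
            n_discarded = int(bad.size)
            pores &= ~np.isin(labels, bad)
            log.info("extract_pores: discarded %d surface-touching pores",
                     n_discarded)
    if return_details:
        return pores, n_discarded
    return pores


def classify_pores(pores: np.ndarray, voxel_size: float,
                   volume_cutoff_um3: float = 2000.0,
                   elongation_cutoff: float = 5.0) -> PoreClassification:
    """Label 26-connected pores; canals are large or elongated components.

    Elongation is the ratio of the largest to smallest principal-axis
    standard deviation of the voxel-centre cloud, regularised by the voxel
    extent so single voxels score 1.
    """
    labels, n = ndi.label(pores, structure=_CONN26)
    labels = labels.astype(np.int32)
    comps: list[PoreComponent] = []
    if n:
        slices = ndi.find_objects(labels)
        for cid, sl in enumerate(slices, start=1):
            if sl is None:
                continue
            sub = labels[sl] == cid
            n_vox = int(sub.sum())
            vol = n_vox * voxel_size ** 3
            elong = _elongation(sub, voxel_size)
            klass = ("canal" if vol > volume_cutoff_um3
                     or elong > elongation_cutoff else "lacuna")
            eq_d = 2.0 * (3.0 * vol / (4.0 * np.pi)) ** (1.0 / 3.0)
            comps.append(PoreComponent(id=cid, n_voxels=n_vox, volume_um3=vol,
                                       klass=klass, elongation=float(elong),
                                       equivalent_size_um=float(eq_d)))
    return PoreClassification(component_labels=labels, components=comps,
                              voxel_size=voxel_size,
                              volume_cutoff_um3=volume_cutoff_um3,
                              elongation_cutoff=elongation_cutoff)


def _elongation(sub_mask: np.ndarray, voxel_size: float) -> float:
    coords = np.argwhere(sub_mask).astype(np.float64) * voxel_size
    centred = coords - coords.mean(axis=0)
    cov = centred.T @ centred / len(coords)
    # A voxel is not a point: add its own second moment (s²/12 per axis).
    cov += np.eye(3) * (voxel_size ** 2 / 12.0)
    eig = np.linalg.eigvalsh(cov)
    return float(np.sqrt(eig[-1] / eig[0]))


# ---------------------------------------------------------------------------
# Vessel detection

def detect_vessels(recon_phase: ReconVolume,
                   classification: PoreClassification,
                   k_sigma: float = 4.5,
                   bone: BoneMask | None = None,
                   min_extent_px: int = 3,
                   contrast_factor: float = 2.0,
                   flag_smooth_slices: int = 5,
                   hull_slices: int = 1,
                   min_distance_mm: float = 1.0) -> VesselMask:
    """Detect the vessel inside each canal from its fringe amplitude.

    Within every canal cross-section (slice-wise) the voxels whose absolute
    deviation from the lumen median exceeds a detection threshold are
    grouped 8-connected; groups of at least ``min_extent_px`` pixels mark
    the cross-section as occupied.  The threshold is the larger of

    * ``k_sigma`` × the background noise SD (robust MAD over eroded bone),
      which controls false detections from reconstruction noise, and
    * ``contrast_factor`` × |bone median − lumen median|, a contrast floor:
      partial-volume deviations at the canal wall are bounded by the
      bone/pore contrast itself, whereas true interference fringes overshoot
      it many-fold.  The floor also exploits that an air-filled (empty)
      lumen sits much deeper below the bone level than one holding soft
      tissue.

    Because a vessel is continuous along the canal, per-slice occupancy
    flags are median-smoothed over ``flag_smooth_slices`` neighbouring
    cross-sections, and the vessel area in a flagged cross-section is the
    convex hull of the fringe arcs pooled over ±``hull_slices`` slices,
    clipped to the lumen.
    """
    beam = recon_phase.provenance
    if beam is not None and beam.propagation_distance_mm < min_distance_mm:
        warnings.warn(
            f"reconstruction acquired at D = {beam.propagation_distance_mm} mm; "
            "vessel fringes need a phase-sensitive propagation distance",
            stacklevel=2)
    values = recon_phase.values
    labels = classification.component_labels
    canal_ids = sorted(c.id for c in classification.components
                       if c.klass == "canal")
    out = np.zeros(values.shape, dtype=bool)
    flags: dict[tuple[int, int], bool] = {}
    if not canal_ids:
        return VesselMask(mask=out, k_sigma=k_sigma,
                          min_extent_px=min_extent_px, occupancy_flags=flags)

    if bone is None:
        bone = segment_bone(recon_phase)
    bone_interior = ndi.binary_erosion(bone.mask, structure=_CONN26)
    if not bone_interior.any():
        bone_interior = bone.mask

    canal_id_arr = np.asarray(canal_ids, dtype=np.int64)
    struct8 = np.ones((3, 3), dtype=bool)
    # Pass 1: per-slice fringe groups per canal.
    kept_masks: dict[tuple[int, int], np.ndarray | None] = {}
    for z in range(values.shape[0]):
        sl_labels = labels[z]
        present = np.intersect1d(np.unique(sl_labels), canal_id_arr)
        if present.size == 0:
            continue
        background = values[z][bone_interior[z]]
        sigma = _noise_sd(background)
        bone_med = float(np.median(background)) if background.size else 0.0
        for cid in present:
            lumen = sl_labels == cid
            lumen_med = float(np.median(values[z][lumen]))
            threshold = max(k_sigma * sigma,
                            contrast_factor * abs(bone_med - lumen_med))
            cand = lumen & (np.abs(values[z] - lumen_med) > threshold)
            kept = None
            if cand.any():
                grp, _ = ndi.label(cand, structure=struct8)
                sizes = np.bincount(grp.ravel())
                sizes[0] = 0
                keep_ids = np.flatnonzero(sizes >= min_extent_px)
                if keep_ids.size:
                    kept = np.isin(grp, keep_ids)
            kept_masks[(int(cid), z)] = kept

    # Pass 2: longitudinal consistency and area estimation.
    from skimage.morphology import convex_hull_image

    for cid in canal_ids:
        zs = sorted(z for c, z in kept_masks if c == cid)
        if not zs:
            continue
        detected = np.array([kept_masks[(cid, z)] is not None for z in zs])
        if flag_smooth_slices > 1 and detected.size > 1:
            # Zero padding: an end slice is flagged only when its first
            # few neighbours agree (guards against boundary artifacts).
            smoothed = ndi.median_filter(detected.astype(np.int8),
                                         size=flag_smooth_slices,
                                         mode="constant", cval=0) > 0
        else:
            smoothed = detected
        for i, z in enumerate(zs):
            flags[(cid, z)] = bool(smoothed[i])
            if not smoothed[i]:
                continue
            pooled = None
            for j in range(max(0, i - hull_slices),
                           min(len(zs), i + hull_slices + 1)):
                m = kept_masks[(cid, zs[j])]
                if m is not None:
                    pooled = m if pooled is None else (pooled | m)
            if pooled is not None:
                lumen = labels[z] == cid
                out[z] |= convex_hull_image(pooled) & lumen
    return VesselMask(mask=out, k_sigma=k_sigma, min_extent_px=min_extent_px,
                      occupancy_flags=flags)


def canal_occupancy_flags(classification: PoreClassification,
                          vessels: VesselMask) -> dict[int, bool]:
    """Per-canal (3D component) occupancy: majority over its cross-sections."""
    votes: dict[int, list[bool]] = {}
    for (cid, _z), flag in vessels.occupancy_flags.items():
        votes.setdefault(cid, []).append(flag)
    return {cid: sum(v) > len(v) / 2 for cid, v in votes.items()}


def _noise_sd(samples: np.ndarray) -> float:
    """Robust SD via the median absolute deviation (×1.4826)."""
    if samples.size < 16:
        return 0.0
    med = np.median(samples)
    return 1.4826 * float(np.median(np.abs(samples - med)))


# ---------------------------------------------------------------------------

def line_profile(image: np.ndarray, p0_um: tuple[float, float],
                 p1_um: tuple[float, float], voxel_size: float,
                 step_um: float | None = None) -> LineProfile:
    """Intensity profile sampled along a segment (linear interpolation).

    Points are (row, col) positions in µm within one slice; the default
    sampling step is one detector pixel.
    """
    step = step_um if step_um is not None else voxel_size
    p0 = np.asarray(p0_um, dtype=float) / voxel_size
    p1 = np.asarray(p1_um, dtype=float) / voxel_size
    for p in (p0, p1):
        if (p < 0).any() or p[0] > image.shape[0] - 1 or p[1] > image.shape[1] - 1:
            raise ValueError(f"profile point {p * voxel_size} µm outside slice")
    length = float(np.hypot(*(p1 - p0))) * voxel_size
    n = max(int(round(length / step)) + 1, 1)
    ts = np.linspace(0.0, 1.0, n)
    coords = p0[:, None] + (p1 - p0)[:, None] * ts[None, :]
    vals = ndi.map_coordinates(image.astype(np.float64), coords, order=1)
    return LineProfile(values=vals, step_um=length / (n - 1) if n > 1 else 0.0,
                       points_um=(tuple(p0_um), tuple(p1_um)))
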