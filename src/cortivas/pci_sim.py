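"""Parallel-beam propagation-based phase contrast CT simulation.

A coherent, monochromatic parallel beam traverses a (δ, β) volume; for each
projection angle the complex transmission is obtained from phase and
absorption line integrals, propagated to the detector with the
angular-spectrum (Fresnel) transfer function, and optionally degraded with
Poisson noise.  Reconstruction is slice-wise filtered backprojection of the
log-normalised intensities.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numba import njit
from skimage.transform import iradon

from .errors import GeometryError
from .phantom import MaterialVolume

log = logging.getLogger(__name__)

HC_KEV_NM = 1.23984193  # h·c in keV·nm


def wavelength_nm(energy_kev: float) -> float:
    """Photon wavelength in nm from energy in keV."""
    if energy_kev <= 0:
        raise GeometryError("energy must be positive")
    return HC_KEV_NM / energy_kev


@dataclass(frozen=True)
class BeamConfig:
    energy_kev: float = 21.0
    propagation_distance_mm: float = 25.0
    n_projections: int = 181
    detector_pixel_um: float = 1.0
    photons_per_pixel: float | None = None  # None/inf → noiseless
    rng_seed: int = 0
    interpolation_order: int = 1  # 0 (nearest) or 1 (bilinear) line integrals
    filter_window: str | None = None  # None → pure ramp; "hann" optional
    log_floor: float = 1e-9

    @property
    def wavelength_nm(self) -> float:
        return wavelength_nm(self.energy_kev)

    @property
    def noiseless(self) -> bool:
        return self.photons_per_pixel is None or not math.isfinite(
            self.photons_per_pixel)

    def validate(self) -> None:
        if self.propagation_distance_mm < 0:
            raise GeometryError("propagation distance must be ≥ 0")
        if self.n_projections < 1:
            raise GeometryError("need at least one projection")
        if self.detector_pixel_um <= 0:
            raise GeometryError("detector pixel must be positive")

    def angles(self) -> np.ndarray:
        """Projection angles in radians, evenly spread over [0, π)."""
        return np.linspace(0.0, np.pi, self.n_projections, endpoint=False)


@dataclass
class Sinogram:
    intensities: np.ndarray  # (angle, detector row, detector column)
    angles: np.ndarray  # radians
    geometry: BeamConfig


@dataclass
class ReconVolume:
    values: np.ndarray  # (z, y, x), effective attenuation (arbitrary units)
    voxel_size: float  # µm
    provenance: BeamConfig


# ---------------------------------------------------------------------------
# Line integrals (rotate-and-sum, fused in one pass over the volume)

@njit(cache=True, fastmath=True)
def _rotsum_pair(vol_a, vol_b, cos_t, sin_t, order):  # pragma: no cover - numba
    nz, ny, nx = vol_a.shape
    out_a = np.zeros((nz, nx), dtype=np.float64)
    out_b = np.zeros((nz, nx), dtype=np.float64)
    # Rotation centre matches skimage.transform.radon/iradon (n // 2).
    cy = float(ny // 2)
    cx = float(nx // 2)
    for iy in range(ny):
        for ix in range(nx):
            yr = cos_t * (iy - cy) - sin_t * (ix - cx) + cy
            xr = sin_t * (iy - cy) + cos_t * (ix - cx) + cx
            if order == 0:
                yy = int(round(yr))
                xx = int(round(xr))
                if yy < 0 or yy >= ny or xx < 0 or xx >= nx:
                    continue
                for iz in range(nz):
                    out_a[iz, ix] += vol_a[iz, yy, xx]
                    out_b[iz, ix] += vol_b[iz, yy, xx]
            else:
                y0 = int(np.floor(yr))
                x0 = int(np.floor(xr))
                if y0 < -1 or y0 > ny - 1 or x0 < -1 or x0 > nx - 1:
                    continue
                wy = yr - y0
                wx = xr - x0
                for dy in range(2):
                    yy = y0 + dy
                    if yy < 0 or yy >= ny:
                        continue
                    wyv = wy if dy == 1 else 1.0 - wy
                    for dx in range(2):
                        xx = x0 + dx
                        if xx < 0 or xx >= nx:
                            continue
                        w = wyv * (wx if dx == 1 else 1.0 - wx)
                        if w == 0.0:
                            continue
                        for iz in range(nz):
                            out_a[iz, ix] += w * vol_a[iz, yy, xx]
                            out_b[iz, ix] += w * vol_b[iz, yy, xx]
    return out_a, out_b


def line_integral_pair(vol_a: np.ndarray, vol_b: np.ndarray, angle: float,
                       order: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Sum both volumes along rays at `angle` (radians); unit path length.

    Multiply by the voxel size to obtain physical line integrals.  The angle
    convention matches ``skimage.transform.radon`` so reconstructions can use
    ``iradon`` directly.
    """
    a = np.ascontiguousarray(vol_a, dtype=np.float32)
    b = np.ascontiguousarray(vol_b, dtype=np.float32)
    return _rotsum_pair(a, b, math.cos(angle), math.sin(angle), order)


def project_complex(materials: MaterialVolume, beam: BeamConfig,
                    angles: np.ndarray | None = None) -> np.ndarray:
    """Complex transmission T = exp(−µ/2 + iφ) per angle.

    φ = −(2π/λ)∫δ ds and µ = (4π/λ)∫β ds along parallel rays; the output has
    shape (n_angles, nz, nx).
    """
    beam.validate()
    if not math.isclose(materials.voxel_size, beam.detector_pixel_um,
                        rel_tol=1e-9):
        raise GeometryError(
            f"voxel size {materials.voxel_size} µm != detector pixel "
            f"{beam.detector_pixel_um} µm")
    if angles is None:
        angles = beam.angles()
    lam_um = beam.wavelength_nm * 1e-3
    ds = materials.voxel_size
    nz, _, nx = materials.delta_map.shape
    out = np.empty((len(angles), nz, nx), dtype=np.complex128)
    for k, theta in enumerate(angles):
        d_sum, b_sum = line_integral_pair(materials.delta_map,
                                          materials.beta_map, theta,
                                          beam.interpolation_order)
        phi = -(2.0 * np.pi / lam_um) * d_sum * ds
        mu = (4.0 * np.pi / lam_um) * b_sum * ds
        out[k] = np.exp(-0.5 * mu + 1j * phi)
    return out


# ---------------------------------------------------------------------------
# Free-space propagation

def fresnel_propagate(transmission: np.ndarray, distance_mm: float,
                      wavelength_nm: float, pixel_um: float) -> np.ndarray:
    """Propagate a complex field and return the detector intensity |E|².

    Uses the Fresnel transfer function H(f) = exp(−iπλD|f|²) in frequency
    space; D = 0 returns |T|² exactly.
    """
    if distance_mm < 0:
        raise GeometryError("propagation distance must be ≥ 0")
    if distance_mm == 0:
        return np.abs(transmission) ** 2
    lam_um = wavelength_nm * 1e-3
    d_um = distance_mm * 1e3
    n = max(transmission.shape[-2:])
    if lam_um * d_um > n * pixel_um ** 2:
        warnings.warn(
            "Fresnel kernel under-sampled: λD = "
            f"{lam_um * d_um:.3g} µm² exceeds N·pixel² = "
            f"{n * pixel_um ** 2:.3g} µm²; expect aliasing",
            stacklevel=2)
    fr = np.fft.fftfreq(transmission.shape[-2], d=pixel_um)
    fc = np.fft.fftfreq(transmission.shape[-1], d=pixel_um)
    f2 = fr[:, None] ** 2 + fc[None, :] ** 2
    kernel = np.exp(-1j * np.pi * lam_um * d_um * f2)
    field = np.fft.ifft2(np.fft.fft2(transmission) * kernel)
    return np.abs(field) ** 2


# ---------------------------------------------------------------------------
# Acquisition

def acquire(materials: MaterialVolume, beam: BeamConfig) -> Sinogram:
    """Full simulated scan at one propagation distance."""
    return acquire_multi(materials, [beam])[0]


def acquire_multi(materials: MaterialVolume,
                  beams: list[BeamConfig]) -> list[Sinogram]:
    """Scans at several distances sharing one set of line integrals.

    All beams must agree on energy, angle count and pixel size; they may
    differ in propagation distance, noise level and seed.
    """
    if not beams:
        return []
    ref = beams[0]
    for b in beams[1:]:
        if (b.energy_kev != ref.energy_kev
                or b.n_projections != ref.n_projections
                or b.detector_pixel_um != ref.detector_pixel_um):
            raise GeometryError("beams in one acquisition must share "
                                "energy, projections and pixel size")
    angles = ref.angles()
    transmission = project_complex(materials, ref, angles)
    out = []
    for beam in beams:
        intens = np.empty(transmission.shape, dtype=np.float64)
        for k in range(transmission.shape[0]):
            intens[k] = fresnel_propagate(transmission[k],
                                          beam.propagation_distance_mm,
                                          beam.wavelength_nm,
                                          beam.detector_pixel_um)
        if not beam.noiseless:
            rng = np.random.default_rng(beam.rng_seed)
            n0 = float(beam.photons_per_pixel)
            intens = rng.poisson(np.clip(intens, 0, None) * n0) / n0
        out.append(Sinogram(intensities=intens, angles=angles, geometry=beam))
    return out


# ---------------------------------------------------------------------------
# Ring correction

def ring_correct(sino: Sinogram, smooth_size: int = 5,
                 gain_threshold: float = 0.02) -> Sinogram:
    """Normalise defective detector pixels toward the smooth column profile.

    The per-pixel mean over angles is compared with its median-smoothed
    (along detector columns) version; pixels whose gain deviates by more
    than `gain_threshold` are divided by that gain.  Clean sinograms pass
    through untouched.
    """
    from scipy.ndimage import median_filter

    if sino.intensities.shape[0] < 8:
        raise GeometryError("ring correction needs at least 8 angles")
    intens = sino.intensities
    mean_map = intens.mean(axis=0)  # (row, col)
    smooth = median_filter(mean_map, size=(1, smooth_size), mode="nearest")
    with np.errstate(divide="ignore", invalid="ignore"):
        gain = np.where(np.abs(smooth) > 1e-12, mean_map / smooth, 1.0)
    defective = np.abs(gain - 1.0) > gain_threshold
    if not defective.any():
        return Sinogram(intensities=intens.copy(), angles=sino.angles.copy(),
                        geometry=sino.geometry)
    corrected = intens.copy()
    corrected[:, defective] /= gain[defective]
    log.info("ring_correct: corrected %d detector pixels",
             int(defective.sum()))
    return Sinogram(intensities=corrected, angles=sino.angles.copy(),
                    geometry=sino.geometry)


# ---------------------------------------------------------------------------
# Reconstruction

def reconstruct_fbp(sino: Sinogram) -> ReconVolume:
    """Slice-wise filtered backprojection of −log(intensity).

    Intensities are assumed flat-field normalised; values are clipped at the
    configured floor before the log.  The ramp filter is pure by default
    (`filter_window` selects an apodisation).
    """
    n_angles = sino.intensities.shape[0]
    if n_angles < 2:
        raise GeometryError("FBP needs at least 2 angles")
    span = float(sino.angles.max() - sino.angles.min())
    if span < np.pi * (1 - 2.0 / n_angles) - 1e-9:
        raise GeometryError("angles must span 180°")
    beam = sino.geometry
    floor = beam.log_floor
    proj = -np.log(np.clip(sino.intensities, floor, None))
    theta_deg = np.degrees(sino.angles)
    filter_name = beam.filter_window or "ramp"
    nz = proj.shape[1]
    nx = proj.shape[2]
    values = np.empty((nz, nx, nx), dtype=np.float32)
    for z in range(nz):
        values[z] = iradon(proj[:, z, :].T, theta=theta_deg,
                           filter_name=filter_name, circle=True,
                           output_size=nx)
    return ReconVolume(values=values, voxel_size=beam.detector_pixel_um,
                       provenance=beam)


# ---------------------------------------------------------------------------
# Serialisation

def _beam_to_dict(beam: BeamConfig) -> dict:
    return dataclasses.asdict(beam)


def save_sinogram(sino: Sinogram, out_dir: str | Path) -> None:
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / "sinogram.tif",
                     sino.intensities.astype(np.float32),
                     photometric="minisblack")
    meta = {"angles_rad": sino.angles.tolist(),
            "beam": _beam_to_dict(sino.geometry)}
    (out / "sinogram.json").write_text(json.dumps(meta, indent=2))


def load_sinogram(in_dir: str | Path) -> Sinogram:
    import tifffile

    src = Path(in_dir)
    intens = tifffile.imread(src / "sinogram.tif")
    meta = json.loads((src / "sinogram.json").read_text())
    return Sinogram(intensities=np.asarray(intens, dtype=np.float64),
                    angles=np.asarray(meta["angles_rad"]),
                    geometry=BeamConfig(**meta["beam"]))


def save_recon(recon: ReconVolume, out_dir: str | Path) -> None:
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / "recon.tif", recon.values.astype(np.float32),
                     photometric="minisblack")
    meta = {"voxel_size_um": recon.voxel_size,
            "beam": _beam_to_dict(recon.provenance)}
    (out / "recon.json").write_text(json.dumps(meta, indent=2))


def load_recon(in_dir: str | Path) -> ReconVolume:
    import tifffile

    src = Path(in_dir)
    values = tifffile.imread(src / "recon.tif")
    meta = json.loads((src / "recon.json").read_text())
    return ReconVolume(values=np.asarray(values, dtype=np.float32),
                       voxel_size=meta["voxel_size_um"],
                       provenance=BeamConfig(**meta["beam"]))
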