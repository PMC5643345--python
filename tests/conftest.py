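"""Shared fixtures: small phantoms and one cached end-to-end simulation."""

from __future__ import annotations

import numpy as np
import pytest

from cortivas import phantom as ph
from cortivas import pci_sim
from cortivas import segmentation as seg


def small_spec(**overrides) -> ph.PhantomSpec:
    """A 96³-ish cortex with 8 canals that simulates in ~15 s."""
    kwargs = dict(
        grid_shape=(96, 128, 128),
        voxel_size=1.0,
        cortex_outer_radius=58.0,
        cortex_inner_radius=26.0,
        n_canals=8,
        canal_diameter_mean=8.0,
        canal_diameter_sd=0.7,
        occupancy_fraction=0.95,
        vessel_fill_fraction=0.85,
        lacunar_density=4.0e4,
        rng_seed=1,
    )
    kwargs.update(overrides)
    return ph.PhantomSpec(**kwargs)


@pytest.fixture(scope="session")
def small_phantom():
    return ph.build_phantom(small_spec())


@pytest.fixture(scope="session")
def small_run(small_phantom):
    """Noiseless two-distance scan + reconstructions of the small phantom."""
    materials = ph.labels_to_materials(small_phantom)
    beams = [
        pci_sim.BeamConfig(propagation_distance_mm=d, n_projections=181,
                           rng_seed=i)
        for i, d in enumerate([0.0, 25.0])
    ]
    sino_abs, sino_phase = pci_sim.acquire_multi(materials, beams)
    recon_abs = pci_sim.reconstruct_fbp(sino_abs)
    recon_phase = pci_sim.reconstruct_fbp(sino_phase)
    return {
        "phantom": small_phantom,
        "materials": materials,
        "sino_abs": sino_abs,
        "sino_phase": sino_phase,
        "recon_abs": recon_abs,
        "recon_phase": recon_phase,
    }


@pytest.fixture(scope="session")
def small_segmentation(small_run):
    bone = seg.segment_bone(small_run["recon_abs"])
    pores = seg.extract_pores(bone, closing_radius_um=24.0)
    classification = seg.classify_pores(pores, bone.voxel_size)
    vessels = seg.detect_vessels(small_run["recon_phase"], classification,
                                 bone=bone)
    return {"bone": bone, "pores": pores, "classification": classification,
            "vessels": vessels}


def dice(a: np.ndarray, b: np.ndarray) -> float:
    return 2.0 * np.count_nonzero(a & b) / (
        np.count_nonzero(a) + np.count_nonzero(b))


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    return np.count_nonzero(a & b) / np.count_nonzero(a | b)
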