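"""Two-sample occupancy comparison, aggregation, and pipeline orchestration."""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .morphometry import MorphometryIndices, compute_indices

log = logging.getLogger(__name__)

#: Largest n1·n2 for which the exact permutation distribution is enumerated.
EXACT_LIMIT = 400


@dataclass
class GroupSample:
    label: str
    values: list[float]

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.size < 1:
            raise ValueError(f"group '{self.label}' is empty")
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"group '{self.label}' has non-finite values")


@dataclass
class TestResult:
    u_statistic: float
    p_two_sided: float
    method: str  # "exact" | "normal-approx"
    n1: int
    n2: int


def _midranks(pooled: np.ndarray) -> np.ndarray:
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def _exact_u_distribution(double_ranks: np.ndarray, n1: int) -> np.ndarray:
    """Counts of each value of 2·R1 over all equally likely subsets of size n1.

    Dynamic programming over the multiset of (doubled, integer) midranks;
    equivalent to full enumeration of the permutation distribution but
    polynomial in the sample sizes.
    """
    total = int(double_ranks.sum())
    # table[k][s] = number of size-k subsets with doubled-rank sum s
    table = np.zeros((n1 + 1, total + 1), dtype=float)
    table[0, 0] = 1.0
    for r in double_ranks:
        r = int(r)
        for k in range(n1, 0, -1):
            table[k, r:] += table[k - 1, :total + 1 - r]
    return table[n1]


def mann_whitney_exact(a: GroupSample, b: GroupSample) -> TestResult:
    """Two-sided Mann–Whitney U test, exact for small samples.

    U is computed from midranks (ties allowed).  When n1·n2 ≤ 400 the
    two-sided p-value is exact: the full permutation distribution of U over
    the observed pooled multiset is enumerated (via dynamic programming) and
    the smaller tail is doubled, capped at 1.  Larger samples fall back to
    the normal approximation with tie and continuity corrections.
    """
    x = np.asarray(a.values, dtype=float)
    y = np.asarray(b.values, dtype=float)
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    r1 = float(ranks[:n1].sum())
    u = r1 - n1 * (n1 + 1) / 2.0

    if n1 * n2 <= EXACT_LIMIT:
        double_ranks = np.round(2.0 * ranks).astype(np.int64)
        dist = _exact_u_distribution(double_ranks, n1)
        n_total = dist.sum()
        # 2·R1 values; convert the observed U to the same doubled scale.
        support = np.arange(dist.size)
        obs = int(round(2.0 * r1))
        p_low = dist[support <= obs].sum() / n_total
        p_high = dist[support >= obs].sum() / n_total
        p = min(1.0, 2.0 * min(p_low, p_high))
        return TestResult(u_statistic=u, p_two_sided=float(p), method="exact",
                          n1=n1, n2=n2)

    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts ** 3 - counts).sum())) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    mu = n1 * n2 / 2.0
    if sigma2 <= 0:
        return TestResult(u_statistic=u, p_two_sided=1.0,
                          method="normal-approx", n1=n1, n2=n2)
    from scipy.stats import norm

    z = (abs(u - mu) - 0.5) / np.sqrt(sigma2)
    p = min(1.0, 2.0 * float(norm.sf(max(z, 0.0))))
    return TestResult(u_statistic=u, p_two_sided=p, method="normal-approx",
                      n1=n1, n2=n2)


def summarize(indices: list[MorphometryIndices]) -> pd.DataFrame:
    """Per-parameter mean and sample SD (n−1) across datasets."""
    if not indices:
        raise ValueError("no datasets to summarize")
    if len(indices) == 1:
        log.warning("summarize: single dataset, SD reported as 0")
    rows = []
    for name in MorphometryIndices.FIELDS:
        vals = np.asarray([getattr(ix, name) for ix in indices], dtype=float)
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        rows.append({"Parameter": name, "Mean": float(vals.mean()), "SD": sd,
                     "N": len(vals)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pipeline

@dataclass
class PipelineConfig:
    """End-to-end run parameters; sections mirror the processing stages."""

    phantom: dict = field(default_factory=dict)
    # Distances: near-absorption ("abs") and phase-sensitive ("phase").
    distance_abs_mm: float = 5.0
    distance_phase_mm: float = 25.0
    n_projections: int = 181
    energy_kev: float = 21.0
    photons_per_pixel: float | None = None
    closing_radius_um: float | None = None  # default: 3 × canal diameter mean
    smooth_sigma_um: float | None = None  # None → 0 noiseless, 1.0 µm noisy
    volume_cutoff_um3: float = 2000.0
    elongation_cutoff: float = 5.0
    k_sigma: float = 4.5
    min_extent_px: int = 3
    n_slices: int = 60
    seed: int = 0
    filter_window: str | None = None

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(raw) - known
        if extra:
            raise ValueError(f"unknown pipeline config keys: {sorted(extra)}")
        return cls(**raw)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """phantom → two-distance acquisition → ring correction → FBP →
    segmentation → morphometry → summary.

    Writes all intermediate artifacts, an indices CSV, a ground-truth
    recovery CSV and a JSON manifest to ``out_dir``; returns a bundle with
    the in-memory results.  Any stage failure aborts with a stage-tagged
    error; artifacts written up to that point are retained.
    """
    from . import __version__, phantom as ph, pci_sim, segmentation as seg
    from .errors import CortivasError

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "init"
    timings: dict[str, float] = {}

    def tick(name):
        nonlocal stage
        timings[stage] = round(time.perf_counter() - tick.t0, 3)
        log.info("stage %-12s %7.2f s", stage, timings[stage])
        stage = name
        tick.t0 = time.perf_counter()

    tick.t0 = time.perf_counter()
    try:
        stage = "phantom"
        spec_kwargs = dict(config.phantom)
        spec_kwargs.setdefault("rng_seed", config.seed)
        if "grid_shape" in spec_kwargs:
            spec_kwargs["grid_shape"] = tuple(spec_kwargs["grid_shape"])
        if "lacuna_semi_axes" in spec_kwargs:
            spec_kwargs["lacuna_semi_axes"] = tuple(
                spec_kwargs["lacuna_semi_axes"])
        spec = ph.PhantomSpec(**spec_kwargs)
        phant = ph.build_phantom(spec)
        ph.save_phantom(phant, out / "phantom")
        truth = ph.ground_truth_indices(phant)
        materials = ph.labels_to_materials(phant)

        tick("acquire")
        beams = [
            pci_sim.BeamConfig(
                energy_kev=config.energy_kev,
                propagation_distance_mm=d,
                n_projections=config.n_projections,
                detector_pixel_um=spec.voxel_size,
                photons_per_pixel=config.photons_per_pixel,
                rng_seed=config.seed + i,
                filter_window=config.filter_window,
            )
            for i, d in enumerate([config.distance_abs_mm,
                                   config.distance_phase_mm])
        ]
        sino_abs, sino_phase = pci_sim.acquire_multi(materials, beams)
        pci_sim.save_sinogram(sino_abs, out / "sino_abs")
        pci_sim.save_sinogram(sino_phase, out / "sino_phase")

        tick("ring_correct")
        sino_abs = pci_sim.ring_correct(sino_abs)
        sino_phase = pci_sim.ring_correct(sino_phase)

        tick("reconstruct")
        recon_abs = pci_sim.reconstruct_fbp(sino_abs)
        recon_phase = pci_sim.reconstruct_fbp(sino_phase)
        pci_sim.save_recon(recon_abs, out / "recon_abs")
        pci_sim.save_recon(recon_phase, out / "recon_phase")

        tick("segment")
        smooth = config.smooth_sigma_um
        if smooth is None:
            smooth = 0.0 if beams[0].noiseless else 1.0
        bone = seg.segment_bone(recon_abs, smooth_sigma_um=smooth)
        closing = (config.closing_radius_um
                   if config.closing_radius_um is not None
                   else 3.0 * spec.canal_diameter_mean)
        pores = seg.extract_pores(bone, closing)
        classification = seg.classify_pores(
            pores, bone.voxel_size, config.volume_cutoff_um3,
            config.elongation_cutoff)
        vessels = seg.detect_vessels(recon_phase, classification,
                                     k_sigma=config.k_sigma, bone=bone,
                                     min_extent_px=config.min_extent_px)
        _write_classification_csv(classification,
                                  out / "pore_components.csv")

        tick("measure")
        estimate = compute_indices(classification, bone, vessels,
                                   n_slices=config.n_slices,
                                   dataset_id="pipeline")
        _write_indices_csv([estimate], out / "indices.csv")
        _write_recovery_csv(truth, estimate, out / "recovery.csv")

        tick("report")
        manifest = {
            "config": dataclasses.asdict(config),
            "phantom_spec": dataclasses.asdict(spec),
            "versions": {"cortivas": __version__,
                         "numpy": np.__version__,
                         "python": platform.python_version()},
            "timings_s": timings,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      sort_keys=True))
        tick("done")
    except CortivasError as err:
        raise type(err)(f"[stage: {stage}] {err}") from err

    return {"spec": spec, "phantom": phant, "truth": truth, "bone": bone,
            "classification": classification, "vessels": vessels,
            "recon_abs": recon_abs, "recon_phase": recon_phase,
            "indices": estimate, "out_dir": out}


def _write_indices_csv(indices: list[MorphometryIndices], path: Path) -> None:
    rows = []
    for ix in indices:
        row = {"dataset_id": ix.dataset_id, **ix.as_dict(),
               "n_slices_sampled": ix.n_slices_sampled}
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def _write_recovery_csv(truth: MorphometryIndices,
                        estimate: MorphometryIndices, path: Path) -> None:
    rows = []
    for name in MorphometryIndices.FIELDS:
        t, e = getattr(truth, name), getattr(estimate, name)
        rows.append({"index": name, "ground_truth": t, "estimate": e,
                     "abs_error": e - t,
                     "rel_error_pct": 100.0 * (e - t) / t if t else np.nan})
    pd.DataFrame(rows).to_csv(path, index=False)


def _write_classification_csv(classification, path: Path) -> None:
    rows = [{"id": c.id, "class": c.klass, "n_voxels": c.n_voxels,
             "volume_um3": c.volume_um3, "elongation": c.elongation,
             "equivalent_size_um": c.equivalent_size_um}
            for c in classification.components]
    pd.DataFrame(rows).to_csv(path, index=False)
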