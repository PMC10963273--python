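"""Operational self-checks of the pipeline's effective constants and calibration.

Rather than asserting configuration values, these probes *measure* what the
running code does: how many voxels influence a detection decision, the
smallest fractional excess that triggers one, the largest connected
component still counted as a cell, the exact QC retention boundaries, the
density-window geometry, the empirical size of the voxelwise test under a
null cohort, and how reliably the IEG score recovers planted activation.
They are used by the test suite and by the reproduction script; each
returns plain numbers computed from scratch.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .core import CountVolume, DensityParams, DetectionParams, Volume3D
from .detection import DetectionMask, cells_to_counts, detect_cells, detect_fos_voxels, find_cells
from .groupstats import local_density, voxelwise_ttest
from .ieg import (
    QCParams,
    ScoreParams,
    compute_cell_metrics,
    fisher_combine,
    qc_filter_cells,
    rank_clusters,
    reference_cluster_de,
    score_clusters,
)
from .sim_counts import SnRnaSimSpec, generate_snrnaseq
from .sim_volumes import CohortSimSpec, VolumeSimSpec, generate_cohort


# ---------------------------------------------------------------- detection

def measure_neighborhood_size(threshold_fraction: float = 0.20) -> int:
    """Count the offsets whose intensity can veto a detection.

    A 9³ probe volume holds one clear peak; every other voxel within a
    Chebyshev distance of 2 is raised in turn far above the peak. Offsets
    whose perturbation suppresses the detection are the detector's
    effective neighborhood.
    """
    base = np.full((9, 9, 9), 100.0)
    center = (4, 4, 4)
    base[center] = 100.0 * (1.0 + threshold_fraction) * 1.5
    params = DetectionParams(threshold_fraction=threshold_fraction)
    assert detect_fos_voxels(Volume3D(base), params=params).data[center]
    influencing = 0
    for dz in range(-2, 3):
        for dy in range(-2, 3):
            for dx in range(-2, 3):
                if (dz, dy, dx) == (0, 0, 0):
                    continue
                probe = base.copy()
                probe[center[0] + dz, center[1] + dy, center[2] + dx] = 1e6
                if not detect_fos_voxels(Volume3D(probe), params=params).data[center]:
                    influencing += 1
    return influencing


def measure_min_detected_excess(
    threshold_fraction: float = 0.20, grid_step: float = 0.001
) -> float:
    """Smallest fractional excess over a flat background that is detected.

    Sweeps a single-voxel peak from 15% to 25% excess in ``grid_step``
    increments and returns the first detected excess (resolution =
    ``grid_step``).
    """
    params = DetectionParams(threshold_fraction=threshold_fraction)
    for excess in np.arange(0.15, 0.25 + grid_step / 2, grid_step):
        data = np.full((5, 5, 5), 100.0)
        data[2, 2, 2] = 100.0 * (1.0 + excess)
        if detect_fos_voxels(Volume3D(data), params=params).data[2, 2, 2]:
            return float(round(excess, 9))
    return float("nan")


def measure_max_cell_size(max_probe: int = 12) -> int:
    """Largest connected component still counted as one cell.

    Plants straight-line components of 1..``max_probe`` voxels into a
    detection mask and records which sizes the cluster stage accepts.
    """
    params = DetectionParams()
    accepted = []
    for length in range(1, max_probe + 1):
        mask = np.zeros((5, 5, max_probe + 4), dtype=bool)
        mask[2, 2, 2 : 2 + length] = True
        cells = find_cells(DetectionMask(mask), params)
        if len(cells) == 1 and cells.cells[0].size == length:
            accepted.append(length)
    return max(accepted)


def measure_noiseless_recall(seed: int = 0) -> dict[str, float]:
    """Recall and precision on noiseless planted single-voxel cells.

    The ratio detector guarantees detection of an isolated peak; two
    planted cells in adjacent voxels form a plateau neither member of
    which exceeds all its neighbors, a collision loss the generator
    deliberately does not hide. Recall is therefore reported both over all
    planted cells and over the isolated ones (no other cell voxel within
    Chebyshev distance 1), where it is exact.
    """
    from .sim_volumes import generate_volume

    spec = VolumeSimSpec(noise_sd=0.0, cell_margin=0.4, seed=seed,
                         region_densities={1: 60.0, 2: 60.0})
    volume, mask, _, truth = generate_volume(spec)
    detected = detect_cells(volume, mask)
    truth_voxels = {c.voxels[0] for c in truth.cells}
    detected_voxels = {c.voxels[0] for c in detected.cells}
    isolated = {
        v for v in truth_voxels
        if not any(
            u != v and max(abs(u[0] - v[0]), abs(u[1] - v[1]), abs(u[2] - v[2])) <= 1
            for u in truth_voxels
        )
    }
    return {
        "recall_isolated_pct": 100.0 * len(isolated & detected_voxels) / len(isolated),
        "recall_all_pct": 100.0 * len(truth_voxels & detected_voxels) / len(truth_voxels),
        "precision_pct": 100.0 * len(detected_voxels & truth_voxels) / max(len(detected_voxels), 1),
        "n_planted": float(len(truth_voxels)),
    }


# ------------------------------------------------------------------ density

def measure_window_volume_ul(
    kernel_extent: int = 20, voxel_size=(25.0, 25.0, 25.0)
) -> float:
    return DensityParams(kernel_extent).window_volume_ul(voxel_size)


def measure_single_cell_plateau(
    kernel_extent: int = 20, voxel_size=(25.0, 25.0, 25.0)
) -> float:
    """Peak density produced by one interior cell, in cells/µl."""
    counts = np.zeros((2 * kernel_extent, ) * 3, dtype=np.int64)
    counts[kernel_extent, kernel_extent, kernel_extent] = 1
    dmap = local_density(CountVolume(counts, voxel_size), DensityParams(kernel_extent))
    return float(dmap.data.max())


def measure_density_mass(
    n_cells: int = 13, kernel_extent: int = 20, seed: int = 0
) -> float:
    """Total density mass (Σ density × voxel volume) per interior cell."""
    from .core import voxel_volume_ul

    rng = np.random.default_rng(seed)
    shape = (3 * kernel_extent,) * 3
    counts = np.zeros(shape, dtype=np.int64)
    for v in rng.integers(kernel_extent, 2 * kernel_extent, size=(n_cells, 3)):
        counts[tuple(v)] += 1
    dmap = local_density(CountVolume(counts, (25.0, 25.0, 25.0)), DensityParams(kernel_extent))
    return float(dmap.data.sum() * voxel_volume_ul((25.0, 25.0, 25.0)) / n_cells)


# ----------------------------------------------------------- group statistics

def _cohort_pvalue_map(spec: CohortSimSpec, detection=DetectionParams(),
                       density=DensityParams()):
    cohort = generate_cohort(spec)
    maps = {"a": [], "b": []}
    for key, animals in (("a", cohort.group_a), ("b", cohort.group_b)):
        for animal in animals:
            cells = detect_cells(animal.volume, animal.mask, detection)
            counts = cells_to_counts(cells, animal.volume.shape, animal.volume.voxel_size)
            maps[key].append(local_density(counts, density))
    return voxelwise_ttest(maps["a"], maps["b"]), cohort.labels


def run_null_calibration(n_reps: int = 200, seed: int = 0, alpha: float = 0.05):
    """Empirical size of the voxelwise test on matched-density cohorts.

    Runs the full pipeline (simulate → detect → density → t-test) on
    ``n_reps`` null cohorts (4 vs 4 animals, identical densities) and
    returns the per-replicate fractions of defined voxels with p < alpha.
    """
    seeds = np.random.SeedSequence(seed).spawn(n_reps)
    fractions = []
    for child in seeds:
        rep_seed = int(child.generate_state(1)[0] % 2**31)
        spec = CohortSimSpec(base=VolumeSimSpec(seed=rep_seed))
        stat, _ = _cohort_pvalue_map(spec)
        p = stat.p[stat.defined]
        fractions.append(float((p < alpha).mean()))
    return np.asarray(fractions)


def run_effect_recovery(n_reps: int = 50, seed: int = 0, alpha: float = 0.05):
    """Planted-effect detection: 40 vs 0 cells/µl in one region.

    Returns a DataFrame with per-replicate significant-voxel fractions
    inside and outside the effect region and whether the effect region has
    the minimum mean p across regions.
    """
    seeds = np.random.SeedSequence(seed).spawn(n_reps)
    rows = []
    for child in seeds:
        rep_seed = int(child.generate_state(1)[0] % 2**31)
        spec = CohortSimSpec(
            base=VolumeSimSpec(seed=rep_seed), group_densities={2: (40.0, 0.0)}
        )
        stat, labels = _cohort_pvalue_map(spec)
        in_region = (labels.data == 2) & stat.defined
        out_region = (labels.data != 2) & (labels.data > 0) & stat.defined
        mean_p = {
            lab: float(stat.p[(labels.data == lab) & stat.defined].mean())
            for lab in labels.labels
        }
        rows.append(
            {
                "frac_in": float((stat.p[in_region] < alpha).mean()),
                "frac_out": float((stat.p[out_region] < alpha).mean()),
                "effect_region_has_min_mean_p": min(mean_p, key=mean_p.get) == 2,
            }
        )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------- QC

def sweep_qc_boundaries(params: QCParams | None = None) -> dict[str, float]:
    """Measure the exact retention boundaries of the QC filter.

    Sweeps each metric through a fine grid while holding the others safely
    in range, and reports the minimal retained UMI count, minimal retained
    gene count and maximal retained mitochondrial fraction.
    """
    params = params or QCParams()

    def metrics(umi, genes, mito):
        return pd.DataFrame(
            {"cell": ["probe"], "umi_count": [umi], "gene_count": [genes],
             "mito_fraction": [mito]}
        )

    umi_grid = np.arange(params.min_umis - 10, params.min_umis + 11)
    retained_umi = [u for u in umi_grid if len(qc_filter_cells(metrics(u, 10_000, 0.0), params))]
    gene_grid = np.arange(params.min_genes - 10, params.min_genes + 11)
    retained_genes = [g for g in gene_grid if len(qc_filter_cells(metrics(10_000, g, 0.0), params))]
    mito_grid = np.round(np.arange(0.085, 0.1155, 0.0005), 4)
    retained_mito = [m for m in mito_grid if len(qc_filter_cells(metrics(10_000, 10_000, m), params))]
    return {
        "min_retained_umis": float(min(retained_umi)),
        "min_retained_genes": float(min(retained_genes)),
        "max_retained_mito_fraction": float(max(retained_mito)),
    }


# -------------------------------------------------------------------- score

def measure_fisher_k1_error(grid: np.ndarray | None = None) -> float:
    """Max |combined_p − p| over a grid of single p-values (k = 1 identity)."""
    if grid is None:
        grid = np.concatenate([np.logspace(-8, -1, 30), np.linspace(0.1, 1.0, 30)])
    errors = [abs(fisher_combine([p])["combined_p"] - p) for p in grid]
    return float(max(errors))


def run_ieg_recovery(n_reps: int = 50, seed: int = 0) -> pd.DataFrame:
    """Planted-activation recovery through QC → DE → score → rank.

    Default study conditions: 6 clusters × 400 cells, 2 samples per
    condition, one activated and one inhibited cluster at |log2FC| = 1.5 on
    the 10-IEG panel. Returns per-replicate outcomes.
    """
    base = SnRnaSimSpec()
    params = ScoreParams()
    seeds = np.random.SeedSequence(seed).spawn(n_reps)
    rows = []
    for child in seeds:
        rep_seed = int(child.generate_state(1)[0] % 2**31)
        spec = dataclasses.replace(base, seed=rep_seed)
        adata, _ = generate_snrnaseq(spec)
        keep = qc_filter_cells(compute_cell_metrics(adata))
        adata = adata[list(keep)].copy()
        de = reference_cluster_de(adata, genes=list(params.ieg_panel))
        scores = score_clusters(de, params)
        ranked = rank_clusters(scores, top_n=4)
        activated = str(next(iter(base.activated_clusters)))
        inhibited = str(next(iter(base.inhibited_clusters)))
        by_cluster = scores.set_index("cluster")
        rows.append(
            {
                "activated_ranked_first": str(ranked[0]) == activated,
                "inhibited_score_negative": float(by_cluster.loc[inhibited, "score"]) < 0,
                "n_retained_cells": int(adata.n_obs),
            }
        )
    return pd.DataFrame(rows)
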