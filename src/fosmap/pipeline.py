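"""End-to-end runs from a single configuration file.

A run config (YAML or JSON) selects one or both branches — the Fos imaging
branch (simulate cohort → detect cells → density maps → voxelwise t-test →
region table) and the snRNA-seq branch (simulate counts → QC → per-cluster
DE → IEG scores → ranking) — under one global seed. Per-stage seeds derive
from the global seed through ``numpy.random.SeedSequence([seed, stage_counter])``,
so stages never share a stream and reruns with the same config are
bit-identical for every deterministic stage.

Every run writes its artifacts plus: the fully-echoed configuration
(``config.yaml``), a machine-readable event log (``events.jsonl``) and a
manifest (``manifest.json``) listing each artifact with its SHA-256 hash.
Unknown configuration keys are rejected outright rather than ignored.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import yaml

from . import io as fio
from .core import DensityParams, DetectionParams
from .detection import cells_to_counts, detect_cells
from .errors import ConfigurationError
from .groupstats import local_density, summarize_regions, voxelwise_ttest
from .ieg import (
    QCParams,
    ScoreParams,
    compute_cell_metrics,
    qc_filter_cells,
    rank_clusters,
    reference_cluster_de,
    score_clusters,
)
from .sim_counts import SnRnaSimSpec, generate_snrnaseq, write_snrnaseq
from .sim_volumes import CohortSimSpec, VolumeSimSpec, generate_cohort

logger = logging.getLogger(__name__)

_STAGE_COUNTERS = {"fos": 1, "ieg": 2}


def stage_seed(seed: int, stage: str) -> int:
    """Counter-based per-stage seed derivation from the global seed."""
    counter = _STAGE_COUNTERS[stage]
    return int(np.random.SeedSequence([int(seed), counter]).generate_state(1)[0] % 2**31)


def _build(cls, data: dict, context: str):
    """Instantiate a dataclass from a mapping, rejecting unknown keys."""
    if not isinstance(data, dict):
        raise ConfigurationError(f"{context}: expected a mapping, got {type(data).__name__}")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigurationError(f"{context}: unknown key(s) {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        if isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


@dataclass(frozen=True)
class FosStageConfig:
    cohort: CohortSimSpec = field(default_factory=CohortSimSpec)
    detection: DetectionParams = field(default_factory=DetectionParams)
    density: DensityParams = field(default_factory=DensityParams)
    variant: str = "student"
    alpha: float = 0.05


@dataclass(frozen=True)
class IegStageConfig:
    sim: SnRnaSimSpec = field(default_factory=SnRnaSimSpec)
    qc: QCParams = field(default_factory=QCParams)
    score: ScoreParams = field(default_factory=ScoreParams)
    de_method: str = "pseudobulk_t"
    top_n: int = 4


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration; at least one branch must be enabled."""

    seed: int = 0
    out_dir: str = "results/run"
    log_level: str = "INFO"
    fos: FosStageConfig | None = None
    ieg: IegStageConfig | None = None

    def __post_init__(self) -> None:
        if self.fos is None and self.ieg is None:
            raise ConfigurationError("config enables neither the fos nor the ieg branch")


def parse_config(data: dict) -> RunConfig:
    """Build a :class:`RunConfig` from a plain mapping (fail-fast)."""
    if not isinstance(data, dict):
        raise ConfigurationError("config root must be a mapping")
    import copy

    data = copy.deepcopy(data)  # parsing pops nested keys; never mutate the caller's mapping
    known = {"seed", "out_dir", "log_level", "fos", "ieg"}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(f"config: unknown key(s) {sorted(unknown)}")
    fos = ieg = None
    if "fos" in data and data["fos"] is not None:
        sub = dict(data["fos"])
        cohort_data = sub.pop("cohort", {})
        base_data = dict(cohort_data.pop("base", {})) if isinstance(cohort_data, dict) else {}
        gd = cohort_data.pop("group_densities", {}) if isinstance(cohort_data, dict) else {}
        base = _build(VolumeSimSpec, base_data, "fos.cohort.base")
        cohort = _build(
            CohortSimSpec,
            {**cohort_data, "base": base, "group_densities": {int(k): tuple(v) for k, v in dict(gd).items()}},
            "fos.cohort",
        )
        detection = _build(DetectionParams, sub.pop("detection", {}), "fos.detection")
        density = _build(DensityParams, sub.pop("density", {}), "fos.density")
        fos = _build(
            FosStageConfig,
            {**sub, "cohort": cohort, "detection": detection, "density": density},
            "fos",
        )
    if "ieg" in data and data["ieg"] is not None:
        sub = dict(data["ieg"])
        sim = _build(SnRnaSimSpec, sub.pop("sim", {}), "ieg.sim")
        qc = _build(QCParams, sub.pop("qc", {}), "ieg.qc")
        score = _build(ScoreParams, sub.pop("score", {}), "ieg.score")
        ieg = _build(IegStageConfig, {**sub, "sim": sim, "qc": qc, "score": score}, "ieg")
    top = {k: v for k, v in data.items() if k in ("seed", "out_dir", "log_level")}
    return RunConfig(fos=fos, ieg=ieg, **top)


def serialize_config(config: RunConfig) -> dict:
    """Plain-mapping echo of a config; ``parse_config`` round-trips it."""

    def as_dict(obj: Any) -> Any:
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: as_dict(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {k: as_dict(v) for k, v in obj.items()}
        if isinstance(obj, (tuple, list, set, frozenset)):
            return [as_dict(v) for v in sorted(obj)] if isinstance(obj, (set, frozenset)) else [as_dict(v) for v in obj]
        return obj

    out = {"seed": config.seed, "out_dir": config.out_dir, "log_level": config.log_level}
    if config.fos is not None:
        out["fos"] = as_dict(config.fos)
    if config.ieg is not None:
        out["ieg"] = as_dict(config.ieg)
    return out


def load_config(path: str) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return parse_config(data or {})


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _EventLog:
    def __init__(self, path: str):
        self._fh = open(path, "w", encoding="utf-8")

    def emit(self, event: str, **fields: Any) -> None:
        record = {"time": round(time.time(), 3), "event": event, **fields}
        self._fh.write(json.dumps(record) + "\n")
        self._fh.flush()
        logger.info("%s %s", event, fields or "")

    def close(self) -> None:
        self._fh.close()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured branches and return the artifact manifest."""
    os.makedirs(config.out_dir, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    log = _EventLog(os.path.join(config.out_dir, "events.jsonl"))
    artifacts: list[str] = []

    config_path = os.path.join(config.out_dir, "config.yaml")
    with open(config_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(serialize_config(config), fh, sort_keys=True)
    artifacts.append(config_path)
    log.emit("config_written", path=config_path)

    if config.fos is not None:
        artifacts += _run_fos(config, log)
    if config.ieg is not None:
        artifacts += _run_ieg(config, log)

    manifest = {
        "seed": config.seed,
        "artifacts": {
            os.path.relpath(p, config.out_dir): _sha256(p) for p in artifacts
        },
    }
    manifest_path = os.path.join(config.out_dir, "manifest.json")
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.emit("manifest_written", path=manifest_path, n_artifacts=len(artifacts))
    log.close()
    return manifest


def _run_fos(config: RunConfig, log: _EventLog) -> list[str]:
    import dataclasses as dc

    import pandas as pd

    cfg = config.fos
    out = os.path.join(config.out_dir, "fos")
    os.makedirs(out, exist_ok=True)
    seeded = dc.replace(cfg.cohort, base=dc.replace(cfg.cohort.base, seed=stage_seed(config.seed, "fos")))
    cohort = generate_cohort(seeded)
    log.emit("cohort_generated", n_per_group=seeded.n_per_group)

    paths: list[str] = []
    density_maps = {"a": [], "b": []}
    cell_rows = []
    for gname, animals in (("a", cohort.group_a), ("b", cohort.group_b)):
        for i, animal in enumerate(animals):
            cells = detect_cells(animal.volume, animal.mask, cfg.detection)
            for j, cell in enumerate(cells.cells):
                cz, cy, cx = cell.centroid
                cell_rows.append(
                    {"group": gname, "animal": i, "cell": j, "size": cell.size,
                     "z": cz, "y": cy, "x": cx}
                )
            counts = cells_to_counts(cells, animal.volume.shape, animal.volume.voxel_size)
            density_maps[gname].append(local_density(counts, cfg.density))
    log.emit("cells_detected", n_cells=len(cell_rows))
    cells_path = os.path.join(out, "cells.tsv")
    fio.write_table(pd.DataFrame(cell_rows, columns=["group", "animal", "cell", "size", "z", "y", "x"]), cells_path)
    paths.append(cells_path)

    stat = voxelwise_ttest(density_maps["a"], density_maps["b"], cfg.variant)
    table = summarize_regions(stat, cohort.labels, alpha=cfg.alpha)
    regions_path = os.path.join(out, "regions.tsv")
    fio.write_table(table, regions_path)
    paths.append(regions_path)

    pmap = np.where(stat.defined, stat.p, np.nan)
    pmap_path = os.path.join(out, "pmap.nii.gz")
    from .core import Volume3D

    fio.write_volume(Volume3D(np.nan_to_num(pmap, nan=1.0), cfg.cohort.base.voxel_size), pmap_path)
    paths.append(pmap_path)
    log.emit("fos_branch_done", regions=len(table))
    return paths


def _run_ieg(config: RunConfig, log: _EventLog) -> list[str]:
    import dataclasses as dc

    import pandas as pd

    cfg = config.ieg
    out = os.path.join(config.out_dir, "ieg")
    os.makedirs(out, exist_ok=True)
    spec = dc.replace(cfg.sim, seed=stage_seed(config.seed, "ieg"))
    adata, effects = generate_snrnaseq(spec)
    written = write_snrnaseq(adata, os.path.join(out, "counts"))
    paths = list(written.values())
    log.emit("snrnaseq_generated", n_cells=adata.n_obs, n_genes=adata.n_vars)

    metrics = compute_cell_metrics(adata)
    keep = qc_filter_cells(metrics, cfg.qc)
    filtered = adata[list(keep)].copy()
    log.emit("qc_filtered", retained=len(keep), removed=adata.n_obs - len(keep))

    de = reference_cluster_de(filtered, method=cfg.de_method)
    de_path = os.path.join(out, "de_table.tsv")
    fio.write_table(de, de_path)
    paths.append(de_path)

    scores = score_clusters(de, cfg.score)
    scores_path = os.path.join(out, "scores.tsv")
    fio.write_table(scores, scores_path)
    paths.append(scores_path)

    ranked = rank_clusters(scores, top_n=cfg.top_n)
    ranked_path = os.path.join(out, "top_clusters.tsv")
    fio.write_table(pd.DataFrame({"rank": range(1, len(ranked) + 1), "cluster": ranked}), ranked_path)
    paths.append(ranked_path)

    effects_path = os.path.join(out, "true_effects.tsv")
    fio.write_table(effects, effects_path)
    paths.append(effects_path)
    log.emit("ieg_branch_done", top_clusters=[str(c) for c in ranked])
    return paths
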