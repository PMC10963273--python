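"""Seeded generator for ground-truthed cleared-brain volumes.

Emulates the statistical structure the Fos pipeline assumes: a spatially
smooth background (low-frequency multiplicative field around a base level)
plus white noise, with point-like Fos⁺ cells planted by a per-region Poisson
process. Each planted cell is a 26-connected voxel cluster whose size is
drawn from ``cell_size_range``; every cell voxel is set to
``(1 + cell_margin) ×`` the local background maximum before noise, so with
``cell_margin`` above the detector threshold and zero noise every interior
single-voxel cell is a guaranteed detection. Cells are rejected and
resampled if they would touch the tissue boundary; overlaps between cells
are allowed — merged clusters exceeding the artefact cap are an honest,
measurable source of false negatives rather than something hidden by an
exclusion zone.

Not modelled: optics (PSF, attenuation, stripe artefacts) or registration
error; volumes arrive pre-registered by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import ndimage

from .core import LabelVolume, TissueMask, Volume3D, voxel_volume_ul
from .detection import Cell, CellSet
from .errors import ConfigurationError, DomainError

#: width of the unlabelled margin around the simulated tissue interior
_EDGE_MARGIN = 2


@dataclass(frozen=True)
class VolumeSimSpec:
    """Parameters of one simulated cleared-brain volume.

    ``region_densities`` maps region label (> 0) to the expected density of
    planted cells in cells/µl; region geometry is deterministic slabs along
    the first axis inside a 2-voxel margin. ``cell_margin`` is the
    fractional intensity excess of cell voxels over the local background
    (0.4 = 40% above, comfortably beyond the 20% detection threshold;
    set it below the threshold for negative controls).

    The default single-voxel ``cell_size_range`` reflects the detector's
    character: the all-neighbor ratio rule fires on local intensity peaks,
    and a noiseless multi-voxel plateau contains no such peak. Extended
    cells (up to the 8-voxel cap) are available for stress tests of the
    cluster/artefact logic.
    """

    shape: tuple[int, int, int] = (48, 48, 48)
    voxel_size: tuple[float, float, float] = (25.0, 25.0, 25.0)
    background_level: float = 100.0
    background_smoothness: float = 0.05  # relative sd of the low-frequency field
    noise_sd: float = 5.0
    cell_margin: float = 0.4
    cell_size_range: tuple[int, int] = (1, 1)
    region_densities: Mapping[int, float] = field(
        default_factory=lambda: {1: 40.0, 2: 40.0, 3: 40.0}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or min(self.shape) < 2 * _EDGE_MARGIN + 3:
            raise ConfigurationError(
                f"shape {self.shape} too small to hold interior cells"
            )
        voxel_volume_ul(self.voxel_size)
        if self.background_level <= 0:
            raise ConfigurationError("background_level must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.cell_margin < 0:
            raise ConfigurationError("cell_margin must be >= 0")
        lo, hi = self.cell_size_range
        if not (1 <= lo <= hi <= 8):
            raise ConfigurationError("cell_size_range must lie within [1, 8]")
        dens = {int(k): float(v) for k, v in dict(self.region_densities).items()}
        if any(k <= 0 for k in dens):
            raise ConfigurationError("region labels must be positive (0 = outside)")
        if any(v < 0 for v in dens.values()):
            raise ConfigurationError("region densities must be >= 0")
        object.__setattr__(self, "region_densities", dens)
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))


def _region_labels(spec: VolumeSimSpec) -> LabelVolume:
    """Deterministic slab geometry: interior split along axis 0 by label."""
    labels = np.zeros(spec.shape, dtype=np.int64)
    keys = sorted(spec.region_densities)
    m = _EDGE_MARGIN
    interior_extent = spec.shape[0] - 2 * m
    if interior_extent < len(keys):
        raise ConfigurationError(
            f"shape {spec.shape} cannot host {len(keys)} slab regions"
        )
    edges = np.linspace(m, spec.shape[0] - m, len(keys) + 1).round().astype(int)
    for label, z0, z1 in zip(keys, edges[:-1], edges[1:]):
        labels[z0:z1, m : spec.shape[1] - m, m : spec.shape[2] - m] = label
    table = {k: f"region_{k}" for k in keys}
    return LabelVolume(labels, table)


def _smooth_background(spec: VolumeSimSpec, rng: np.random.Generator) -> np.ndarray:
    coarse_shape = tuple(max(2, s // 12 + 1) for s in spec.shape)
    coarse = rng.normal(0.0, spec.background_smoothness, size=coarse_shape)
    axes = [np.linspace(0, cs - 1, s) for cs, s in zip(coarse_shape, spec.shape)]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    field = ndimage.map_coordinates(coarse, [zz, yy, xx], order=1, mode="nearest")
    return spec.background_level * np.clip(1.0 + field, 0.1, None)


def _grow_cell(
    seed_voxel: tuple[int, int, int],
    size: int,
    allowed: np.ndarray,
    rng: np.random.Generator,
) -> tuple[tuple[int, int, int], ...] | None:
    """Grow a 26-connected cluster inside ``allowed``; None if stuck."""
    voxels = {seed_voxel}
    attempts = 0
    while len(voxels) < size:
        attempts += 1
        if attempts > 200:
            return None
        base = list(voxels)[rng.integers(len(voxels))]
        off = rng.integers(-1, 2, size=3)
        if not off.any():
            continue
        cand = (base[0] + int(off[0]), base[1] + int(off[1]), base[2] + int(off[2]))
        if cand in voxels:
            continue
        if not (
            0 <= cand[0] < allowed.shape[0]
            and 0 <= cand[1] < allowed.shape[1]
            and 0 <= cand[2] < allowed.shape[2]
        ) or not allowed[cand]:
            continue
        voxels.add(cand)
    return tuple(sorted(voxels))


def generate_volume(
    spec: VolumeSimSpec,
) -> tuple[Volume3D, TissueMask, LabelVolume, CellSet]:
    """Simulate one volume with ground truth.

    Returns the intensity volume, the tissue mask (all-tissue; boundary
    handling is exercised at the array edge), the region label volume, and
    the ground-truth ``CellSet`` of planted cells. Identical specs (seed
    included) give bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    labels = _region_labels(spec)
    mask = TissueMask.all_tissue(spec.shape)
    background = _smooth_background(spec, rng)
    # local background maximum: planted peaks must beat every neighbor
    local_bg_max = ndimage.maximum_filter(background, size=3, mode="nearest")

    interior = ndimage.binary_erosion(
        mask.data, structure=np.ones((3, 3, 3), bool), border_value=0
    )
    vox_ul = voxel_volume_ul(spec.voxel_size)
    lo, hi = spec.cell_size_range

    planted: list[Cell] = []
    volume = background.copy()
    for label in sorted(spec.region_densities):
        density = spec.region_densities[label]
        region = (labels.data == label) & interior
        region_idx = np.argwhere(region)
        if region_idx.size == 0:
            if density > 0:
                raise ConfigurationError(
                    f"region {label} has no interior voxels to host cells"
                )
            continue
        n_cells = rng.poisson(density * len(region_idx) * vox_ul)
        placed = 0
        while placed < n_cells:
            seed_voxel = tuple(region_idx[rng.integers(len(region_idx))].tolist())
            size = int(rng.integers(lo, hi + 1))
            voxels = _grow_cell(seed_voxel, size, interior, rng)
            if voxels is None:
                continue
            centroid = tuple(np.mean(voxels, axis=0).tolist())
            planted.append(Cell(voxels=voxels, centroid=centroid))
            for v in voxels:
                value = (1.0 + spec.cell_margin) * local_bg_max[v]
                volume[v] = max(volume[v], value)
            placed += 1

    if spec.noise_sd > 0:
        volume = volume + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    truth = CellSet(cells=tuple(planted))
    return Volume3D(volume, spec.voxel_size), mask, labels, truth


@dataclass(frozen=True)
class CohortSimSpec:
    """Two groups of simulated animals differing only in region densities.

    ``group_densities`` maps region label to ``(density_group_a,
    density_group_b)`` in cells/µl; regions not listed keep the base
    density in both groups. ``n_per_group`` defaults to 4 animals, the
    group size of the whole-brain comparison this emulates.
    """

    base: VolumeSimSpec = field(default_factory=VolumeSimSpec)
    group_densities: Mapping[int, tuple[float, float]] = field(default_factory=dict)
    n_per_group: int = 4

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ConfigurationError(
                "n_per_group must be >= 2 (the group t-test is undefined below that)"
            )
        gd = {
            int(k): (float(v[0]), float(v[1]))
            for k, v in dict(self.group_densities).items()
        }
        unknown = set(gd) - set(self.base.region_densities)
        if unknown:
            raise ConfigurationError(
                f"group_densities refers to unknown regions {sorted(unknown)}"
            )
        if any(d < 0 for pair in gd.values() for d in pair):
            raise ConfigurationError("group densities must be >= 0")
        object.__setattr__(self, "group_densities", gd)


@dataclass(frozen=True)
class SimulatedAnimal:
    """One simulated animal: its volume, mask and ground-truth cells."""

    volume: Volume3D
    mask: TissueMask
    truth: CellSet


@dataclass(frozen=True)
class Cohort:
    group_a: tuple[SimulatedAnimal, ...]
    group_b: tuple[SimulatedAnimal, ...]
    labels: LabelVolume


def generate_cohort(spec: CohortSimSpec) -> Cohort:
    """Simulate ``n_per_group`` animals per group with derived seeds.

    Per-animal seeds come from spawning a ``numpy.random.SeedSequence`` on
    the base seed, so the whole cohort is reproducible from one integer and
    no two animals share a stream.
    """
    children = np.random.SeedSequence(spec.base.seed).spawn(2 * spec.n_per_group)
    child_seeds = [int(c.generate_state(1)[0] % 2**31) for c in children]

    def densities_for(group: int) -> dict[int, float]:
        out = dict(spec.base.region_densities)
        for label, pair in spec.group_densities.items():
            out[label] = pair[group]
        return out

    animals: dict[int, list[SimulatedAnimal]] = {0: [], 1: []}
    labels = None
    for i, seed in enumerate(child_seeds):
        group = i % 2
        vspec = replace(
            spec.base, seed=seed, region_densities=densities_for(group)
        )
        volume, mask, lab, truth = generate_volume(vspec)
        animals[group].append(SimulatedAnimal(volume, mask, truth))
        labels = lab  # geometry identical across animals
    assert labels is not None
    return Cohort(
        group_a=tuple(animals[0]), group_b=tuple(animals[1]), labels=labels
    )
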