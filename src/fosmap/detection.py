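"""Fos⁺ cell detection on registered light-sheet volumes.

Two stages. (1) Voxel detection: a voxel is rated Fos-positive when its
value exceeds each of its 26 neighbors (3×3×3 cube minus the center) by at
least a fractional margin, 20% by default. Only voxels whose entire
neighborhood lies inside the tissue mask — and hence off the array edge —
are considered, which suppresses artefacts at the brain surface. The rule
is a ratio, so detections are invariant to any global rescaling of the
intensities (but not to additive offsets). (2) Clustering: connected
components of the detection mask (26-connectivity by default); components
of 1–8 voxels count as one Fos⁺ cell, larger components are recorded as
artefacts.

A ``mean-of-neighbors`` comparison mode (margin over the neighborhood mean
instead of every neighbor) is provided as a non-default alternative reading
of the rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import (
    NEIGHBOR_OFFSETS_26,
    CountVolume,
    DetectionParams,
    TissueMask,
    Volume3D,
)
from .errors import DomainError


@dataclass(frozen=True)
class DetectionMask:
    """Boolean grid of Fos-candidate voxels plus the parameters that made it."""

    data: np.ndarray
    params: DetectionParams = field(default_factory=DetectionParams)

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=bool)
        if data.ndim != 3:
            raise DomainError("detection mask must be 3-D")
        object.__setattr__(self, "data", data)

    @property
    def n_flagged(self) -> int:
        return int(self.data.sum())


@dataclass(frozen=True)
class Cell:
    """One detected Fos⁺ cell: its voxels, size, and unweighted centroid."""

    voxels: tuple[tuple[int, int, int], ...]
    centroid: tuple[float, float, float]

    @property
    def size(self) -> int:
        return len(self.voxels)


@dataclass(frozen=True)
class CellSet:
    """Accepted cells and discarded artefact clusters from one volume."""

    cells: tuple[Cell, ...]
    artefacts: tuple[Cell, ...] = ()
    params: DetectionParams = field(default_factory=DetectionParams)

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def centroids(self) -> np.ndarray:
        if not self.cells:
            return np.empty((0, 3))
        return np.array([c.centroid for c in self.cells], dtype=float)


def _interior(mask: np.ndarray) -> np.ndarray:
    """Voxels whose full 26-neighborhood exists and lies inside the tissue."""
    return ndimage.binary_erosion(mask, structure=np.ones((3, 3, 3), bool), border_value=0)


def detect_fos_voxels(
    volume: Volume3D,
    mask: TissueMask | None = None,
    params: DetectionParams | None = None,
) -> DetectionMask:
    """Rate voxels as Fos-positive by the neighborhood-excess rule.

    A voxel ``v`` is flagged iff (a) all 26 neighbors exist and are inside
    ``mask``, and (b) ``value(v) >= (1 + threshold_fraction) * value(u)``
    together with ``value(v) > value(u)`` for every neighbor ``u`` (under
    ``mean-of-neighbors``, against the neighbor mean). The strict part of
    the comparison only matters on exactly-zero background, where the ratio
    alone would be vacuous.
    """
    params = params or DetectionParams()
    if mask is None:
        mask = TissueMask.all_tissue(volume.shape)
    mask.check_shape(volume)

    data = np.asarray(volume.data, dtype=np.float64)
    candidates = _interior(mask.data)
    factor = 1.0 + params.threshold_fraction

    if params.comparison_mode == "each-neighbor":
        ok = candidates.copy()
        for offset in NEIGHBOR_OFFSETS_26:
            if not ok.any():
                break
            shifted = np.roll(data, shift=offset, axis=(0, 1, 2))
            # wrapped entries only land on edge voxels, which are never candidates
            ok &= (data >= factor * shifted) & (data > shifted)
    else:
        total = np.zeros_like(data)
        for offset in NEIGHBOR_OFFSETS_26:
            total += np.roll(data, shift=offset, axis=(0, 1, 2))
        neighbor_mean = total / 26.0
        ok = candidates & (data >= factor * neighbor_mean) & (data > neighbor_mean)

    return DetectionMask(data=ok, params=params)


_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


def find_cells(mask: DetectionMask, params: DetectionParams | None = None) -> CellSet:
    """Group flagged voxels into cells by the 1–8-voxel cluster rule.

    Connected components are computed under ``params.connectivity``;
    components with size in ``[min_cluster_voxels, max_cluster_voxels]``
    become cells, all others artefacts. Centroids are unweighted means of
    member voxel coordinates (fractional, ``(z, y, x)``).
    """
    params = params or mask.params
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[params.connectivity])
    labels, n_components = ndimage.label(mask.data, structure=structure)

    cells: list[Cell] = []
    artefacts: list[Cell] = []
    if n_components:
        coords = np.argwhere(labels > 0)
        comp = labels[tuple(coords.T)]
        order = np.argsort(comp, kind="stable")
        coords = coords[order]
        comp = comp[order]
        boundaries = np.searchsorted(comp, np.arange(1, n_components + 2))
        for i in range(n_components):
            vox = coords[boundaries[i] : boundaries[i + 1]]
            cell = Cell(
                voxels=tuple(map(tuple, vox.tolist())),
                centroid=tuple(vox.mean(axis=0).tolist()),
            )
            if params.min_cluster_voxels <= len(vox) <= params.max_cluster_voxels:
                cells.append(cell)
            else:
                artefacts.append(cell)
    return CellSet(cells=tuple(cells), artefacts=tuple(artefacts), params=params)


def _round_half_down(x: float) -> int:
    """Component-wise centroid rounding, halves toward the lower index."""
    return int(np.ceil(x - 0.5))


def cells_to_counts(
    cells: CellSet,
    shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float],
) -> CountVolume:
    """Rasterize a cell set: one count at each cell's rounded centroid voxel."""
    counts = np.zeros(shape, dtype=np.int64)
    for cell in cells.cells:
        idx = tuple(_round_half_down(c) for c in cell.centroid)
        if any(i < 0 or i >= s for i, s in zip(idx, shape)):
            raise DomainError(f"cell centroid {cell.centroid} falls outside shape {shape}")
        counts[idx] += 1
    return CountVolume(counts, voxel_size)


def detect_cells(
    volume: Volume3D,
    mask: TissueMask | None = None,
    params: DetectionParams | None = None,
) -> CellSet:
    """Convenience: voxel detection followed by clustering."""
    params = params or DetectionParams()
    return find_cells(detect_fos_voxels(volume, mask, params), params)
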