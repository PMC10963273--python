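"""Core domain types for cleared-brain activity mapping.

Volumes are indexed ``(z, y, x)`` internally; this single fixed axis
convention is applied by all readers and writers (NIfTI stores ``(x, y, z)``
and is transposed on I/O, multi-page TIFF is already page-major ``(z, y, x)``).
Physical voxel sizes are carried in micrometres; densities are reported in
cells per microlitre (1 µl = 1e9 µm³).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import DomainError

#: conversion factor: cubic micrometres per microlitre
UM3_PER_UL = 1e9


def voxel_volume_ul(voxel_size: tuple[float, float, float]) -> float:
    """Physical volume of one voxel in microlitres.

    Parameters
    ----------
    voxel_size
        Edge lengths in µm, ``(z, y, x)`` order. All must be positive.

    Returns
    -------
    float
        ``prod(voxel_size) / 1e9``. A 25 µm isotropic voxel is
        ``1.5625e-5`` µl, so a 20×20×20-voxel counting window is 0.125 µl.
    """
    vs = tuple(float(v) for v in voxel_size)
    if len(vs) != 3:
        raise DomainError(f"voxel_size must have 3 components, got {len(vs)}")
    if any(not np.isfinite(v) or v <= 0 for v in vs):
        raise DomainError(f"voxel_size components must be positive and finite, got {vs}")
    return vs[0] * vs[1] * vs[2] / UM3_PER_UL


@dataclass(frozen=True)
class Volume3D:
    """Scalar intensity grid with physical voxel size.

    ``data`` is a 3-D array in arbitrary fluorescence units, indexed
    ``(z, y, x)``; ``voxel_size`` the matching edge lengths in µm.
    Every dimension must be at least 3 so that interior voxels have a full
    26-neighborhood; intensities must be finite.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (25.0, 25.0, 25.0)

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        object.__setattr__(self, "data", data)
        if data.ndim != 3:
            raise DomainError(f"volume must be 3-D, got ndim={data.ndim}")
        if min(data.shape) < 3:
            raise DomainError(
                f"every dimension must be >= 3 for a full interior neighborhood, got {data.shape}"
            )
        if not np.all(np.isfinite(data)):
            raise DomainError("volume intensities must be finite")
        voxel_volume_ul(self.voxel_size)  # validates positivity
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass(frozen=True)
class TissueMask:
    """Boolean grid marking voxels inside the brain tissue."""

    data: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.dtype != bool:
            if not np.isin(np.unique(data), (0, 1)).all():
                raise DomainError("tissue mask must be boolean or 0/1-valued")
            data = data.astype(bool)
        if data.ndim != 3:
            raise DomainError(f"tissue mask must be 3-D, got ndim={data.ndim}")
        object.__setattr__(self, "data", data)

    @classmethod
    def all_tissue(cls, shape: tuple[int, int, int]) -> "TissueMask":
        """Default mask: everything is tissue; boundary exclusion then
        applies only at the array edge."""
        return cls(np.ones(shape, dtype=bool))

    def check_shape(self, volume: Volume3D) -> None:
        if self.data.shape != volume.shape:
            raise DomainError(
                f"mask shape {self.data.shape} does not match volume shape {volume.shape}"
            )


@dataclass(frozen=True)
class LabelVolume:
    """Integer region labels over the grid; 0 is reserved for outside/unlabelled.

    ``label_table`` maps every nonzero label occurring in ``data`` to a
    region name (e.g. atlas structures such as NTS or PVH).
    """

    data: np.ndarray
    label_table: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise DomainError(f"label volume must be 3-D, got ndim={data.ndim}")
        if not np.issubdtype(data.dtype, np.integer):
            raise DomainError("label volume must hold integers")
        if data.min() < 0:
            raise DomainError("labels must be non-negative (0 = outside)")
        present = set(np.unique(data).tolist()) - {0}
        table = {int(k): str(v) for k, v in dict(self.label_table).items()}
        missing = present - set(table)
        if missing:
            raise DomainError(f"labels present in data but absent from label_table: {sorted(missing)}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "label_table", table)

    @property
    def labels(self) -> list[int]:
        return sorted(set(np.unique(self.data).tolist()) - {0})


@dataclass(frozen=True)
class CountVolume:
    """Cells-per-voxel counts; the bridge between detection and density."""

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (25.0, 25.0, 25.0)

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise DomainError(f"count volume must be 3-D, got ndim={data.ndim}")
        if not np.issubdtype(data.dtype, np.integer):
            raise DomainError("count volume must hold integers")
        if data.min() < 0:
            raise DomainError("counts must be non-negative")
        voxel_volume_ul(self.voxel_size)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))

    @property
    def total(self) -> int:
        return int(self.data.sum())


@dataclass(frozen=True)
class DetectionParams:
    """Parameters of the ratio-based local-maximum detector.

    A voxel is a Fos candidate when its value exceeds its 26 neighbors
    (the 3×3×3 cube minus the center) by at least ``threshold_fraction``
    (default 20%), either against every neighbor (default) or against the
    neighbor mean. Candidate clusters of ``min_cluster_voxels`` to
    ``max_cluster_voxels`` voxels (default 1–8) count as one cell; larger
    clusters are artefacts.
    """

    threshold_fraction: float = 0.20
    comparison_mode: str = "each-neighbor"  # or "mean-of-neighbors"
    min_cluster_voxels: int = 1
    max_cluster_voxels: int = 8
    connectivity: int = 26  # 6 | 18 | 26

    def __post_init__(self) -> None:
        if not self.threshold_fraction > 0:
            raise DomainError("threshold_fraction must be > 0")
        if self.comparison_mode not in ("each-neighbor", "mean-of-neighbors"):
            raise DomainError(f"unknown comparison_mode {self.comparison_mode!r}")
        if not (1 <= self.min_cluster_voxels <= self.max_cluster_voxels):
            raise DomainError("need 1 <= min_cluster_voxels <= max_cluster_voxels")
        if self.connectivity not in (6, 18, 26):
            raise DomainError(f"connectivity must be 6, 18 or 26, got {self.connectivity}")


#: the 26 offsets of the 3×3×3 neighborhood minus the center
NEIGHBOR_OFFSETS_26: tuple[tuple[int, int, int], ...] = tuple(
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
)


@dataclass(frozen=True)
class DensityParams:
    """Uniform counting-window parameters for the local density map.

    ``kernel_extent`` voxels per axis (default 20); at the canonical 25 µm
    isotropic resolution the window volume is 20³ × 25³ µm³ = 0.125 µl and
    densities come out in cells per microlitre.
    """

    kernel_extent: int = 20

    def __post_init__(self) -> None:
        if int(self.kernel_extent) != self.kernel_extent or self.kernel_extent < 1:
            raise DomainError("kernel_extent must be an integer >= 1")
        object.__setattr__(self, "kernel_extent", int(self.kernel_extent))

    def window_volume_ul(self, voxel_size: tuple[float, float, float]) -> float:
        """Physical volume of the counting window in µl."""
        return self.kernel_extent**3 * voxel_volume_ul(voxel_size)
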