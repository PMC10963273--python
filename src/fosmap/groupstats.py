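"""Local density maps and voxelwise group statistics.

The density step slides a uniform ``kernel_extent``³ counting window over
the cells-per-voxel grid and divides by the window's physical volume, giving
cells per microlitre (0.125 µl for the canonical 20³ window of 25 µm
voxels). The even default extent has no exact center; the window spans
offsets [−extent/2, extent/2 − 1] per axis, a fixed convention. At the
array edge the window is zero-padded and still normalized by the full
window volume, so densities are biased low within one kernel width of the
edge — a deliberate, documented choice matching a plain uniform
convolution.

Group comparison is a per-voxel two-sample t-test (Student pooled-variance
by default, Welch optional), two-sided, between two groups of density maps.
Voxels where both groups have zero variance and equal means carry no
information; they are marked undefined in a validity mask rather than given
an arbitrary p.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .core import CountVolume, DensityParams, LabelVolume
from .errors import DomainError


@dataclass(frozen=True)
class DensityMap:
    """Per-voxel local Fos⁺ cell density in cells per microlitre."""

    data: np.ndarray
    params: DensityParams
    voxel_size: tuple[float, float, float]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass(frozen=True)
class StatMap:
    """Voxelwise two-sample t statistic and two-sided p-value map.

    ``p`` is NaN and ``defined`` False where both groups had zero variance
    and equal means (typically empty voxels in every animal).
    """

    t: np.ndarray
    p: np.ndarray
    defined: np.ndarray
    n_a: int
    n_b: int
    variant: str = "student"
    sidedness: str = "two-sided"


def local_density(counts: CountVolume, params: DensityParams | None = None) -> DensityMap:
    """Uniform-kernel local density in cells/µl.

    Each output voxel is the count sum inside the centered
    ``kernel_extent``³ window divided by the window's physical volume
    (zero-padded, full-volume normalization at edges).
    """
    params = params or DensityParams()
    k = params.kernel_extent
    if any(s < k for s in counts.data.shape):
        raise DomainError(
            f"kernel extent {k} exceeds volume shape {counts.data.shape}"
        )
    # uniform_filter computes the window mean over k^3 positions with zero
    # padding; multiply back to a sum, then divide by the window volume.
    window_mean = ndimage.uniform_filter(
        counts.data.astype(np.float64), size=k, mode="constant", cval=0.0
    )
    window_sum = window_mean * float(k**3)
    density = window_sum / params.window_volume_ul(counts.voxel_size)
    np.clip(density, 0.0, None, out=density)  # guard tiny negative rounding
    return DensityMap(data=density, params=params, voxel_size=counts.voxel_size)


def voxelwise_ttest(
    group_a: list[DensityMap],
    group_b: list[DensityMap],
    variant: str = "student",
) -> StatMap:
    """Two-sample t-test at every voxel between two groups of density maps.

    Requires at least two maps per group with identical shapes and kernel
    parameters. ``variant`` is ``student`` (pooled variance) or ``welch``.
    """
    if variant not in ("student", "welch"):
        raise DomainError(f"unknown t-test variant {variant!r}")
    if len(group_a) < 2 or len(group_b) < 2:
        raise DomainError("need at least 2 density maps per group")
    ref = group_a[0]
    for m in [*group_a, *group_b]:
        if m.shape != ref.shape:
            raise DomainError("density maps differ in shape")
        if m.params.kernel_extent != ref.params.kernel_extent:
            raise DomainError("density maps computed with different kernels")

    a = np.stack([m.data for m in group_a]).astype(np.float64)
    b = np.stack([m.data for m in group_b]).astype(np.float64)
    na, nb = a.shape[0], b.shape[0]
    mean_a, mean_b = a.mean(axis=0), b.mean(axis=0)
    var_a = a.var(axis=0, ddof=1)
    var_b = b.var(axis=0, ddof=1)
    diff = mean_a - mean_b

    both_flat = (var_a == 0) & (var_b == 0)
    undefined = both_flat & (diff == 0)

    with np.errstate(divide="ignore", invalid="ignore"):
        if variant == "student":
            pooled = ((na - 1) * var_a + (nb - 1) * var_b) / (na + nb - 2)
            se = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
            df = np.full(ref.shape, float(na + nb - 2))
        else:
            sa, sb = var_a / na, var_b / nb
            se = np.sqrt(sa + sb)
            df = (sa + sb) ** 2 / (
                sa**2 / (na - 1) + sb**2 / (nb - 1)
            )
        t = diff / se
        # zero variance, unequal means: infinite evidence -> p = 0
        t = np.where(both_flat & (diff != 0), np.sign(diff) * np.inf, t)
        t = np.where(undefined, 0.0, t)
    df = np.where(np.isfinite(df), df, float(na + nb - 2))

    p = np.full(ref.shape, np.nan)
    valid = ~undefined
    with np.errstate(invalid="ignore"):
        p[valid] = 2.0 * stats.t.sf(np.abs(t[valid]), df[valid])
    p[valid & np.isinf(t)] = 0.0
    return StatMap(t=t, p=p, defined=valid, n_a=na, n_b=nb, variant=variant)


def bh_significance_mask(stat: StatMap, q: float = 0.05) -> np.ndarray:
    """Optional Benjamini–Hochberg mask over the defined voxels.

    An exploratory extension: the base output is the raw p-value map.
    """
    from statsmodels.stats.multitest import multipletests

    mask = np.zeros(stat.p.shape, dtype=bool)
    pv = stat.p[stat.defined]
    if pv.size:
        rejected = multipletests(pv, alpha=q, method="fdr_bh")[0]
        mask[stat.defined] = rejected
    return mask


def summarize_regions(
    map_: "DensityMap | StatMap",
    labels: LabelVolume,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-region summaries of a density or statistic map.

    For a ``StatMap``: voxel count, mean and minimum p over defined voxels,
    and the fraction of defined voxels with p < ``alpha``. For a
    ``DensityMap``: voxel count and mean density. Label 0 (outside) is
    skipped; rows are ordered by label.
    """
    if isinstance(map_, DensityMap):
        grid_shape = map_.shape
    elif isinstance(map_, StatMap):
        grid_shape = map_.p.shape
    else:
        raise DomainError(f"unsupported map type {type(map_).__name__}")
    if labels.data.shape != grid_shape:
        raise DomainError(
            f"label shape {labels.data.shape} does not match map shape {grid_shape}"
        )

    rows = []
    for label in labels.labels:
        region = labels.data == label
        row: dict = {
            "label": label,
            "name": labels.label_table.get(label, str(label)),
            "n_voxels": int(region.sum()),
        }
        if isinstance(map_, DensityMap):
            row["mean_density"] = float(map_.data[region].mean()) if region.any() else np.nan
        else:
            sel = region & map_.defined
            n_def = int(sel.sum())
            row["n_defined"] = n_def
            row["mean_p"] = float(map_.p[sel].mean()) if n_def else np.nan
            row["min_p"] = float(map_.p[sel].min()) if n_def else np.nan
            row["frac_significant"] = (
                float((map_.p[sel] < alpha).mean()) if n_def else np.nan
            )
            row["alpha"] = alpha
        rows.append(row)
    columns = ["label", "name", "n_voxels"] + (
        ["mean_density"]
        if isinstance(map_, DensityMap)
        else ["n_defined", "mean_p", "min_p", "frac_significant", "alpha"]
    )
    return pd.DataFrame(rows, columns=columns)
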