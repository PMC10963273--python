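#!/usr/bin/env python
"""Voxelwise two-sample t-test between the two simulated groups.

Reads the density maps from 02_detect_and_map.py, computes the Student
(pooled-variance) t and two-sided p at every voxel, writes the p-value map
and a per-region summary table, and reports which region carries the
planted effect.
"""

import argparse
import glob

import numpy as np

from fosmap import io as fio
from fosmap.core import DensityParams, Volume3D
from fosmap.groupstats import DensityMap, summarize_regions, voxelwise_ttest


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--maps", default="results/maps")
    parser.add_argument("--cohort", default="results/cohort")
    parser.add_argument("--alpha", type=float, default=0.05)
    parser.add_argument("--out", default="results/comparison")
    args = parser.parse_args()

    params = DensityParams()

    def load_group(g):
        paths = sorted(glob.glob(f"{args.maps}/group_{g}_*_density.nii.gz"))
        maps = []
        for p in paths:
            vol = fio.read_volume(p)
            maps.append(DensityMap(vol.data, params, vol.voxel_size))
        return maps

    group_a, group_b = load_group("a"), load_group("b")
    if len(group_a) < 2 or len(group_b) < 2:
        raise SystemExit("need the density maps from 02_detect_and_map.py")
    stat = voxelwise_ttest(group_a, group_b, variant="student")

    import os

    os.makedirs(args.out, exist_ok=True)
    vs = (25.0, 25.0, 25.0)
    fio.write_volume(Volume3D(np.nan_to_num(stat.p, nan=1.0), vs), f"{args.out}/pmap.nii.gz")
    labels = fio.read_labels(f"{args.cohort}/labels.nii.gz", f"{args.cohort}/labels.tsv")
    table = summarize_regions(stat, labels, alpha=args.alpha)
    fio.write_table(table, f"{args.out}/regions.tsv")

    print(f"defined voxels: {int(stat.defined.sum())} of {stat.p.size}")
    print(table.to_string(index=False))
    best = table.loc[table["mean_p"].idxmin()]
    print(f"lowest mean p: region {int(best['label'])} ({best['name']}), "
          f"mean p = {best['mean_p']:.2e}, "
          f"{100 * best['frac_significant']:.0f}% of voxels below alpha={args.alpha}")
    print(f"-> {args.out}/")


if __name__ == "__main__":
    main()
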