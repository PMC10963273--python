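# Methods

## Fos⁺ cell detection

Volumes are scalar intensity grids indexed `(z, y, x)` with physical voxel
sizes in µm (canonically 25 µm isotropic). A voxel `v` is rated
Fos-positive iff

* its full 26-neighborhood (the 3×3×3 cube minus the center) exists and
  lies inside the tissue mask — voxels at the array edge or adjacent to
  non-tissue are never candidates, which suppresses surface artefacts; and
* `I(v) ≥ (1 + f)·I(u)` **and** `I(v) > I(u)` for every neighbor `u`,
  with threshold fraction `f = 0.20` by default.

The comparison against *every* neighbor makes the detector a strict local
maximum test with a 20% margin. Consequences worth knowing:

* **Scale invariance, offset sensitivity.** The rule is a ratio: global
  rescaling of intensities changes nothing, but adding a constant offset
  dilutes the relative excess. Background subtraction is deliberately out
  of scope; inputs are assumed offset-free fluorescence.
* **The strict `>` conjunct** only matters on exactly-zero background,
  where `v ≥ 1.2·0` would otherwise hold vacuously and flag flat empty
  space.
* **Exact 20% counts.** The threshold is inclusive (`≥`), read as a
  minimum attained requirement.
* **Plateaus are invisible.** Two adjacent voxels of equal elevated
  intensity suppress each other; multi-voxel clusters of detections arise
  in practice from noise-broken plateaus, not from uniformly bright
  blobs. A `mean-of-neighbors` comparison mode (margin over the
  neighborhood mean) is provided as the alternative reading; it is not
  the default and the cluster stage is identical under both.

Detected voxels are grouped by connected components (26-connectivity by
default, matching the neighborhood; 6 and 18 available). Components of
1–8 voxels count as one cell; larger components are recorded as artefacts
and excluded. Centroids are unweighted voxel-coordinate means; when
rasterized back to a count grid each cell contributes one count at its
centroid voxel, with half-coordinates rounded toward the lower index (a
fixed tie-break).

## Local density and group statistics

The density map convolves the cells-per-voxel grid with a uniform
`k³` counting window (`k = 20`) and divides by the window's physical
volume `k³ ·` voxel volume — 0.125 µl at 25 µm isotropic — yielding
cells/µl. Numerical conventions:

* **Even kernel centering.** `k = 20` has no central voxel; the window
  spans offsets `[−10, +9]` per axis. Any consistent choice shifts the
  map by at most one voxel.
* **Edges.** Windows are zero-padded and always normalized by the full
  0.125 µl, so density is biased low within one kernel width of the array
  edge. This matches a plain uniform convolution; for interior cells the
  map conserves mass exactly (Σ density × voxel volume = cell count, to
  ~1e-15 relative in practice, asserted at 1e-9).

Group comparison is a per-voxel two-sample t-test between ≥ 2 density
maps per group: Student pooled-variance by default (chosen for the tiny
group sizes this design uses, n = 4 per group), Welch optional, two-sided
only. Voxels where both groups have zero variance and equal means carry no
information; they get `t = 0` and NaN p plus `defined = False` in a
validity mask — never a silent `p = 1`. Zero variance with unequal means
yields `p = 0` (infinite evidence under the model). No multiplicity
correction is applied to the p map by default — the intended readout is
the p-value image itself; an optional Benjamini–Hochberg mask
(`bh_significance_mask`) is provided as a clearly-labelled extension.

**Empirical size.** Monte-Carlo calibration on 600 null cohorts
(4 vs 4 animals, matched densities, full simulate→detect→density→test
pipeline) measures the fraction of defined voxels with p < 0.05 at
0.0522 ± 0.0009: the pooled t at n = 4 on count-derived, spatially
smoothed maps is very slightly anti-conservative. This is a property of
the t-test at such sample sizes, documented rather than corrected; the
acceptance suite checks the size is within Monte-Carlo resolution
(±2 SE over 200 replicates) of the nominal 5%.

## Synthetic cleared-brain volumes

The generator emulates the statistical structure the detector assumes,
not the optics: a smooth multiplicative background field (trilinear
interpolation of a coarse Gaussian grid, relative SD 0.05, around level
100) plus white Gaussian noise (SD 5 by default), with cells planted by a
per-region Poisson process at configurable densities (default 40 cells/µl
— a realistic local Fos⁺ density in activated hindbrain regions at this
resolution, ≈ 5 cells per counting window). Region geometry is
deterministic slabs inside a 2-voxel margin. Each cell is a 26-connected
cluster grown by random neighbor accretion; every cell voxel is set to
`(1 + m)·` the local background maximum before noise (`m = 0.4`, i.e.
double the detection threshold), so an isolated interior cell is a
guaranteed detection at zero noise.

Two honest limitations are built in rather than hidden:

* **Collisions.** Cell placements are independent; cells may be adjacent
  or overlap, producing plateaus the peak rule cannot resolve. Noiseless
  recall is therefore 100% for *isolated* planted cells and slightly
  below overall (≈ 97% at 60 cells/µl). No exclusion zone is enforced.
* **Default single-voxel cells.** Because plateaus are invisible to the
  all-neighbor rule, the canonical fixture plants single-voxel cells;
  multi-voxel sizes (up to the 8-voxel cap) are available to exercise the
  cluster/artefact logic.

Not modelled: PSF, attenuation, stripe artefacts, registration error,
intensity inhomogeneity beyond the smooth field. Passing tests therefore
demonstrate the *algorithmic* contract (detection geometry, density
physics, statistical calibration), not robustness to real optical
artefacts.

Cohorts derive per-animal seeds by spawning a `SeedSequence` on the base
seed; groups differ only in designated regions' densities.

## Synthetic snRNA-seq counts

Gamma–Poisson (negative-binomial) counts with overdispersion φ = 0.1
(`var = µ + φµ²`). Defaults mirror the experimental design the scorer
targets: 2 conditions × 2 samples, 6 clusters × 400 cells balanced across
samples, 2000 genes — enough for realistic detected-gene counts
(median ≈ 1300 at 2k–10k UMIs) under the ≥ 500-gene QC rule — including
the 10-IEG panel (kept moderately expressed so the 5% detection filter is
attainable) and 5 mitochondrial genes whose per-cell share is tuned to a
target fraction drawn from 1–5%. Cluster identity upregulates a random 5%
marker-gene set 2–8-fold. The planted condition effect multiplies panel
genes by `2^±1.5` in stimulated cells of designated activated/inhibited
clusters; everything else is null. Per-cell library sizes are uniform on
2,000–10,000 before NB noise.

Not modelled: sample-level random effects beyond the label (the real
experiment pooled two animals per sample — whether pooling adds variance
components is left open), ambient RNA, doublets, batch effects.

## IEG activation scoring

QC removal bounds are exclusive as worded ("fewer than 800", "above
10%"): a cell with exactly 800 UMIs, 500 genes and 10.0% mitochondrial
reads is retained.

The DE stage is a pluggable interface (`cluster, gene, p_raw, p_adjusted,
log2fc, frac_expressing`). The analysis this package descends from used a
negative-binomial mixed model with sample-level effects; that model is
not re-implemented. Shipped producers:

* `pseudobulk_t` (preferred): per-sample mean of depth-normalized
  expression (counts per 10k; totals always over the full gene set, so
  subsetting genes cannot distort depth), Student t across samples. With
  2 samples per condition this has 2 df — low power per gene, which is
  exactly the regime the Fisher combination is designed to aggregate.
* `percell_wilcoxon`: rank-sum over individual cells. Anti-conservative
  (cells within a sample are not independent); exploration only.

Log2 fold changes use a pseudocount of 0.01 on the per-condition means of
normalized expression. Holm–Bonferroni adjustment is applied within each
cluster and carried in the table; **the score uses raw p-values** — the
IEG signal is weak and the score is a ranking device, at the documented
cost of retaining false positives.

Per cluster: usable IEGs are panel genes with `frac_expressing ≥ 0.05`
(inclusive) and `p_raw < 0.05` (strict). None ⇒ score exactly 0 (never a
small residue). Otherwise Fisher's statistic `X = −2 Σ ln pᵢ ~ χ²₂ₖ`
gives a combined p, and

```
score = sign · (−log₁₀ combined_p),   sign = −1 iff mean log2FC of usable IEGs < 0
```

The phrase "negative logarithm of the chi-squared test statistic" admits
a literal reading, `−log₁₀ X`, which *decreases* with stronger evidence;
the default here is `−log₁₀ combined_p`, which behaves as an activation
score should, and the literal mode is available as
`score_mode="neglog_chi2_statistic"`. The mean log2FC is averaged over
the same filtered IEG set used in the combination. Base 10 throughout.
`p = 0` underflow from a DE producer is clamped to the smallest positive
double with a warning before logs.

Ranking is by descending score with ties broken by ascending combined p,
then cluster id (the all-zero case thus orders by id — arbitrary but
stable); the top 4 are reported by default.

## Problem sizes and numerical choices

Desk-scale defaults throughout: 48³ simulated volumes (the canonical
registered grid is 440×320×520; all algorithms are resolution-agnostic),
200 Monte-Carlo replicates for null calibration, 50 for power and
recovery experiments — sizes at which every documented property is
measurable in minutes on one CPU. Detection uses array shifts (wrap-around
entries never reach candidates, which exclude the edge); connected
components and the uniform window come from `scipy.ndimage`; t statistics
are computed in closed form and cross-checked against `scipy.stats`.
Seeds: every generator is a pure function of its spec including the seed;
multi-run experiments spawn child seeds via `numpy.random.SeedSequence`;
pipeline stages use `SeedSequence([seed, stage_counter])`.

## Known limitations

* The imaging arm consumes *registered* volumes; registration quality is
  assumed, not assessed.
* Density near array/tissue edges is biased low by design (full-volume
  normalization).
* The voxelwise test is uncorrected for multiplicity by default and
  slightly anti-conservative at n = 4 (see above).
* The pseudobulk DE producer with 2 samples per condition has 2 df per
  gene; single-gene p-values are noisy and only meaningful in aggregate.
* The score's raw-p design favours sensitivity over specificity; null
  clusters can receive nonzero scores by chance (observed in practice),
  so ranked candidates require downstream validation.
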