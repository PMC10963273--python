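"""Seeded negative-binomial snRNA-seq simulator with planted IEG effects.

Emulates the design of the hindbrain single-nucleus experiment the IEG
scorer was built for: two conditions (control vs stimulated), two samples
per condition, cells partitioned into clusters, and a panel of immediate
early genes whose expression in designated "activated" clusters is shifted
by a known log2 fold change in stimulated cells (mirrored negatively in
"inhibited" clusters). Counts are negative-binomial (gamma–Poisson) with a
shared overdispersion; per-cell library sizes and mitochondrial fractions
are drawn from configurable ranges so the QC stage has something real to
filter.

Not modelled: sample-level random effects beyond the sample labels (the
real data pooled two animals per sample), ambient RNA, or doublets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

from .errors import ConfigurationError

#: the ten-gene immediate-early-gene panel used for activation scoring
DEFAULT_IEG_PANEL: tuple[str, ...] = (
    "Fos",
    "Fosl2",
    "Homer1",
    "Nr4a3",
    "Nr4a1",
    "Gem",
    "Jun",
    "Junb",
    "Btg1",
    "1700016P03Rik",
)

_MITO_GENES: tuple[str, ...] = ("mt-Nd1", "mt-Nd2", "mt-Co1", "mt-Co2", "mt-Cytb")


@dataclass(frozen=True)
class SnRnaSimSpec:
    """Parameters of one simulated snRNA-seq count matrix.

    ``dispersion`` is the negative-binomial overdispersion φ in
    ``var = µ + φ µ²`` (φ → 0 recovers Poisson). ``ieg_log2fc`` is the
    planted stimulated-vs-control log2 fold change of panel genes in
    ``activated_clusters`` (negated in ``inhibited_clusters``); all other
    (cluster, gene) combinations are null.
    """

    n_genes: int = 2000
    n_cells: int = 2400
    n_clusters: int = 6
    samples_per_condition: int = 2
    ieg_panel: tuple[str, ...] = DEFAULT_IEG_PANEL
    activated_clusters: frozenset[int] = frozenset({1})
    inhibited_clusters: frozenset[int] = frozenset({2})
    ieg_log2fc: float = 1.5
    dispersion: float = 0.1
    library_size_range: tuple[int, int] = (2000, 10000)
    mito_fraction_range: tuple[float, float] = (0.01, 0.05)
    gene_names: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        panel = tuple(self.ieg_panel)
        if not panel:
            raise ConfigurationError("ieg_panel must be non-empty")
        if self.n_genes < len(panel) + len(_MITO_GENES) + 1:
            raise ConfigurationError(
                f"n_genes={self.n_genes} too small for panel plus mitochondrial genes"
            )
        if self.n_clusters < 1 or self.n_cells < self.n_clusters:
            raise ConfigurationError("need at least one cell per cluster")
        if self.samples_per_condition < 1:
            raise ConfigurationError("samples_per_condition must be >= 1")
        act = frozenset(int(c) for c in self.activated_clusters)
        inh = frozenset(int(c) for c in self.inhibited_clusters)
        valid = set(range(self.n_clusters))
        if not act <= valid or not inh <= valid:
            raise ConfigurationError(
                "activated/inhibited cluster ids must be in "
                f"[0, {self.n_clusters}), got {sorted((act | inh) - valid)}"
            )
        if act & inh:
            raise ConfigurationError(
                f"clusters cannot be both activated and inhibited: {sorted(act & inh)}"
            )
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be > 0")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ConfigurationError("library_size_range must satisfy 0 < lo <= hi")
        mlo, mhi = self.mito_fraction_range
        if not (0 <= mlo <= mhi < 1):
            raise ConfigurationError("mito_fraction_range must lie in [0, 1)")
        if self.gene_names is not None:
            names = tuple(str(g) for g in self.gene_names)
            if len(names) != self.n_genes:
                raise ConfigurationError(
                    f"gene_names has {len(names)} entries, expected n_genes={self.n_genes}"
                )
            missing = [g for g in panel if g not in names]
            if missing:
                raise ConfigurationError(
                    f"ieg_panel genes absent from gene_names: {missing}"
                )
            object.__setattr__(self, "gene_names", names)
        object.__setattr__(self, "ieg_panel", panel)
        object.__setattr__(self, "activated_clusters", act)
        object.__setattr__(self, "inhibited_clusters", inh)


def _default_gene_names(spec: SnRnaSimSpec) -> tuple[str, ...]:
    n_filler = spec.n_genes - len(spec.ieg_panel) - len(_MITO_GENES)
    filler = tuple(f"Gene{i:04d}" for i in range(n_filler))
    return spec.ieg_panel + _MITO_GENES + filler


def generate_snrnaseq(spec: SnRnaSimSpec) -> tuple[ad.AnnData, pd.DataFrame]:
    """Simulate a count matrix plus its ground-truth effect table.

    Returns an :class:`anndata.AnnData` (cells × genes, integer counts in
    ``X``) whose ``obs`` carries ``sample``, ``condition``, ``cluster`` and
    the measured QC metrics (``umi_count``, ``gene_count``,
    ``mito_fraction``), and a tidy DataFrame of the planted per-(cluster,
    panel-gene) log2 fold changes. Identical specs give identical output.
    """
    rng = np.random.default_rng(spec.seed)
    genes = list(spec.gene_names) if spec.gene_names is not None else list(
        _default_gene_names(spec)
    )
    gene_idx = {g: i for i, g in enumerate(genes)}
    panel_idx = np.array([gene_idx[g] for g in spec.ieg_panel])
    mito_idx = np.array(
        [i for i, g in enumerate(genes) if g.lower().startswith("mt-")], dtype=int
    )
    other_idx = np.setdiff1d(np.arange(spec.n_genes), mito_idx)

    # relative expression levels; panel genes kept moderately expressed so
    # the 5%-of-cells detection filter is attainable at realistic depth
    rel = np.zeros(spec.n_genes)
    rel[other_idx] = rng.lognormal(mean=0.0, sigma=1.2, size=other_idx.size)
    rel[panel_idx] = rng.lognormal(mean=0.5, sigma=0.3, size=panel_idx.size)
    rel[mito_idx] = rng.lognormal(mean=0.0, sigma=0.3, size=mito_idx.size)

    # cluster structure: each cluster upregulates a random set of marker genes
    cluster_mult = np.ones((spec.n_clusters, spec.n_genes))
    marker_pool = np.setdiff1d(other_idx, panel_idx)
    n_markers = max(1, int(0.05 * marker_pool.size))
    for k in range(spec.n_clusters):
        markers = rng.choice(marker_pool, size=n_markers, replace=False)
        cluster_mult[k, markers] = 2.0 ** rng.uniform(1.0, 3.0, size=n_markers)

    # cell annotations: equal cluster sizes, conditions and samples balanced
    # within every cluster
    clusters = np.arange(spec.n_cells) % spec.n_clusters
    conditions = np.empty(spec.n_cells, dtype=object)
    samples = np.empty(spec.n_cells, dtype=object)
    for k in range(spec.n_clusters):
        idx = np.flatnonzero(clusters == k)
        for j, cell in enumerate(idx):
            cond = "control" if j % 2 == 0 else "stimulated"
            rep = (j // 2) % spec.samples_per_condition + 1
            conditions[cell] = cond
            samples[cell] = f"{cond}_{rep}"

    # condition effect on panel genes in designated clusters
    cond_mult = np.ones((spec.n_clusters, spec.n_genes))
    for k in spec.activated_clusters:
        cond_mult[k, panel_idx] = 2.0**spec.ieg_log2fc
    for k in spec.inhibited_clusters:
        cond_mult[k, panel_idx] = 2.0**-spec.ieg_log2fc

    lib = rng.uniform(*spec.library_size_range, size=spec.n_cells)
    mito_frac_target = rng.uniform(*spec.mito_fraction_range, size=spec.n_cells)

    stim = conditions == "stimulated"
    mu = np.empty((spec.n_cells, spec.n_genes))
    for k in range(spec.n_clusters):
        sel = clusters == k
        base = rel * cluster_mult[k]
        mu[sel] = base
        mu[sel & stim] = base * cond_mult[k]
    # split each cell's expected library between mitochondrial and nuclear genes
    mito_w = mu[:, mito_idx].sum(axis=1)
    other_w = mu[:, other_idx].sum(axis=1)
    mu[:, mito_idx] *= (mito_frac_target * lib / mito_w)[:, None]
    mu[:, other_idx] *= ((1.0 - mito_frac_target) * lib / other_w)[:, None]

    theta = 1.0 / spec.dispersion
    lam = rng.gamma(shape=theta, scale=mu / theta)
    counts = rng.poisson(lam).astype(np.int32)

    obs = pd.DataFrame(
        {
            "sample": pd.Categorical(samples),
            "condition": pd.Categorical(conditions, categories=["control", "stimulated"]),
            "cluster": pd.Categorical(clusters.astype(str), categories=[str(k) for k in range(spec.n_clusters)]),
        },
        index=[f"cell{i:05d}" for i in range(spec.n_cells)],
    )
    obs["umi_count"] = counts.sum(axis=1)
    obs["gene_count"] = (counts > 0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        obs["mito_fraction"] = np.where(
            obs["umi_count"] > 0, counts[:, mito_idx].sum(axis=1) / obs["umi_count"], 0.0
        )

    adata = ad.AnnData(
        X=sparse.csr_matrix(counts),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )

    effect_rows = []
    for k in range(spec.n_clusters):
        if k in spec.activated_clusters:
            lfc = spec.ieg_log2fc
        elif k in spec.inhibited_clusters:
            lfc = -spec.ieg_log2fc
        else:
            lfc = 0.0
        for g in spec.ieg_panel:
            effect_rows.append({"cluster": str(k), "gene": g, "true_log2fc": lfc})
    effects = pd.DataFrame(effect_rows, columns=["cluster", "gene", "true_log2fc"])
    return adata, effects


def write_snrnaseq(adata: ad.AnnData, out_dir: str) -> dict[str, str]:
    """Write MatrixMarket counts (genes × cells) plus TSV sidecars."""
    import os

    from scipy.io import mmwrite

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "matrix": os.path.join(out_dir, "matrix.mtx"),
        "genes": os.path.join(out_dir, "genes.tsv"),
        "barcodes": os.path.join(out_dir, "barcodes.tsv"),
        "meta": os.path.join(out_dir, "meta.tsv"),
    }
    mmwrite(paths["matrix"], sparse.csc_matrix(adata.X.T))
    pd.Series(adata.var_names).to_csv(paths["genes"], sep="\t", index=False, header=False)
    pd.Series(adata.obs_names).to_csv(paths["barcodes"], sep="\t", index=False, header=False)
    adata.obs.reset_index(names="cell").to_csv(paths["meta"], sep="\t", index=False)
    return paths


def read_snrnaseq(matrix: str, genes: str, barcodes: str, meta: str) -> ad.AnnData:
    """Read counts written by :func:`write_snrnaseq` (or Cell Ranger-style trios)."""
    from scipy.io import mmread

    X = sparse.csr_matrix(mmread(matrix).T)
    gene_names = pd.read_csv(genes, sep="\t", header=None)[0].astype(str)
    cell_names = pd.read_csv(barcodes, sep="\t", header=None)[0].astype(str)
    obs = pd.read_csv(meta, sep="\t").set_index("cell").loc[cell_names]
    adata = ad.AnnData(
        X=X, obs=obs, var=pd.DataFrame(index=pd.Index(gene_names, name="gene"))
    )
    return adata
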