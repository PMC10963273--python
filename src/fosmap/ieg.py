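"""IEG activation scoring for snRNA-seq neuronal clusters.

The score summarizes, per cluster, how strongly a ten-gene immediate-early
gene (IEG) panel responds to a stimulation condition. For each cluster the
raw per-gene p-values of a differential-expression (DE) test are filtered
to panel genes expressed in at least 5% of the cluster's cells with raw
p < 0.05, combined by Fisher's method (−2 Σ ln pᵢ ~ χ² with 2k df), and
reported as −log₁₀ of the combined p, with the sign flipped to negative
when the mean log2 fold change of the contributing IEGs is negative
(potential inhibition) and set to exactly 0 when no IEG survives the
filters. Raw rather than multiplicity-adjusted p-values feed the score —
the IEG signal in this setting is weak, and the score is a ranking device,
not a test; Holm–Bonferroni-adjusted values are carried alongside for
reference.

The DE producer is pluggable behind the DE-table interface. The original
analysis used a negative-binomial mixed model with sample-level effects
(nebula); re-implementing that model is out of scope here, so two reference
producers ship: a pseudobulk t-test on per-sample mean expression
(preferred — it respects the two-samples-per-condition replication) and a
per-cell Wilcoxon rank-sum test (anti-conservative, since cells within a
sample are not independent; use for exploration only).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, stats
from statsmodels.stats.multitest import multipletests

from .errors import DomainError
from .sim_counts import DEFAULT_IEG_PANEL

logger = logging.getLogger(__name__)

_TINY_P = np.finfo(float).tiny  # clamp for p-value underflow


@dataclass(frozen=True)
class QCParams:
    """Cell-level quality-control thresholds.

    A cell is retained iff it has at least ``min_umis`` UMIs, at least
    ``min_genes`` detected genes and a mitochondrial read fraction of at
    most ``max_mito_fraction`` — i.e. removal bounds ("fewer than 800",
    "above 10%") are exclusive.
    """

    min_umis: int = 800
    min_genes: int = 500
    max_mito_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.min_umis < 0 or self.min_genes < 0:
            raise DomainError("QC count thresholds must be >= 0")
        if not 0 <= self.max_mito_fraction <= 1:
            raise DomainError("max_mito_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class ScoreParams:
    """Configuration of the IEG activation score."""

    ieg_panel: tuple[str, ...] = DEFAULT_IEG_PANEL
    min_frac: float = 0.05
    alpha: float = 0.05
    score_mode: str = "neglog_combined_p"  # or "neglog_chi2_statistic"

    def __post_init__(self) -> None:
        if not self.ieg_panel:
            raise DomainError("ieg_panel must be non-empty")
        if not 0 < self.alpha < 1:
            raise DomainError("alpha must lie in (0, 1)")
        if not 0 <= self.min_frac <= 1:
            raise DomainError("min_frac must lie in [0, 1]")
        if self.score_mode not in ("neglog_combined_p", "neglog_chi2_statistic"):
            raise DomainError(f"unknown score_mode {self.score_mode!r}")
        object.__setattr__(self, "ieg_panel", tuple(self.ieg_panel))


def qc_filter_cells(cell_metrics: pd.DataFrame, params: QCParams | None = None) -> pd.Index:
    """Apply the UMI / gene-count / mitochondrial-fraction filters.

    ``cell_metrics`` needs columns ``cell``, ``umi_count``, ``gene_count``,
    ``mito_fraction`` (or an index of cell ids). Returns the retained cell
    ids in input order.
    """
    params = params or QCParams()
    df = cell_metrics
    required = {"umi_count", "gene_count", "mito_fraction"}
    missing = required - set(df.columns)
    if missing:
        raise DomainError(f"cell metrics missing columns: {sorted(missing)}")
    ids = df["cell"] if "cell" in df.columns else df.index.to_series()
    for col in required:
        vals = df[col].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise DomainError(f"non-finite values in {col}")
    if (df["umi_count"] < 0).any() or (df["gene_count"] < 0).any():
        raise DomainError("negative counts in cell metrics")
    if ((df["mito_fraction"] < 0) | (df["mito_fraction"] > 1)).any():
        raise DomainError("mito_fraction outside [0, 1]")
    keep = (
        (df["umi_count"] >= params.min_umis)
        & (df["gene_count"] >= params.min_genes)
        & (df["mito_fraction"] <= params.max_mito_fraction)
    )
    return pd.Index(ids[keep.to_numpy()])


def holm_bonferroni(p: "np.ndarray | list[float]") -> np.ndarray:
    """Holm–Bonferroni step-down adjustment, input order preserved."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0) or np.any(arr > 1):
        raise DomainError("p-values must lie in (0, 1]")
    return multipletests(arr, method="holm")[1]


def fisher_combine(p: "np.ndarray | list[float]") -> dict[str, float]:
    """Fisher's method: combine independent p-values.

    Returns ``statistic = -2 Σ ln pᵢ``, ``df = 2k`` and the upper-tail
    χ²-probability ``combined_p``.
    """
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        raise DomainError("fisher_combine needs at least one p-value")
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0) or np.any(arr > 1):
        raise DomainError("p-values must lie in (0, 1]")
    statistic = float(-2.0 * np.log(arr).sum())
    df = 2 * arr.size
    combined_p = float(stats.chi2.sf(statistic, df))
    return {"statistic": statistic, "df": df, "combined_p": combined_p}


def _normalized_expression(
    adata: ad.AnnData, columns: "np.ndarray | None" = None, scale: float = 1e4
) -> sparse.csr_matrix:
    """Per-cell depth normalization (counts per ``scale`` total).

    Totals are always taken over the full gene set; ``columns`` then selects
    the genes of interest without distorting the depth estimate.
    """
    X = adata.X
    if not sparse.issparse(X):
        X = sparse.csr_matrix(X)
    X = X.tocsr().astype(np.float64)
    totals = np.asarray(X.sum(axis=1)).ravel()
    totals[totals == 0] = 1.0
    scaling = sparse.diags(scale / totals)
    norm = scaling @ X
    if columns is not None:
        norm = sparse.csr_matrix(norm[:, columns])
    return norm


def reference_cluster_de(
    adata: ad.AnnData,
    method: str = "pseudobulk_t",
    genes: "list[str] | None" = None,
    pseudocount: float = 0.01,
    cluster_key: str = "cluster",
    condition_key: str = "condition",
    sample_key: str = "sample",
    control: str = "control",
    stimulated: str = "stimulated",
) -> pd.DataFrame:
    """Per-cluster, per-gene differential expression between conditions.

    For every (cluster, gene): a two-sided raw p-value, the log2 fold
    change of stimulated vs control mean normalized expression (with
    ``pseudocount`` added to both means), the fraction of the cluster's
    cells expressing the gene, and the Holm-adjusted p within the cluster.
    Clusters missing one condition get NaN statistics and a logged warning.

    ``method='pseudobulk_t'`` aggregates to per-sample means before a
    Student t-test across samples; ``'percell_wilcoxon'`` ranks individual
    cells (anti-conservative; see module docstring).
    """
    if method not in ("pseudobulk_t", "percell_wilcoxon"):
        raise DomainError(f"unknown DE method {method!r}")
    for key in (cluster_key, condition_key, sample_key):
        if key not in adata.obs.columns:
            raise DomainError(f"cell metadata missing column {key!r}")
    name_to_col = {g: i for i, g in enumerate(adata.var_names)}
    if genes is not None:
        genes = [g for g in genes if g in name_to_col]
        columns = np.array([name_to_col[g] for g in genes], dtype=int)
    else:
        genes = list(adata.var_names)
        columns = None

    norm = _normalized_expression(adata, columns)
    raw = adata.X if sparse.issparse(adata.X) else sparse.csr_matrix(adata.X)
    raw = raw.tocsr()
    if columns is not None:
        raw = sparse.csr_matrix(raw[:, columns])
    obs = adata.obs
    cond = obs[condition_key].astype(str).to_numpy()
    samp = obs[sample_key].astype(str).to_numpy()
    clus = obs[cluster_key].astype(str).to_numpy()

    # pseudobulk needs >= 2 samples per condition overall
    if method == "pseudobulk_t":
        for c in (control, stimulated):
            if len(set(samp[cond == c])) < 2:
                raise DomainError(f"need >= 2 samples in condition {c!r} for pseudobulk_t")

    rows: list[pd.DataFrame] = []
    for cluster in pd.unique(clus):
        in_cluster = clus == cluster
        n_cells = int(in_cluster.sum())
        frac = np.asarray((raw[in_cluster] > 0).mean(axis=0)).ravel()
        present = {control, stimulated} <= set(cond[in_cluster])
        if not present:
            logger.warning(
                "cluster %s lacks cells in one condition; DE undefined", cluster
            )
            p_raw = np.full(len(genes), np.nan)
            lfc = np.full(len(genes), np.nan)
        elif method == "pseudobulk_t":
            p_raw, lfc = _pseudobulk_t(
                norm, in_cluster, cond, samp, control, stimulated, pseudocount
            )
        else:
            p_raw, lfc = _percell_wilcoxon(
                norm, in_cluster, cond, control, stimulated, pseudocount
            )
        block = pd.DataFrame(
            {
                "cluster": cluster,
                "gene": genes,
                "p_raw": p_raw,
                "log2fc": lfc,
                "frac_expressing": frac,
                "n_cells": n_cells,
            }
        )
        ok = block["p_raw"].notna()
        adj = np.full(len(block), np.nan)
        if ok.any():
            adj[ok.to_numpy()] = holm_bonferroni(
                np.clip(block.loc[ok, "p_raw"].to_numpy(), _TINY_P, 1.0)
            )
        block["p_adjusted"] = adj
        rows.append(block)
    out = pd.concat(rows, ignore_index=True)
    return out[["cluster", "gene", "p_raw", "p_adjusted", "log2fc", "frac_expressing", "n_cells"]]


def _pseudobulk_t(norm, in_cluster, cond, samp, control, stimulated, pseudocount):
    sample_ids = pd.unique(samp[in_cluster])
    means, labels = [], []
    for s in sample_ids:
        sel = in_cluster & (samp == s)
        if not sel.any():
            continue
        means.append(np.asarray(norm[sel].mean(axis=0)).ravel())
        labels.append(cond[sel][0])
    means = np.vstack(means)
    labels = np.asarray(labels)
    a = means[labels == stimulated]
    b = means[labels == control]
    if len(a) < 2 or len(b) < 2:
        return np.full(means.shape[1], np.nan), np.full(means.shape[1], np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=True)
    # flat genes (zero everywhere) yield nan p; report p = 1, no evidence
    p = np.where(np.isnan(p), 1.0, p)
    lfc = np.log2(a.mean(axis=0) + pseudocount) - np.log2(b.mean(axis=0) + pseudocount)
    return p, lfc


def _percell_wilcoxon(norm, in_cluster, cond, control, stimulated, pseudocount):
    a = norm[in_cluster & (cond == stimulated)].toarray()
    b = norm[in_cluster & (cond == control)].toarray()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.mannwhitneyu(a, b, axis=0, alternative="two-sided")
    p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    lfc = np.log2(a.mean(axis=0) + pseudocount) - np.log2(b.mean(axis=0) + pseudocount)
    return p, lfc


def ieg_activation_score(
    de_rows: pd.DataFrame, params: ScoreParams | None = None
) -> dict:
    """Score one cluster's DE table rows.

    Usable IEGs are panel genes with ``frac_expressing >= min_frac`` and
    raw ``p < alpha``. With none, the score is exactly 0; otherwise the raw
    p-values are Fisher-combined and the score magnitude is
    −log₁₀(combined p) (default) or −log₁₀(χ² statistic) under
    ``score_mode='neglog_chi2_statistic'``, negated when the mean log2FC of
    the usable IEGs is negative. Missing panel genes count as unexpressed.
    """
    params = params or ScoreParams()
    panel = de_rows[de_rows["gene"].isin(params.ieg_panel)]
    p_raw = panel["p_raw"].to_numpy(dtype=float)
    if np.any(p_raw == 0):
        warnings.warn("p_raw underflow clamped to the smallest positive float")
        p_raw = np.clip(p_raw, _TINY_P, None)
    with np.errstate(invalid="ignore"):
        usable = (
            panel["p_raw"].notna().to_numpy()
            & (panel["frac_expressing"].to_numpy(dtype=float) >= params.min_frac)
            & (p_raw < params.alpha)
        )
    n_used = int(usable.sum())
    if n_used == 0:
        return {
            "score": 0.0,
            "n_iegs_used": 0,
            "combined_p": np.nan,
            "mean_log2fc": np.nan,
            "sign": 0,
        }
    combo = fisher_combine(p_raw[usable])
    combined_p = max(combo["combined_p"], _TINY_P)
    if params.score_mode == "neglog_combined_p":
        magnitude = -np.log10(combined_p)
    else:
        magnitude = -np.log10(max(combo["statistic"], _TINY_P))
    mean_lfc = float(panel.loc[usable, "log2fc"].mean())
    sign = -1 if mean_lfc < 0 else 1
    return {
        "score": float(sign * magnitude),
        "n_iegs_used": n_used,
        "combined_p": combined_p,
        "mean_log2fc": mean_lfc,
        "sign": sign,
    }


def score_clusters(de: pd.DataFrame, params: ScoreParams | None = None) -> pd.DataFrame:
    """Apply :func:`ieg_activation_score` to every cluster in a DE table."""
    params = params or ScoreParams()
    rows = []
    for cluster, block in de.groupby("cluster", observed=True, sort=True):
        row = {"cluster": cluster}
        row.update(ieg_activation_score(block, params))
        rows.append(row)
    return pd.DataFrame(
        rows, columns=["cluster", "score", "n_iegs_used", "combined_p", "mean_log2fc", "sign"]
    )


def rank_clusters(scores: pd.DataFrame, top_n: int = 4) -> list:
    """Clusters ordered by descending activation score.

    Ties break by ascending combined p, then by cluster id (the all-zero
    case therefore orders by id — an arbitrary but stable convention).
    Returns the top ``top_n`` cluster ids.
    """
    if top_n < 1:
        raise DomainError("top_n must be >= 1")
    df = scores.copy()
    df["_p"] = df["combined_p"].fillna(np.inf)
    df["_id"] = df["cluster"].astype(str)
    df = df.sort_values(
        by=["score", "_p", "_id"], ascending=[False, True, True], kind="stable"
    )
    return df["cluster"].head(top_n).tolist()


def compute_cell_metrics(adata: ad.AnnData, mito_prefix: str = "mt-") -> pd.DataFrame:
    """Derive QC metrics (UMIs, detected genes, mito fraction) from counts."""
    X = adata.X if sparse.issparse(adata.X) else sparse.csr_matrix(adata.X)
    X = X.tocsr()
    umi = np.asarray(X.sum(axis=1)).ravel()
    genes = np.asarray((X > 0).sum(axis=1)).ravel()
    mito_cols = [i for i, g in enumerate(adata.var_names) if g.lower().startswith(mito_prefix)]
    mito = (
        np.asarray(X[:, mito_cols].sum(axis=1)).ravel() if mito_cols else np.zeros_like(umi)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(umi > 0, mito / umi, 0.0)
    return pd.DataFrame(
        {"cell": adata.obs_names, "umi_count": umi.astype(int), "gene_count": genes.astype(int), "mito_fraction": frac}
    )
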