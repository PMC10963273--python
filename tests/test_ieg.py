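"""Cell QC, p-value machinery and the signed IEG activation score."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fosmap as fm


def chi2_sf_4df(x):
    """Closed-form upper tail of chi-squared with 4 df (independent oracle)."""
    return np.exp(-x / 2.0) * (1.0 + x / 2.0)


def make_de_rows(entries):
    """entries: list of (gene, p_raw, log2fc, frac_expressing)."""
    return pd.DataFrame(
        [
            {"cluster": "c", "gene": g, "p_raw": p, "log2fc": lfc, "frac_expressing": f}
            for g, p, lfc, f in entries
        ]
    )


class TestQcFilterCells:
    @staticmethod
    def _metrics(rows):
        return pd.DataFrame(rows, columns=["cell", "umi_count", "gene_count", "mito_fraction"])

    def test_799_umis_removed_800_retained(self):
        df = self._metrics([("a", 799, 600, 0.01), ("b", 800, 600, 0.01)])
        assert list(fm.qc_filter_cells(df)) == ["b"]

    def test_exact_boundary_cell_is_retained(self):
        # 800 UMIs, 500 genes, exactly 10% mito: none of the removal
        # conditions ("fewer than", "above") applies
        df = self._metrics([("edge", 800, 500, 0.10)])
        assert list(fm.qc_filter_cells(df)) == ["edge"]

    @pytest.mark.parametrize(
        "umi,genes,mito",
        [(800, 499, 0.01), (800, 500, 0.101), (799, 500, 0.10)],
    )
    def test_each_filter_removes_independently(self, umi, genes, mito):
        df = self._metrics([("bad", umi, genes, mito)])
        assert len(fm.qc_filter_cells(df)) == 0

    def test_empty_input_empty_output(self):
        assert len(fm.qc_filter_cells(self._metrics([]))) == 0

    def test_invalid_metrics_rejected(self):
        with pytest.raises(fm.DomainError):
            fm.qc_filter_cells(self._metrics([("x", -1, 500, 0.05)]))
        with pytest.raises(fm.DomainError):
            fm.qc_filter_cells(self._metrics([("x", 1000, 500, 1.5)]))


class TestHolmBonferroni:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(fm.holm_bonferroni([0.03]), [0.03])

    def test_two_value_step_down_by_hand(self):
        # sorted: 2 x 0.01 = 0.02, then max(0.02, 1 x 0.04) = 0.04
        np.testing.assert_allclose(fm.holm_bonferroni([0.01, 0.04]), [0.02, 0.04])

    def test_out_of_range_rejected(self):
        for bad in ([0.0, 0.5], [0.5, 1.2], [np.nan]):
            with pytest.raises(fm.DomainError):
                fm.holm_bonferroni(bad)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=12))
    def test_dominates_raw_and_bounded_by_bonferroni(self, p):
        adjusted = fm.holm_bonferroni(p)
        assert (adjusted >= np.asarray(p) - 1e-15).all()
        assert (adjusted <= np.minimum(1.0, len(p) * np.asarray(p)) + 1e-12).all()

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=8), st.randoms(use_true_random=False))
    def test_permutation_equivariant(self, p, rnd):
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        direct = fm.holm_bonferroni(p)[perm]
        permuted = fm.holm_bonferroni([p[i] for i in perm])
        np.testing.assert_allclose(direct, permuted)


class TestFisherCombine:
    def test_p_equal_one_gives_zero_statistic(self):
        res = fm.fisher_combine([1.0])
        assert res["statistic"] == 0.0 and res["combined_p"] == pytest.approx(1.0)

    @pytest.mark.parametrize("p", [0.001, 0.05, 0.5, 0.99])
    def test_k1_identity(self, p):
        assert fm.fisher_combine([p])["combined_p"] == pytest.approx(p, rel=1e-9)

    def test_two_value_example_against_closed_form(self):
        res = fm.fisher_combine([0.01, 0.04])
        expected_stat = -2 * (np.log(0.01) + np.log(0.04))
        assert res["statistic"] == pytest.approx(expected_stat, rel=1e-12)
        assert res["statistic"] == pytest.approx(15.65, abs=0.01)
        assert res["df"] == 4
        assert res["combined_p"] == pytest.approx(chi2_sf_4df(expected_stat), rel=1e-9)

    def test_empty_input_rejected(self):
        with pytest.raises(fm.DomainError):
            fm.fisher_combine([])

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=10),
        st.integers(0, 9),
    )
    def test_monotone_decreasing_in_any_input(self, p, idx):
        idx = idx % len(p)
        base = fm.fisher_combine(p)["combined_p"]
        smaller = list(p)
        smaller[idx] = p[idx] / 2.0
        assert fm.fisher_combine(smaller)["combined_p"] < base + 1e-15


class TestActivationScore:
    def test_no_significant_ieg_scores_exactly_zero(self):
        rows = make_de_rows([("Fos", 0.2, 1.0, 0.5), ("Junb", 0.8, -0.3, 0.4)])
        res = fm.ieg_activation_score(rows)
        assert res["score"] == 0.0 and res["n_iegs_used"] == 0 and res["sign"] == 0

    def test_low_expression_gene_excluded_by_min_frac(self):
        rows = make_de_rows([("Fos", 0.001, 2.0, 0.04)])  # below the 5% filter
        assert fm.ieg_activation_score(rows)["score"] == 0.0
        rows = make_de_rows([("Fos", 0.001, 2.0, 0.05)])  # exactly 5% passes
        assert fm.ieg_activation_score(rows)["n_iegs_used"] == 1

    def test_alpha_is_strict(self):
        assert fm.ieg_activation_score(make_de_rows([("Fos", 0.05, 1.0, 0.5)]))["score"] == 0.0
        assert fm.ieg_activation_score(make_de_rows([("Fos", 0.049, 1.0, 0.5)]))["score"] > 0.0

    def test_non_panel_genes_ignored(self):
        rows = make_de_rows([("Gapdh", 1e-10, 3.0, 0.9), ("Fos", 0.2, 1.0, 0.5)])
        assert fm.ieg_activation_score(rows)["score"] == 0.0

    def test_negative_mean_log2fc_flips_sign(self):
        rows = make_de_rows([("Fos", 0.01, -1.0, 0.5), ("Junb", 0.04, -0.5, 0.5)])
        res = fm.ieg_activation_score(rows)
        assert res["score"] < 0 and res["sign"] == -1
        assert res["mean_log2fc"] == pytest.approx(-0.75)

    def test_two_gene_score_composes_fisher_and_log(self):
        rows = make_de_rows([("Fos", 0.01, 1.0, 0.5), ("Junb", 0.04, 1.0, 0.5)])
        res = fm.ieg_activation_score(rows)
        stat = -2 * (np.log(0.01) + np.log(0.04))
        assert res["score"] == pytest.approx(-np.log10(chi2_sf_4df(stat)), rel=1e-9)
        assert res["combined_p"] == pytest.approx(chi2_sf_4df(stat), rel=1e-9)
        assert res["n_iegs_used"] == 2

    def test_literal_statistic_mode(self):
        rows = make_de_rows([("Fos", 0.01, 1.0, 0.5), ("Junb", 0.04, 1.0, 0.5)])
        res = fm.ieg_activation_score(rows, fm.ScoreParams(score_mode="neglog_chi2_statistic"))
        stat = -2 * (np.log(0.01) + np.log(0.04))
        assert res["score"] == pytest.approx(-np.log10(stat), rel=1e-9)

    def test_score_invariant_to_expression_level_above_filter(self):
        lo = make_de_rows([("Fos", 0.01, 1.0, 0.06), ("Junb", 0.04, 1.0, 0.08)])
        hi = make_de_rows([("Fos", 0.01, 1.0, 0.6), ("Junb", 0.04, 1.0, 0.8)])
        assert fm.ieg_activation_score(lo)["score"] == fm.ieg_activation_score(hi)["score"]

    def test_underflow_p_clamped_with_warning(self):
        rows = make_de_rows([("Fos", 0.0, 1.0, 0.5)])
        with pytest.warns(UserWarning, match="underflow"):
            res = fm.ieg_activation_score(rows)
        assert np.isfinite(res["score"]) and res["score"] > 0


class TestRankClusters:
    @staticmethod
    def _scores(rows):
        return pd.DataFrame(rows, columns=["cluster", "score", "n_iegs_used", "combined_p", "mean_log2fc", "sign"])

    def test_descending_by_score_top_n(self):
        scores = self._scores([
            ("a", 1.0, 1, 0.1, 1.0, 1),
            ("b", 3.0, 2, 0.001, 1.0, 1),
            ("c", 2.0, 1, 0.01, 1.0, 1),
            ("d", -1.0, 1, 0.1, -1.0, -1),
            ("e", 0.0, 0, np.nan, np.nan, 0),
        ])
        assert fm.rank_clusters(scores, top_n=4) == ["b", "c", "a", "e"]

    def test_all_zero_orders_by_cluster_id(self):
        scores = self._scores([
            (cid, 0.0, 0, np.nan, np.nan, 0) for cid in ["3", "1", "2"]
        ])
        assert fm.rank_clusters(scores, top_n=3) == ["1", "2", "3"]

    def test_tie_breaks_by_combined_p(self):
        scores = self._scores([
            ("x", 2.0, 1, 0.02, 1.0, 1),
            ("y", 2.0, 1, 0.01, 1.0, 1),
        ])
        assert fm.rank_clusters(scores, top_n=2) == ["y", "x"]

    def test_top_n_validated(self):
        with pytest.raises(fm.DomainError):
            fm.rank_clusters(self._scores([("a", 1.0, 1, 0.1, 1.0, 1)]), top_n=0)


class TestReferenceClusterDe:
    def test_identical_condition_means_give_zero_log2fc(self):
        spec = fm.SnRnaSimSpec(n_genes=100, n_cells=400, n_clusters=2,
                               activated_clusters=frozenset({1}),
                               inhibited_clusters=frozenset(),
                               ieg_log2fc=0.0, dispersion=1e-4, seed=3)
        adata, _ = fm.generate_snrnaseq(spec)
        de = fm.reference_cluster_de(adata, genes=list(spec.ieg_panel))
        assert de["log2fc"].abs().max() < 0.2

    def test_all_zero_gene_has_zero_frac_and_p_one(self, small_snrnaseq):
        _, adata, _ = small_snrnaseq
        adata = adata.copy()
        zeroed = adata.var_names[-1]
        X = adata.X.tolil()
        X[:, -1] = 0
        adata.X = X.tocsr()
        de = fm.reference_cluster_de(adata, genes=[zeroed])
        assert (de["frac_expressing"] == 0).all()
        assert (de["p_raw"] == 1.0).all()

    def test_adjusted_dominates_raw_within_cluster(self, small_snrnaseq):
        spec, adata, _ = small_snrnaseq
        de = fm.reference_cluster_de(adata, genes=list(spec.ieg_panel))
        ok = de["p_raw"].notna()
        assert (de.loc[ok, "p_adjusted"] >= de.loc[ok, "p_raw"] - 1e-12).all()
        assert de.groupby("cluster", observed=True).size().nunique() == 1

    def test_activated_cluster_recovered(self, small_snrnaseq):
        spec, adata, _ = small_snrnaseq
        de = fm.reference_cluster_de(adata, genes=list(spec.ieg_panel))
        scores = fm.score_clusters(de)
        ranked = fm.rank_clusters(scores, top_n=1)
        assert ranked[0] == str(next(iter(spec.activated_clusters)))
        inhibited = str(next(iter(spec.inhibited_clusters)))
        assert scores.set_index("cluster").loc[inhibited, "score"] < 0

    def test_wilcoxon_method_agrees_on_direction(self, small_snrnaseq):
        spec, adata, _ = small_snrnaseq
        de = fm.reference_cluster_de(adata, method="percell_wilcoxon",
                                     genes=list(spec.ieg_panel))
        act = str(next(iter(spec.activated_clusters)))
        block = de[de["cluster"] == act]
        assert (block["log2fc"] > 0).mean() > 0.8

    def test_single_sample_condition_rejected_for_pseudobulk(self, small_snrnaseq):
        _, adata, _ = small_snrnaseq
        adata = adata[adata.obs["sample"].isin(["control_1", "stimulated_1", "stimulated_2"])].copy()
        with pytest.raises(fm.DomainError):
            fm.reference_cluster_de(adata)

    def test_missing_condition_yields_undefined_rows(self, small_snrnaseq):
        spec, adata, _ = small_snrnaseq
        keep = ~((adata.obs["cluster"] == "0") & (adata.obs["condition"] == "stimulated"))
        sub = adata[keep].copy()
        de = fm.reference_cluster_de(sub, genes=list(spec.ieg_panel))
        assert de.loc[de["cluster"] == "0", "p_raw"].isna().all()
        assert de.loc[de["cluster"] == "1", "p_raw"].notna().all()
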