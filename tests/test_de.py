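import numpy as np
import pandas as pd
import pytest

from cutspec.de import (
    DEParams,
    PAPER_COMPARISON_ORDER,
    enumerate_comparisons,
    pairwise_de,
    size_factors,
    summarize_de,
)
from conftest import make_two_group_counts


class TestEnumerateComparisons:
    def test_default_six_cuts_give_fifteen_pairs_in_conventional_order(self):
        pairs = enumerate_comparisons(["LD", "IM", "T", "BB", "GM", "QF"])
        assert len(pairs) == 15
        assert pairs == PAPER_COMPARISON_ORDER
        # every unordered pair exactly once
        assert len({frozenset(p) for p in pairs}) == 15

    @pytest.mark.parametrize("regions,expected", [(list("AB"), 1), (list("ABC"), 3), (list("ABCD"), 6)])
    def test_choose_two_counts(self, regions, expected):
        assert len(enumerate_comparisons(regions)) == expected

    def test_single_region_rejected(self):
        with pytest.raises(ValueError):
            enumerate_comparisons(["A"])


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        counts = pd.DataFrame(
            [[10, 10], [50, 50]], index=["G1", "G2"], columns=["S1", "S2"]
        )
        np.testing.assert_allclose(size_factors(counts), 1.0)

    def test_doubled_sample_gets_double_factor(self):
        rng = np.random.default_rng(0)
        base = rng.integers(5, 100, 50)
        counts = pd.DataFrame(
            {"A": base, "B": 2 * base}, index=[f"G{i}" for i in range(50)]
        )
        sf = size_factors(counts)
        assert sf["B"] / sf["A"] == pytest.approx(2.0)

    def test_all_zero_gene_is_ignored(self):
        counts = pd.DataFrame(
            [[10, 20], [0, 0], [30, 60]], index=["G1", "G2", "G3"], columns=["S1", "S2"]
        )
        sf = size_factors(counts)
        assert np.isfinite(sf).all()

    def test_agrees_with_reference_implementation(self):
        """Cross-check the median-of-ratios factors against pydeseq2.

        The two differ only in where the even-count median interpolates
        (log vs linear space), so agreement is to a fraction of a percent.
        """
        from pydeseq2.dds import DeseqDataSet

        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.integers(1, 500, (51, 8)),
            index=[f"G{i}" for i in range(51)],
            columns=[f"S{i}" for i in range(8)],
        )
        meta = pd.DataFrame({"condition": ["A"] * 4 + ["B"] * 4}, index=counts.columns)
        dds = DeseqDataSet(counts=counts.T, metadata=meta, design="~condition", quiet=True)
        dds.fit_size_factors()
        ref = np.asarray(dds.obs["size_factors"])
        np.testing.assert_allclose(size_factors(counts).to_numpy(), ref, rtol=5e-3)

    def test_no_usable_gene_is_an_error(self):
        counts = pd.DataFrame([[0, 5], [3, 0]], index=["G1", "G2"], columns=["S1", "S2"])
        with pytest.raises(ValueError, match="reference"):
            size_factors(counts)


class TestPairwiseDe:
    def test_identical_groups_are_all_null(self):
        rng = np.random.default_rng(1)
        base = rng.integers(10, 200, 30)
        counts, samples = make_two_group_counts(rng, 30, 4, base.astype(float), alpha=0)
        # force both groups exactly identical per gene
        for i in range(4):
            counts[f"B_{i}"] = counts[f"A_{i}"]
        res = pairwise_de(counts, samples, ("A", "B"))
        np.testing.assert_allclose(res["log2fc"], 0.0)
        assert (res["direction"] == "ns").all()

    def test_swapping_pair_negates_log2fc_and_swaps_directions(self):
        rng = np.random.default_rng(2)
        base = rng.lognormal(np.log(80), 1, 100)
        counts, samples = make_two_group_counts(
            rng, 100, 6, base, alpha=0.1, fold_genes=np.arange(10), fold=5.0
        )
        ab = pairwise_de(counts, samples, ("A", "B"))
        ba = pairwise_de(counts, samples, ("B", "A"))
        np.testing.assert_allclose(ab["log2fc"], -ba["log2fc"])
        np.testing.assert_allclose(ab["pvalue"], ba["pvalue"])
        assert (ab["direction"] == "up").sum() == (ba["direction"] == "down").sum()
        assert (ab["direction"] == "down").sum() == (ba["direction"] == "up").sum()

    def test_bh_qvalues_monotone_in_pvalue_rank(self):
        rng = np.random.default_rng(3)
        base = rng.lognormal(np.log(50), 1, 200)
        counts, samples = make_two_group_counts(rng, 200, 5, base, alpha=0.1)
        res = pairwise_de(counts, samples, ("A", "B")).sort_values("pvalue")
        q = res["qvalue"].to_numpy()
        assert (np.diff(q) >= -1e-12).all()
        assert q[-1] >= res["pvalue"].to_numpy()[-1] - 1e-12
        assert ((res["pvalue"] >= 0) & (res["pvalue"] <= 1)).all()
        assert ((res["qvalue"] >= 0) & (res["qvalue"] <= 1)).all()

    def test_planted_fourfold_genes_recover_log2fc_two(self):
        """20 genes planted at 4-fold against 200 nulls, n=12 per group: the
        median estimated log2 fold change of the planted genes sits within
        0.3 of log2(4) = 2."""
        rng = np.random.default_rng(42)
        base = rng.lognormal(np.log(100), 0.8, 220)
        counts, samples = make_two_group_counts(
            rng, 220, 12, base, alpha=0.1, fold_genes=np.arange(20), fold=4.0
        )
        res = pairwise_de(counts, samples, ("A", "B"))
        med = float(res["log2fc"].iloc[:20].median())
        assert abs(med - 2.0) <= 0.3

    def test_both_groups_zero_convention(self):
        counts = pd.DataFrame(
            {
                "A_0": [0, 10], "A_1": [0, 12],
                "B_0": [0, 11], "B_1": [0, 9],
            },
            index=pd.Index(["Gzero", "Gok"], name="gene_id"),
        )
        samples = pd.DataFrame(
            {"region": ["A", "A", "B", "B"], "animal_id": ["a", "b", "a", "b"]},
            index=pd.Index(counts.columns, name="sample_id"),
        )
        res = pairwise_de(counts, samples, ("A", "B")).set_index("gene_id")
        assert res.at["Gzero", "pvalue"] == 1.0
        assert res.at["Gzero", "log2fc"] == 0.0

    def test_group_with_single_sample_rejected(self):
        counts = pd.DataFrame(
            {"A_0": [5], "A_1": [6], "B_0": [7]},
            index=pd.Index(["G1"], name="gene_id"),
        )
        samples = pd.DataFrame(
            {"region": ["A", "A", "B"], "animal_id": ["a", "b", "a"]},
            index=pd.Index(counts.columns, name="sample_id"),
        )
        with pytest.raises(ValueError, match="B"):
            pairwise_de(counts, samples, ("A", "B"))


class TestSummarizeDe:
    def test_counts_match_independent_recount(self):
        rng = np.random.default_rng(5)
        base = rng.lognormal(np.log(100), 1, 150)
        counts, samples = make_two_group_counts(
            rng, 150, 8, base, alpha=0.05, fold_genes=np.arange(15), fold=6.0
        )
        res = pairwise_de(counts, samples, ("A", "B"))
        summary = summarize_de(res)
        row = summary.iloc[0]
        # independent recount straight off the records table
        params = DEParams()
        sig = res[(res["qvalue"] < params.fdr_threshold)]
        n_up = int((sig["log2fc"] > params.lfc_threshold).sum())
        n_down = int((sig["log2fc"] < -params.lfc_threshold).sum())
        assert (row["n_up"], row["n_down"], row["n_total"]) == (n_up, n_down, n_up + n_down)
        assert row["n_total"] > 0  # the planted effects are detectable

    def test_zero_significant_records(self):
        res = pd.DataFrame(
            {
                "comparison": ["A_vs_B"] * 3,
                "gene_id": ["G1", "G2", "G3"],
                "log2fc": [0.1, -0.2, 0.0],
                "pvalue": [0.5, 0.9, 0.7],
                "qvalue": [0.9, 0.9, 0.9],
                "direction": ["ns"] * 3,
            }
        )
        summary = summarize_de(res)
        assert summary.iloc[0][["n_up", "n_down", "n_total"]].tolist() == [0, 0, 0]
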