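"""Gene-level counting, Rx scaling, BH and the NB Wald test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chiprx._stats import bh_adjust
from chiprx.dug import (
    classify_dugs,
    count_reads_in_gene_regions,
    join_expression,
    median_of_ratios_factors,
    nb_wald_test,
    rx_scale_counts,
    total_count_factors,
)
from conftest import make_readset
from _brute import brute_bh, brute_count_reads


def _regions(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


class TestCounting:
    def test_reads_overlapping_any_region_counted(self):
        rs = make_readset(
            [("chr1", 100, 150, "+"), ("chr1", 140, 190, "+"), ("chr1", 300, 350, "+")]
        )
        regions = _regions([("gA", "chr1", 120, 200), ("gA", "chr1", 310, 320)])
        counts = count_reads_in_gene_regions(rs, regions)
        assert counts["gA"] == 3

    def test_read_spanning_two_regions_counts_once(self):
        rs = make_readset([("chr1", 95, 160, "+")])
        regions = _regions([("gA", "chr1", 90, 100), ("gA", "chr1", 150, 200)])
        assert count_reads_in_gene_regions(rs, regions)["gA"] == 1

    def test_read_may_count_for_multiple_genes(self):
        rs = make_readset([("chr1", 95, 160, "+")])
        regions = _regions([("gA", "chr1", 90, 100), ("gB", "chr1", 150, 200)])
        counts = count_reads_in_gene_regions(rs, regions)
        assert counts["gA"] == 1 and counts["gB"] == 1

    def test_no_reads_gives_zero_vector(self):
        rs = make_readset([("dmel_chr2L", 0, 50, "+")])
        counts = count_reads_in_gene_regions(rs, _regions([("gA", "chr1", 0, 100)]))
        assert counts["gA"] == 0

    def test_matches_brute_force(self, rng):
        for _ in range(15):
            n_reads = rng.integers(5, 60)
            starts = rng.integers(0, 2000, n_reads)
            lens = rng.integers(10, 120, n_reads)
            reads = [("chr1", int(s), int(s + l), "+") for s, l in zip(starts, lens)]
            gene_regions = {}
            rows = []
            for g in range(int(rng.integers(1, 5))):
                regs = []
                pos = int(rng.integers(0, 1500))
                for _r in range(int(rng.integers(1, 3))):
                    end = pos + int(rng.integers(20, 200))
                    regs.append((pos, end))
                    rows.append((f"g{g}", "chr1", pos, end))
                    pos = end + int(rng.integers(10, 200))
                gene_regions[f"g{g}"] = regs
            got = count_reads_in_gene_regions(make_readset(reads), _regions(rows))
            expected = brute_count_reads([(s, e) for _, s, e, _ in reads], gene_regions)
            assert dict(got) == expected


class TestRxScaling:
    def test_scalar_and_identity(self):
        raw = pd.DataFrame({"s1": [100, 3], "s2": [7, 9]}, index=["gA", "gB"])
        cm = rx_scale_counts(raw, {"s1": 2.0, "s2": 1.0})
        assert cm.scaled.loc["gA", "s1"] == 200
        assert cm.scaled["s2"].tolist() == [7, 9]

    def test_half_rounds_away_from_zero(self):
        raw = pd.DataFrame({"s1": [3]}, index=["gA"])
        cm = rx_scale_counts(raw, {"s1": 0.5})
        assert cm.scaled.loc["gA", "s1"] == 2

    def test_missing_alpha_fails(self):
        raw = pd.DataFrame({"s1": [1], "s2": [2]}, index=["gA"])
        with pytest.raises(ValueError, match="s2"):
            rx_scale_counts(raw, {"s1": 1.0})

    def test_comparison_normalizations(self):
        raw = pd.DataFrame(
            {"a": [100, 200, 300], "b": [50, 100, 150]}, index=["g1", "g2", "g3"]
        )
        tot = total_count_factors(raw)
        # equalizing totals doubles the shallower library relative to geometry
        assert tot["b"] / tot["a"] == pytest.approx(2.0)
        mor = median_of_ratios_factors(raw)
        assert mor["b"] / mor["a"] == pytest.approx(2.0)


class TestBhAdjust:
    def test_hand_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37]).tolist() == [0.37]

    def test_all_ones(self):
        assert bh_adjust([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_nan_excluded_from_universe(self):
        out = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2]], brute_bh([0.01, 0.04]))

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
    def test_matches_direct_step_up_and_is_monotone(self, pvals):
        got = bh_adjust(pvals)
        np.testing.assert_allclose(got, brute_bh(pvals), atol=1e-12)
        order = np.argsort(pvals, kind="stable")
        assert (np.diff(got[order]) >= -1e-12).all()


def _null_matrix(rng, n_genes, mu_lo=50, mu_hi=400, disp=0.005):
    mu = rng.uniform(mu_lo, mu_hi, n_genes)
    r = 1 / disp
    counts = rng.negative_binomial(r, r / (r + mu[:, None]), size=(n_genes, 4))
    return pd.DataFrame(
        counts, columns=["a1", "a2", "b1", "b2"],
        index=[f"g{i}" for i in range(n_genes)],
    )


DESIGN = pd.Series({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})


class TestNbWaldTest:
    def test_identical_counts_give_null_result(self):
        df = pd.DataFrame(
            {"a1": [50], "a2": [50], "b1": [50], "b2": [50]}, index=["gA"]
        )
        res = nb_wald_test(df, DESIGN, contrast=("B", "A"))
        assert res.loc["gA", "log2FC"] == 0.0
        assert res.loc["gA", "pvalue"] == pytest.approx(1.0)

    def test_all_zero_gene_flagged_and_outside_fdr_universe(self):
        df = pd.DataFrame(
            {"a1": [0, 60], "a2": [0, 55], "b1": [0, 20], "b2": [0, 25]},
            index=["gZ", "gA"],
        )
        res = classify_dugs(nb_wald_test(df, DESIGN, contrast=("B", "A")))
        assert res.loc["gZ", "call"] == "flagged"
        assert np.isnan(res.loc["gZ", "FDR"])
        assert res.loc["gA", "FDR"] == res.loc["gA", "pvalue"]  # universe of 1

    def test_insufficient_replication_fails(self):
        df = pd.DataFrame({"a1": [5], "b1": [9], "b2": [7]}, index=["gA"])
        design = pd.Series({"a1": "A", "b1": "B", "b2": "B"})
        with pytest.raises(ValueError, match="replicates"):
            nb_wald_test(df, design, contrast=("B", "A"))

    def test_null_type_i_error_calibrated(self, rng):
        """On NB null counts (equal means, 2+2), the p<0.05 rate is ~5%."""
        df = _null_matrix(rng, 2000)
        res = nb_wald_test(df, DESIGN, contrast=("B", "A"))
        frac = (res["pvalue"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_strong_shift_detected_with_correct_sign(self, rng):
        mu = 200.0
        a = rng.poisson(mu, (300, 2))
        b = rng.poisson(mu * 4, (300, 2))
        df = pd.DataFrame(
            np.hstack([a, b]), columns=["a1", "a2", "b1", "b2"],
            index=[f"g{i}" for i in range(300)],
        )
        res = nb_wald_test(df, DESIGN, contrast=("B", "A"))
        assert np.median(res["log2FC"]) == pytest.approx(2.0, abs=0.1)
        assert (res["pvalue"] < 0.01).mean() > 0.95


class TestClassification:
    def test_call_definitions(self):
        table = pd.DataFrame(
            {
                "baseMean": [10, 10, 10],
                "log2FC": [1.3, -3.4, 0.4],
                "stat": [5, -6, 1],
                "pvalue": [1e-6, 1e-8, 0.3],
            },
            index=["g1", "g2", "g3"],
        )
        res = classify_dugs(table, fdr_threshold=0.01)
        assert res["call"].tolist() == ["hyper", "hypo", "ns"]

    def test_calls_partition_universe(self, rng):
        df = _null_matrix(rng, 500)
        df.iloc[0] = 0  # one all-zero gene
        res = classify_dugs(nb_wald_test(df, DESIGN, contrast=("B", "A")))
        counts = res["call"].value_counts()
        assert counts.sum() == len(res)
        assert counts.get("flagged", 0) == 1


class TestJoinExpression:
    def _dug(self, ids):
        return pd.DataFrame(
            {"log2FC": 1.0, "pvalue": 0.5, "call": "ns"},
            index=pd.Index(ids, name="gene_id"),
        )

    def test_disjoint_sets_warn_and_return_empty(self):
        expr = pd.DataFrame({"gene_id": ["x"], "log2FC": [2.0], "FDR": [0.001]})
        with pytest.warns(UserWarning, match="empty join"):
            out = join_expression(self._dug(["a"]), expr)
        assert len(out) == 0

    def test_single_overlap_reports_both_fold_changes(self):
        expr = pd.DataFrame({"gene_id": ["a"], "log2FC": [3.7], "FDR": [0.001]})
        out = join_expression(self._dug(["a", "b"]), expr)
        assert len(out) == 1
        assert out.iloc[0]["expression_log2FC"] == 3.7
        assert out.iloc[0]["log2FC"] == 1.0

    def test_cardinality_matches_set_intersection(self, rng):
        ids = [f"g{i}" for i in range(200)]
        left = list(rng.choice(ids, 80, replace=False))
        right = list(rng.choice(ids, 90, replace=False))
        expr = pd.DataFrame({"gene_id": right, "log2FC": 0.0, "FDR": 0.5})
        out = join_expression(self._dug(left), expr)
        assert len(out) == len(set(left) & set(right))
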