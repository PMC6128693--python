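"""Stand-in peak caller, reproducibility rule, gene annotation, unions."""

import numpy as np
import pandas as pd
import pytest

from chiprx._intervals import merge_intervals
from chiprx.peaks import (
    PeakCallerParams,
    annotate_genes,
    call_peaks_poisson,
    compare_marked_sets,
    gene_windows,
    intersect_replicate_peaks,
    union_peaks_by_gene,
)
from conftest import make_readset
from _brute import (
    bases,
    brute_marked_genes,
    brute_reproducible_peaks,
    brute_union_by_gene,
)


def _peaks(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"]).assign(
        score=1.0, qvalue=0.001
    )


def _genes(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "tss", "tes"])


class TestParams:
    def test_window_step_ordering_enforced(self):
        with pytest.raises(ValueError, match="window >= step"):
            PeakCallerParams(window=50, step=100)

    def test_threshold_range(self):
        with pytest.raises(ValueError, match="qvalue_threshold"):
            PeakCallerParams(qvalue_threshold=1.5)


class TestPoissonCaller:
    def test_uniform_background_yields_almost_no_peak_bases(self, rng):
        genome = 500_000
        starts = rng.integers(0, genome - 50, 60_000)
        ip = make_readset([("chr1", int(s), int(s) + 50, "+") for s in starts])
        peaks = call_peaks_poisson(ip, None, chrom_lengths={"chr1": genome})
        covered = int((peaks["end"] - peaks["start"]).sum())
        assert covered <= 0.01 * genome

    def test_enriched_domain_recovered_as_single_peak(self, rng):
        genome = 100_000
        domain = (40_000, 42_000)
        # 20x background coverage with a 10-fold enriched 2 kb domain
        n_bg = genome * 20 // 50
        bg = rng.integers(0, genome - 50, n_bg)
        n_dom = (domain[1] - domain[0]) * 20 * 10 // 50
        dom = rng.integers(domain[0], domain[1] - 50, n_dom)
        ip = make_readset(
            [("chr1", int(s), int(s) + 50, "+") for s in np.concatenate([bg, dom])]
        )
        peaks = call_peaks_poisson(ip, None, chrom_lengths={"chr1": genome})
        sig = peaks[peaks["qvalue"] < 0.01]
        assert len(sig) == 1
        row = sig.iloc[0]
        overlap = min(row.end, domain[1]) - max(row.start, domain[0])
        assert overlap >= 0.8 * (domain[1] - domain[0])

    def test_empty_ip_gives_zero_peaks_with_warning(self):
        ip = make_readset([("dmel_chr2L", 0, 50, "+")])  # no target reads
        with pytest.warns(UserWarning, match="empty IP"):
            peaks = call_peaks_poisson(ip, None)
        assert len(peaks) == 0


class TestReplicateIntersection:
    def test_ten_percent_rule_strict_boundary(self):
        # overlap exactly 10% of a 100 bp peak is NOT beyond 10% -> dropped
        rep1 = _peaks([("chr1", 100, 200)])
        rep2 = _peaks([("chr1", 190, 400)])
        assert len(intersect_replicate_peaks(rep1, rep2)) == 0

    def test_ten_percent_rule_one_base_beyond(self):
        rep1 = _peaks([("chr1", 100, 200)])
        rep2 = _peaks([("chr1", 189, 400)])
        out = intersect_replicate_peaks(rep1, rep2)
        # rep1 kept (11 > 10), rep2 dropped (11 < 30% of 211... 10% of 211 = 21.1)
        assert list(map(tuple, out[["start", "end"]].to_numpy())) == [(100, 200)]

    def test_identical_lists_return_merged_input(self):
        peaks = _peaks([("chr1", 0, 100), ("chr1", 300, 500)])
        out = intersect_replicate_peaks(peaks, peaks)
        assert list(map(tuple, out[["start", "end"]].to_numpy())) == [(0, 100), (300, 500)]

    def test_symmetric_in_arguments(self, rng):
        for _ in range(20):
            rep1 = _random_peaks(rng)
            rep2 = _random_peaks(rng)
            a = intersect_replicate_peaks(rep1, rep2)
            b = intersect_replicate_peaks(rep2, rep1)
            pd.testing.assert_frame_equal(
                a[["chrom", "start", "end"]], b[["chrom", "start", "end"]]
            )

    def test_matches_per_base_brute_force(self, rng):
        for _ in range(30):
            rep1 = _random_peaks(rng)
            rep2 = _random_peaks(rng)
            out = intersect_replicate_peaks(rep1, rep2)
            got = bases(out[["start", "end"]].to_numpy())
            expected = brute_reproducible_peaks(
                rep1[["start", "end"]].to_numpy(), rep2[["start", "end"]].to_numpy()
            )
            assert got == expected


def _random_peaks(rng, n_max=8, span=1000):
    n = rng.integers(1, n_max)
    starts = rng.integers(0, span, n)
    ends = starts + rng.integers(1, 200, n)
    ms, me = merge_intervals(starts, ends)  # keep inputs non-overlapping
    return _peaks([("chr1", int(s), int(e)) for s, e in zip(ms, me)])


class TestGeneAnnotation:
    def test_upstream_window_overlap_counts(self):
        genes = _genes([("gA", "chr1", "+", 1000, 2000)])
        marked = annotate_genes(_peaks([("chr1", 500, 920)]), genes)
        assert marked["gene_id"].tolist() == ["gA"]
        assert marked["overlap_bp"].tolist() == [170]

    def test_exactly_150_bp_is_not_marked(self):
        genes = _genes([("gA", "chr1", "+", 1000, 2000)])
        marked = annotate_genes(_peaks([("chr1", 500, 900)]), genes)
        assert len(marked) == 0

    def test_minus_strand_window(self):
        win = gene_windows(_genes([("gA", "chr1", "-", 2000, 1000)]))
        assert (win.iloc[0].window_start, win.iloc[0].window_end) == (1000, 2250)

    def test_window_clipped_at_zero(self):
        win = gene_windows(_genes([("gA", "chr1", "+", 100, 900)]))
        assert win.iloc[0].window_start == 0

    def test_summed_overlap_across_peaks(self):
        genes = _genes([("gA", "chr1", "+", 1000, 2000)])
        peaks = _peaks([("chr1", 800, 880), ("chr1", 900, 980)])  # 80 + 80 = 160
        marked = annotate_genes(peaks, genes)
        assert marked["overlap_bp"].tolist() == [160]

    def test_matches_per_base_brute_force(self, rng):
        for _ in range(30):
            peaks = _random_peaks(rng, span=3000)
            genes = _random_genes(rng)
            got = annotate_genes(peaks, genes)
            win = gene_windows(genes)
            windows = {
                r.gene_id: (r.window_start, r.window_end) for r in win.itertuples()
            }
            expected = brute_marked_genes(peaks[["start", "end"]].to_numpy(), windows)
            assert dict(zip(got["gene_id"], got["overlap_bp"])) == expected


def _random_genes(rng, n_max=6, span=3000):
    n = rng.integers(1, n_max)
    rows = []
    for i in range(n):
        a = int(rng.integers(300, span))
        b = a + int(rng.integers(200, 800))
        strand = "+" if rng.random() < 0.5 else "-"
        tss, tes = (a, b) if strand == "+" else (b, a)
        rows.append((f"g{i}", "chr1", strand, tss, tes))
    return _genes(rows)


class TestUnionByGene:
    def test_union_within_window(self):
        genes = _genes([("gA", "chr1", "+", 250, 600)])  # window [0, 600)
        regions = union_peaks_by_gene(
            [_peaks([("chr1", 100, 300)]), _peaks([("chr1", 250, 500)])], genes
        )
        assert list(map(tuple, regions[["start", "end"]].to_numpy())) == [(100, 500)]

    def test_clipping_to_window(self):
        genes = _genes([("gA", "chr1", "+", 250, 600)])
        regions = union_peaks_by_gene([_peaks([("chr1", 500, 700)])], genes)
        assert list(map(tuple, regions[["start", "end"]].to_numpy())) == [(500, 600)]

    def test_gene_without_peaks_absent(self):
        genes = _genes([("gA", "chr1", "+", 250, 600), ("gB", "chr1", "+", 5000, 6000)])
        regions = union_peaks_by_gene([_peaks([("chr1", 100, 300)])], genes)
        assert set(regions["gene_id"]) == {"gA"}

    def test_regions_stay_inside_windows(self, rng):
        for _ in range(20):
            genes = _random_genes(rng)
            sets = [_random_peaks(rng, span=3000) for _ in range(3)]
            regions = union_peaks_by_gene(sets, genes)
            win = gene_windows(genes).set_index("gene_id")
            for row in regions.itertuples():
                assert row.start >= win.loc[row.gene_id, "window_start"]
                assert row.end <= win.loc[row.gene_id, "window_end"]

    def test_matches_per_base_brute_force(self, rng):
        for _ in range(30):
            genes = _random_genes(rng)
            sets = [_random_peaks(rng, span=3000) for _ in range(3)]
            regions = union_peaks_by_gene(sets, genes)
            got = {
                g: bases(grp[["start", "end"]].to_numpy())
                for g, grp in regions.groupby("gene_id")
            }
            all_peaks = np.vstack([p[["start", "end"]].to_numpy() for p in sets])
            win = gene_windows(genes)
            windows = {r.gene_id: (r.window_start, r.window_end) for r in win.itertuples()}
            assert got == brute_union_by_gene(all_peaks, windows)


class TestCompareMarkedSets:
    def test_set_algebra_counts(self):
        membership, counts = compare_marked_sets(
            {"s1": ["a", "b", "c"], "s2": ["b", "c", "d"]}
        )
        assert counts["all"] == 2 and counts["any"] == 4
        assert membership.loc["a"].tolist() == [True, False]

    def test_identical_sets(self):
        _, counts = compare_marked_sets({"s1": ["a", "b"], "s2": ["a", "b"]})
        assert counts["all"] == counts["any"] == 2

    def test_random_sets_against_set_ops(self, rng):
        ids = [f"g{i}" for i in range(50)]
        s1 = set(rng.choice(ids, 20, replace=False))
        s2 = set(rng.choice(ids, 25, replace=False))
        s3 = set(rng.choice(ids, 10, replace=False))
        _, counts = compare_marked_sets({"a": s1, "b": s2, "c": s3})
        assert counts["all"] == len(s1 & s2 & s3)
        assert counts["any"] == len(s1 | s2 | s3)


class TestMarkedGeneRecovery:
    def test_true_domains_recovered_with_few_unexplained_calls(self, default_analysis):
        """Genes with true domains are found; marked calls not explained by a
        true domain overlapping the gene's annotation window stay rare."""
        cfg, exp, result = default_analysis
        truth = exp.truth.genes.set_index("gene_id")
        marked_true = set(truth.index[truth["marked"]])
        unmarked = set(truth.index) - marked_true

        # genes whose window genuinely overlaps a true marked body by >150 bp
        from chiprx._intervals import overlap_with_merged

        win = gene_windows(exp.genes).set_index("gene_id")
        bodies = truth[truth["marked"]]
        bs = np.minimum(bodies["tss"], bodies["tes"]).to_numpy()
        be = np.maximum(bodies["tss"], bodies["tes"]).to_numpy()
        ms, me = merge_intervals(bs, be)
        ov = overlap_with_merged(
            win["window_start"].to_numpy(), win["window_end"].to_numpy(), ms, me
        )
        explained = set(win.index[ov > 150])

        for cond in ("ctrl", "treat"):
            called = set(result.marked[cond]["gene_id"])
            sensitivity = len(called & marked_true) / len(marked_true)
            unexplained = len((called & unmarked) - explained) / len(unmarked)
            assert sensitivity >= 0.9
            assert unexplained <= 0.02
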