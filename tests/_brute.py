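"""Per-base brute-force oracles used to validate the interval arithmetic.

Everything here works on explicit base sets, deliberately independent of
the vectorized implementations under test.
"""

from __future__ import annotations

import numpy as np


def bases(intervals) -> set[int]:
    """All covered base positions of a list of (start, end) half-open pairs."""
    out: set[int] = set()
    for s, e in intervals:
        out.update(range(int(s), int(e)))
    return out


def brute_total_overlap(query, others) -> int:
    """Overlap (bp) of one (start, end) query with the union of others."""
    return len(set(range(int(query[0]), int(query[1]))) & bases(others))


def brute_reproducible_peaks(rep1, rep2, min_frac=0.10):
    """The 10%-rule keep/merge operation done per base.

    Returns the set of covered bases of the merged kept peaks.
    """
    kept = []
    for a in rep1:
        if brute_total_overlap(a, rep2) > min_frac * (a[1] - a[0]):
            kept.append(a)
    for b in rep2:
        if brute_total_overlap(b, rep1) > min_frac * (b[1] - b[0]):
            kept.append(b)
    return bases(kept)


def brute_marked_genes(peaks, windows, min_overlap_bp=150):
    """gene_id -> overlap bp for genes strictly above the threshold."""
    peak_bases = bases(peaks)
    out = {}
    for gene_id, (ws, we) in windows.items():
        ov = len(set(range(int(ws), int(we))) & peak_bases)
        if ov > min_overlap_bp:
            out[gene_id] = ov
    return out


def brute_union_by_gene(peaks, windows):
    """gene_id -> covered-base set of peaks clipped to the gene window."""
    peak_bases = bases(peaks)
    out = {}
    for gene_id, (ws, we) in windows.items():
        hit = set(range(int(ws), int(we))) & peak_bases
        if hit:
            out[gene_id] = hit
    return out


def brute_count_reads(reads, gene_regions):
    """gene_id -> number of reads overlapping >=1 bp of the gene's regions."""
    out = {}
    for gene_id, regions in gene_regions.items():
        region_bases = bases(regions)
        n = 0
        for s, e in reads:
            if set(range(int(s), int(e))) & region_bases:
                n += 1
        out[gene_id] = n
    return out


def brute_bh(pvalues):
    """Step-up BH by direct definition."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p)
    out = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        prev = min(prev, p[idx] * m / rank)
        out[idx] = prev
    return out
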