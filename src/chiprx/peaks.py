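"""Peak calling (Poisson stand-in), reproducibility filtering and gene annotation.

The built-in caller is a deliberately simple sliding-window Poisson scorer:
it exists so the whole pipeline runs self-contained, and its narrowPeak
output is format-compatible with external callers (MACS2 peak files can be
substituted per sample). The reproducibility rule keeps a peak iff its
total overlap with the other replicate's peaks exceeds 10% of its own
length (strict, applied symmetrically to both replicates); kept peaks are
interval-merged. The annotation window of a gene runs from 250 bp upstream
of the TSS to the TES, and a gene counts as marked when the summed overlap
between its window and the merged peaks is strictly greater than 150 bp.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._intervals import (
    clip_intervals,
    count_overlapping,
    merge_intervals,
    overlap_with_merged,
)
from ._stats import bh_adjust
from .model import TARGET, AlignedReadSet, genes_to_frame, peaks_to_frame


@dataclass(frozen=True)
class PeakCallerParams:
    """Sliding-window Poisson caller settings.

    ``lambda_mode``: "local-input" rates each window against
    max(global IP rate, input-local rate scaled to IP depth); "global"
    uses the global IP rate only.
    """

    window: int = 200
    step: int = 50
    merge_gap: int = 100
    qvalue_threshold: float = 0.01
    lambda_mode: str = "local-input"

    def __post_init__(self) -> None:
        if not (self.window >= self.step > 0):
            raise ValueError("need window >= step > 0")
        if not 0.0 < self.qvalue_threshold < 1.0:
            raise ValueError("qvalue_threshold must be in (0,1)")
        if self.merge_gap < 0:
            raise ValueError("merge_gap must be >= 0")
        if self.lambda_mode not in {"global", "local-input"}:
            raise ValueError(f"unknown lambda_mode {self.lambda_mode!r}")


def call_peaks_poisson(
    ip: AlignedReadSet,
    input_: AlignedReadSet | None = None,
    params: PeakCallerParams = PeakCallerParams(),
    chrom_lengths: dict | None = None,
) -> pd.DataFrame:
    """Call enriched regions on the target genome.

    Windows of ``params.window`` bp every ``params.step`` bp are scored by
    the Poisson upper-tail probability of the IP read count under
    λ = max(global target rate, input-estimated local rate scaled to IP
    depth) per window; window p-values are BH-adjusted genome-wide and
    significant windows within ``merge_gap`` bp are merged into peaks
    carrying the minimum window q-value.
    """
    ip_reads = ip.subset(TARGET)
    if not len(ip_reads):
        warnings.warn(f"{ip.sample_id}: empty IP, no peaks called", stacklevel=2)
        return peaks_to_frame(pd.DataFrame(columns=["chrom", "start", "end", "score", "qvalue"]))
    in_reads = input_.subset(TARGET) if input_ is not None else None

    if chrom_lengths is None:
        chrom_lengths = {
            chrom: int(grp["end"].max())
            for chrom, grp in ip_reads.groupby("chrom", sort=True)
        }
    genome_len = float(sum(chrom_lengths.values()))
    mean_read_len = float((ip_reads["end"] - ip_reads["start"]).mean())
    # expected reads overlapping a window under a uniform global rate
    lam_global = len(ip_reads) * (params.window + mean_read_len) / genome_len
    depth_ratio = (
        len(ip_reads) / len(in_reads) if in_reads is not None and len(in_reads) else 0.0
    )

    all_windows = []
    for chrom, length in sorted(chrom_lengths.items()):
        grp = ip_reads[ip_reads["chrom"] == chrom]
        if not len(grp):
            continue
        w_starts = np.arange(0, max(length - params.window, 0) + 1, params.step, dtype=np.int64)
        if not w_starts.size:
            w_starts = np.array([0], dtype=np.int64)
        w_ends = w_starts + params.window
        k = count_overlapping(
            np.sort(grp["start"].to_numpy(np.int64)),
            np.sort(grp["end"].to_numpy(np.int64)),
            w_starts, w_ends,
        )
        lam = np.full(w_starts.size, lam_global)
        if params.lambda_mode == "local-input" and in_reads is not None and len(in_reads):
            igrp = in_reads[in_reads["chrom"] == chrom]
            if len(igrp):
                k_in = count_overlapping(
                    np.sort(igrp["start"].to_numpy(np.int64)),
                    np.sort(igrp["end"].to_numpy(np.int64)),
                    w_starts, w_ends,
                )
                lam = np.maximum(lam, k_in * depth_ratio)
        pvals = stats.poisson.sf(k - 1, lam)
        all_windows.append(
            pd.DataFrame({"chrom": chrom, "start": w_starts, "end": w_ends, "pvalue": pvals})
        )
    win = pd.concat(all_windows, ignore_index=True)
    win["qvalue"] = bh_adjust(win["pvalue"].to_numpy())
    sig = win[win["qvalue"] < params.qvalue_threshold]

    peak_rows = []
    for chrom, grp in sig.groupby("chrom", sort=True):
        s = grp["start"].to_numpy(np.int64)
        e = grp["end"].to_numpy(np.int64)
        ms, me = merge_intervals(s, e, gap=params.merge_gap)
        # min q-value of the windows inside each merged peak
        q = grp["qvalue"].to_numpy()
        for a, b in zip(ms, me):
            inside = (s >= a) & (e <= b)
            qmin = float(q[inside].min())
            peak_rows.append(
                {"chrom": chrom, "start": int(a), "end": int(b),
                 "score": float(-np.log10(max(qmin, 1e-300))), "qvalue": qmin}
            )
    return peaks_to_frame(pd.DataFrame(peak_rows, columns=["chrom", "start", "end", "score", "qvalue"]))


def filter_peaks_fdr(peaks: pd.DataFrame, threshold: float = 0.01) -> pd.DataFrame:
    """Keep peaks with qvalue strictly below the FDR threshold."""
    return peaks[peaks["qvalue"] < threshold].reset_index(drop=True)


def intersect_replicate_peaks(
    rep1: pd.DataFrame,
    rep2: pd.DataFrame,
    min_frac: float = 0.10,
    mode: str = "symmetric",
) -> pd.DataFrame:
    """Reproducible peaks across two biological replicates.

    A peak is kept iff its total overlap with the other replicate's peaks
    is strictly greater than ``min_frac`` × its own length. In the default
    "symmetric" mode the rule is applied to the peaks of both replicates
    and all kept peaks are interval-merged; "one-sided" tests and keeps
    rep1 peaks only. Inputs are expected to be pre-filtered to the desired
    FDR. The merged output carries the minimum contributing q-value.
    """
    if mode not in {"symmetric", "one-sided"}:
        raise ValueError(f"unknown mode {mode!r}")
    rep1 = peaks_to_frame(rep1)
    rep2 = peaks_to_frame(rep2)

    def _kept(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
        if not len(a) or not len(b):
            return a.iloc[0:0]
        keep_rows = []
        b_by_chrom = {c: g for c, g in b.groupby("chrom")}
        for chrom, grp in a.groupby("chrom", sort=False):
            other = b_by_chrom.get(chrom)
            if other is None:
                continue
            ms, me = merge_intervals(
                other["start"].to_numpy(np.int64), other["end"].to_numpy(np.int64)
            )
            s = grp["start"].to_numpy(np.int64)
            e = grp["end"].to_numpy(np.int64)
            ov = overlap_with_merged(s, e, ms, me)
            keep_rows.append(grp[ov > min_frac * (e - s)])
        return pd.concat(keep_rows) if keep_rows else a.iloc[0:0]

    kept = [_kept(rep1, rep2)]
    if mode == "symmetric":
        kept.append(_kept(rep2, rep1))
    kept_df = pd.concat(kept, ignore_index=True)
    if not len(kept_df):
        return peaks_to_frame(kept_df)

    out_rows = []
    for chrom, grp in kept_df.groupby("chrom", sort=True):
        s = grp["start"].to_numpy(np.int64)
        e = grp["end"].to_numpy(np.int64)
        ms, me = merge_intervals(s, e)
        q = grp["qvalue"].to_numpy()
        for a, b in zip(ms, me):
            inside = (s < b) & (e > a)
            out_rows.append(
                {"chrom": chrom, "start": int(a), "end": int(b),
                 "score": float(grp["score"].to_numpy()[inside].max()),
                 "qvalue": float(q[inside].min())}
            )
    return peaks_to_frame(pd.DataFrame(out_rows))


# ---------------------------------------------------------------------------
# gene annotation


def gene_windows(genes: pd.DataFrame, upstream: int = 250) -> pd.DataFrame:
    """Annotation window per gene: TSS − upstream through TES, strand-aware.

    0-based half-open: [tss−u, tes) on +, [tes, tss+u) on −; clipped at 0.
    """
    genes = genes_to_frame(genes)
    plus = genes["strand"] == "+"
    w_start = np.where(plus, genes["tss"] - upstream, genes["tes"])
    w_end = np.where(plus, genes["tes"], genes["tss"] + upstream)
    out = genes[["gene_id", "chrom", "strand"]].copy()
    out["window_start"] = np.maximum(w_start, 0).astype(np.int64)
    out["window_end"] = w_end.astype(np.int64)
    return out


def annotate_genes(
    peaks: pd.DataFrame,
    genes: pd.DataFrame,
    upstream: int = 250,
    min_overlap_bp: int = 150,
) -> pd.DataFrame:
    """Marked genes: summed window/peak overlap strictly greater than 150 bp.

    Returns one row per marked gene: gene_id, n_intervals (merged peak
    intervals overlapping the window), overlap_bp.
    """
    peaks = peaks_to_frame(peaks)
    win = gene_windows(genes, upstream=upstream)
    rows = []
    merged_by_chrom = {}
    for chrom, grp in peaks.groupby("chrom"):
        merged_by_chrom[chrom] = merge_intervals(
            grp["start"].to_numpy(np.int64), grp["end"].to_numpy(np.int64)
        )
    for chrom, wgrp in win.groupby("chrom", sort=False):
        if chrom not in merged_by_chrom:
            continue
        ms, me = merged_by_chrom[chrom]
        ws = wgrp["window_start"].to_numpy(np.int64)
        we = wgrp["window_end"].to_numpy(np.int64)
        ov = overlap_with_merged(ws, we, ms, me)
        lo = np.searchsorted(me, ws, side="right")
        hi = np.searchsorted(ms, we, side="left")
        n_int = np.maximum(hi - lo, 0)
        marked = ov > min_overlap_bp
        sub = wgrp[marked]
        rows.append(
            pd.DataFrame(
                {"gene_id": sub["gene_id"], "n_intervals": n_int[marked],
                 "overlap_bp": ov[marked]}
            )
        )
    if not rows:
        return pd.DataFrame(columns=["gene_id", "n_intervals", "overlap_bp"])
    return pd.concat(rows, ignore_index=True)


def union_peaks_by_gene(
    peak_sets: list[pd.DataFrame],
    genes: pd.DataFrame,
    upstream: int = 250,
) -> pd.DataFrame:
    """Unique peak coordinates per gene across all samples.

    For each gene, the interval union of every sample's peaks overlapping
    its annotation window, clipped to the window. Genes with no overlapping
    peak in any sample are absent. Returns gene_id/chrom/start/end rows
    with non-overlapping intervals per gene.
    """
    all_peaks = peaks_to_frame(pd.concat([peaks_to_frame(p) for p in peak_sets], ignore_index=True))
    win = gene_windows(genes, upstream=upstream)
    merged_by_chrom = {
        chrom: merge_intervals(g["start"].to_numpy(np.int64), g["end"].to_numpy(np.int64))
        for chrom, g in all_peaks.groupby("chrom")
    }
    rows = []
    for row in win.itertuples():
        hit = merged_by_chrom.get(row.chrom)
        if hit is None:
            continue
        ms, me = hit
        cs, ce = clip_intervals(ms, me, row.window_start, row.window_end)
        for a, b in zip(cs, ce):
            rows.append({"gene_id": row.gene_id, "chrom": row.chrom, "start": int(a), "end": int(b)})
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


def compare_marked_sets(marked_sets: dict) -> tuple[pd.DataFrame, dict]:
    """Membership table and intersection counts across >=2 marked-gene sets.

    Returns (per-gene boolean membership DataFrame, counts with the number
    of genes marked in all sets, in any set, and in each set).
    """
    if len(marked_sets) < 2:
        raise ValueError("need at least 2 marked-gene sets")
    sets = {name: set(ids) for name, ids in marked_sets.items()}
    universe = sorted(set().union(*sets.values()))
    membership = pd.DataFrame(
        {name: [g in s for g in universe] for name, s in sets.items()},
        index=pd.Index(universe, name="gene_id"),
    )
    counts = {name: int(membership[name].sum()) for name in sets}
    counts["all"] = int(membership.all(axis=1).sum())
    counts["any"] = int(len(universe))
    return membership, counts
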