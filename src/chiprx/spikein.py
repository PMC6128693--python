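"""Per-replicate spike-in (Rx) scaling factors and signal-track scaling.

The scaling factor of a replicate is

    alpha = r / Nd_IP,      r = 100 * Nd_in / (Na_in + Nd_in)

where Nd_IP is the number of IP reads (in millions) aligning to the
spike-in genome, and r is the percentage of input-library reads aligning
to the spike-in genome (Nd_in, Na_in: spike-in and target input reads, in
millions). Quantifying r per replicate absorbs technical variation in the
amount of spike-in chromatin actually added to each input. No further
library-size normalization is applied on top of alpha: alpha already
embeds input-composition correction, and avoiding per-sample total-count
normalization is the point of the spike-in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import TARGET, AlignedReadSet, Track


@dataclass(frozen=True)
class RxFactors:
    """Spike-in bookkeeping for one biological replicate (counts in millions)."""

    sample_id: str
    Na_IP: float
    Nd_IP: float
    Na_in: float
    Nd_in: float
    r: float
    alpha: float


def partition_counts(readset: AlignedReadSet) -> tuple[float, float]:
    """(target, spike-in) read counts of a library, in millions.

    The two tallies always sum to the total read count / 1e6 exactly.
    """
    return readset.n_target / 1e6, readset.n_spikein / 1e6


def compute_input_fraction(Nd_in: float, Na_in: float) -> float:
    """Percent spike-in reads in an input library: 100·Nd_in/(Na_in + Nd_in)."""
    total = Na_in + Nd_in
    if total <= 0:
        raise ValueError("empty input library: Na_in + Nd_in must be > 0")
    return 100.0 * Nd_in / total


def compute_rx_factor(r: float, Nd_IP: float, sample_id: str = "?") -> float:
    """Rx scaling factor alpha = r / Nd_IP (Nd_IP in millions)."""
    if Nd_IP <= 0:
        raise ValueError(
            f"library {sample_id}: no spike-in reads in IP (Nd_IP={Nd_IP}); "
            "alpha is undefined"
        )
    return r / Nd_IP


def compute_rx_factor_original(Nd_IP: float) -> float:
    """Comparison mode: the unmodified reference-exogenous-genome factor 1/Nd_IP.

    Assumes an invariable amount of spike-in chromatin per input sample, so
    it does not correct for per-replicate spike-in loading differences.
    Provided for comparison only; :func:`compute_rx_factor` is the default.
    """
    if Nd_IP <= 0:
        raise ValueError("Nd_IP must be > 0")
    return 1.0 / Nd_IP


def rx_factors_for_replicate(ip: AlignedReadSet, input_: AlignedReadSet) -> RxFactors:
    """Rx factors of one biological replicate from its deduplicated IP+input pair."""
    if (ip.condition, ip.replicate) != (input_.condition, input_.replicate):
        raise ValueError(
            f"IP {ip.sample_id} and input {input_.sample_id} are not the same replicate"
        )
    na_ip, nd_ip = partition_counts(ip)
    na_in, nd_in = partition_counts(input_)
    r = compute_input_fraction(nd_in, na_in)
    alpha = compute_rx_factor(r, nd_ip, sample_id=ip.sample_id)
    return RxFactors(
        sample_id=ip.sample_id,
        Na_IP=na_ip, Nd_IP=nd_ip, Na_in=na_in, Nd_in=nd_in,
        r=r, alpha=alpha,
    )


RX_TABLE_COLUMNS = ["sample_id", "Na_IP", "Nd_IP", "Na_in", "Nd_in", "r", "alpha"]


def rx_factors_table(factors: list[RxFactors]) -> pd.DataFrame:
    """RxFactors as the canonical TSV layout."""
    return pd.DataFrame([f.__dict__ for f in factors], columns=RX_TABLE_COLUMNS)


# ---------------------------------------------------------------------------
# signal tracks


def scale_track(track: Track, alpha: float) -> Track:
    """Multiply every segment value by alpha; boundaries unchanged."""
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    seg = track.segments.copy()
    seg["value"] = seg["value"] * alpha
    return Track(seg)


def track_from_reads(readset: AlignedReadSet, genome: str = TARGET) -> Track:
    """Per-base read-coverage pileup of one genome as a piecewise track."""
    reads = readset.subset(genome)
    rows = []
    for chrom, grp in reads.groupby("chrom", sort=True):
        starts = grp["start"].to_numpy(np.int64)
        ends = grp["end"].to_numpy(np.int64)
        bounds = np.unique(np.concatenate((starts, ends)))
        delta = np.zeros(bounds.size, dtype=np.int64)
        np.add.at(delta, np.searchsorted(bounds, starts), 1)
        np.add.at(delta, np.searchsorted(bounds, ends), -1)
        cov = np.cumsum(delta)[:-1]
        seg = pd.DataFrame(
            {"chrom": chrom, "start": bounds[:-1], "end": bounds[1:], "value": cov.astype(float)}
        )
        rows.append(seg[seg["value"] > 0])
    if not rows:
        return Track(pd.DataFrame(columns=["chrom", "start", "end", "value"]))
    return Track(pd.concat(rows, ignore_index=True))


def _coalesce(seg: pd.DataFrame) -> pd.DataFrame:
    """Merge adjacent segments with identical value (per chromosome)."""
    if not len(seg):
        return seg
    same = (
        (seg["chrom"] == seg["chrom"].shift())
        & (seg["start"] == seg["end"].shift())
        & (seg["value"] == seg["value"].shift())
    )
    grp = (~same).cumsum()
    out = seg.groupby(grp, sort=False).agg(
        chrom=("chrom", "first"), start=("start", "first"),
        end=("end", "last"), value=("value", "first"),
    )
    return out.reset_index(drop=True)


def average_tracks(tracks: list[Track]) -> Track:
    """Arithmetic mean of >=2 piecewise tracks on the union of breakpoints.

    Positions where a track has no segment contribute 0 for that track;
    regions covered by no track at all are omitted from the output.
    """
    if len(tracks) < 2:
        raise ValueError("need at least 2 tracks to average")
    chroms = sorted({c for t in tracks for c in t.segments["chrom"].unique()})
    pieces = []
    for chrom in chroms:
        per_track = [
            t.segments[t.segments["chrom"] == chrom].sort_values("start")
            for t in tracks
        ]
        bounds = np.unique(
            np.concatenate(
                [np.concatenate((d["start"].to_numpy(), d["end"].to_numpy()))
                 for d in per_track if len(d)]
            )
        )
        seg_s, seg_e = bounds[:-1], bounds[1:]
        values = np.zeros((len(tracks), seg_s.size))
        covered = np.zeros(seg_s.size, dtype=bool)
        for i, d in enumerate(per_track):
            if not len(d):
                continue
            ts = d["start"].to_numpy(np.int64)
            te = d["end"].to_numpy(np.int64)
            tv = d["value"].to_numpy(float)
            idx = np.searchsorted(ts, seg_s, side="right") - 1
            ok = (idx >= 0) & (seg_s < te[np.maximum(idx, 0)])
            values[i, ok] = tv[idx[ok]]
            covered |= ok
        mean = values.mean(axis=0)
        piece = pd.DataFrame(
            {"chrom": chrom, "start": seg_s[covered], "end": seg_e[covered],
             "value": mean[covered]}
        )
        pieces.append(piece)
    if not pieces:
        return Track(pd.DataFrame(columns=["chrom", "start", "end", "value"]))
    return Track(_coalesce(pd.concat(pieces, ignore_index=True)))
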