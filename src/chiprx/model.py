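"""Domain types and coordinate conventions.

All genomic coordinates are 0-based, half-open. Gene models keep the
biological orientation: ``tss`` is always the transcription start, so
``tss < tes`` on the + strand and ``tes < tss`` on the − strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TARGET = "target"
SPIKEIN = "spikein"

#: default chromosome-name prefix marking spike-in contigs in a
#: concatenated target+spike-in reference
DEFAULT_SPIKEIN_PREFIX = "dmel_"

READ_COLUMNS = ["chrom", "start", "end", "strand"]


@dataclass(frozen=True)
class GenomeTag:
    """Partition of chromosome names into target and spike-in genomes.

    Any chromosome whose name starts with ``chrom_prefix`` belongs to the
    spike-in (exogenous) genome; every other name is the target genome.
    Classification is deterministic given the prefix.
    """

    chrom_prefix: str = DEFAULT_SPIKEIN_PREFIX

    def classify(self, chrom: str) -> str:
        return SPIKEIN if chrom.startswith(self.chrom_prefix) else TARGET

    def classify_array(self, chroms: pd.Series | np.ndarray) -> np.ndarray:
        is_spike = pd.Series(chroms, dtype="string").str.startswith(self.chrom_prefix)
        return np.where(is_spike.to_numpy(dtype=bool), SPIKEIN, TARGET)


@dataclass(frozen=True)
class ReadInterval:
    """A single aligned read as a genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")


@dataclass
class AlignedReadSet:
    """Aligned reads of one sequencing library (sample × role).

    ``reads`` is a DataFrame with columns chrom/start/end/strand. Reads are
    tagged target vs spike-in by chromosome-name prefix; tallies of both
    tags are computed once and retrievable in O(1).
    """

    sample_id: str
    condition: str
    replicate: int
    role: str  # "IP" or "input"
    reads: pd.DataFrame
    genome_tag: GenomeTag = field(default_factory=GenomeTag)
    target_chroms: frozenset[str] | None = None
    deduplicated: bool = False
    n_duplicates_removed: int = 0

    def __post_init__(self) -> None:
        if self.role not in {"IP", "input"}:
            raise ValueError(f"role must be 'IP' or 'input', got {self.role!r}")
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")
        missing = [c for c in READ_COLUMNS if c not in self.reads.columns]
        if missing:
            raise ValueError(f"reads missing columns {missing}")
        self.reads = self.reads.reset_index(drop=True)
        tags = self.genome_tag.classify_array(self.reads["chrom"])
        self._is_spikein = tags == SPIKEIN
        self._n_spikein = int(self._is_spikein.sum())
        self._n_target = int(len(self.reads) - self._n_spikein)
        # chromosomes matching neither the spike-in prefix nor a declared
        # target set are still counted as target, but tallied as a warning
        self.n_unrecognized = 0
        if self.target_chroms is not None:
            known = self.reads["chrom"].isin(self.target_chroms).to_numpy()
            unrec = (~known) & (~self._is_spikein)
            self.n_unrecognized = int(unrec.sum())
            if self.n_unrecognized:
                warnings.warn(
                    f"{self.sample_id}: {self.n_unrecognized} reads on "
                    "chromosomes matching neither genome convention; "
                    "classified as target",
                    stacklevel=2,
                )

    def __len__(self) -> int:
        return len(self.reads)

    @property
    def n_target(self) -> int:
        return self._n_target

    @property
    def n_spikein(self) -> int:
        return self._n_spikein

    def subset(self, genome: str) -> pd.DataFrame:
        """Reads belonging to one genome ('target' or 'spikein')."""
        if genome == TARGET:
            return self.reads.loc[~self._is_spikein]
        if genome == SPIKEIN:
            return self.reads.loc[self._is_spikein]
        raise ValueError(f"unknown genome {genome!r}")

    def genome_of(self, read: ReadInterval) -> str:
        return self.genome_tag.classify(read.chrom)


def deduplicate_reads(readset: AlignedReadSet) -> AlignedReadSet:
    """Drop positional duplicates: at most one read per (chrom, start, end, strand).

    This is the single-end positional-duplicate convention; the number of
    reads removed is recorded on the returned set.
    """
    deduped = readset.reads.drop_duplicates(subset=READ_COLUMNS)
    return AlignedReadSet(
        sample_id=readset.sample_id,
        condition=readset.condition,
        replicate=readset.replicate,
        role=readset.role,
        reads=deduped,
        genome_tag=readset.genome_tag,
        target_chroms=readset.target_chroms,
        deduplicated=True,
        n_duplicates_removed=len(readset.reads) - len(deduped),
    )


@dataclass(frozen=True)
class GeneModel:
    """A gene as TSS/TES positions; tss is the transcription start."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be + or -, got {self.strand!r}")
        if self.tss == self.tes:
            raise ValueError(f"{self.gene_id}: tss == tes")
        if self.strand == "+" and not self.tss < self.tes:
            raise ValueError(f"{self.gene_id}: + strand requires tss < tes")
        if self.strand == "-" and not self.tes < self.tss:
            raise ValueError(f"{self.gene_id}: - strand requires tes < tss")


GENE_COLUMNS = ["gene_id", "chrom", "strand", "tss", "tes"]


def genes_to_frame(genes) -> pd.DataFrame:
    """Gene models (iterable of GeneModel or DataFrame) as a validated frame."""
    if isinstance(genes, pd.DataFrame):
        df = genes
    else:
        df = pd.DataFrame([g.__dict__ for g in genes])
    missing = [c for c in GENE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"gene table missing columns {missing}")
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate gene_id(s): {sorted(set(dup))}")
    return df.reset_index(drop=True)


@dataclass(frozen=True)
class Peak:
    """A called enrichment peak with an FDR-style q-value."""

    chrom: str
    start: int
    end: int
    score: float = 0.0
    qvalue: float = 1.0

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"peak {self.chrom}:{self.start}-{self.end}: start >= end")
        if not 0.0 <= self.qvalue <= 1.0:
            raise ValueError(f"qvalue {self.qvalue} outside [0,1]")


PEAK_COLUMNS = ["chrom", "start", "end", "score", "qvalue"]


def peaks_to_frame(peaks) -> pd.DataFrame:
    """Peak collection (iterable of Peak or DataFrame) as a sorted frame."""
    if isinstance(peaks, pd.DataFrame):
        df = peaks.copy()
        if "score" not in df.columns:
            df["score"] = 0.0
        if "qvalue" not in df.columns:
            df["qvalue"] = 1.0
    else:
        df = pd.DataFrame([p.__dict__ for p in peaks], columns=PEAK_COLUMNS)
    df = df[PEAK_COLUMNS].sort_values(["chrom", "start", "end"], kind="stable")
    return df.reset_index(drop=True)


@dataclass
class Track:
    """A piecewise-constant signal (bedGraph semantics).

    ``segments``: DataFrame chrom/start/end/value, sorted, with
    non-overlapping intervals per chromosome.
    """

    segments: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.segments
        missing = [c for c in ("chrom", "start", "end", "value") if c not in df.columns]
        if missing:
            raise ValueError(f"track missing columns {missing}")
        df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        bad = df["start"] >= df["end"]
        if bad.any():
            row = df[bad].iloc[0]
            raise ValueError(f"empty/negative segment {row.chrom}:{row.start}-{row.end}")
        same_chrom = df["chrom"].shift(-1) == df["chrom"]
        overlap = same_chrom & (df["end"] > df["start"].shift(-1))
        if overlap.any():
            i = int(np.flatnonzero(overlap.to_numpy())[0])
            a, b = df.iloc[i], df.iloc[i + 1]
            raise ValueError(
                "overlapping segments "
                f"{a.chrom}:{a.start}-{a.end} and {b.chrom}:{b.start}-{b.end}"
            )
        self.segments = df

    def value_at(self, chrom: str, pos: int) -> float:
        """Signal at a single position (0 where uncovered)."""
        df = self.segments[self.segments["chrom"] == chrom]
        hit = df[(df["start"] <= pos) & (pos < df["end"])]
        return float(hit["value"].iloc[0]) if len(hit) else 0.0

    def __eq__(self, other) -> bool:
        if not isinstance(other, Track):
            return NotImplemented
        return self.segments.equals(other.segments)
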