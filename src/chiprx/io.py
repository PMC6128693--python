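"""Readers and writers for the standard formats the pipeline touches.

BED, narrowPeak, bedGraph and the TSV gene table are parsed with pandas;
SAM/BAM goes through pysam. External coordinates follow each format's
convention (BED-family 0-based half-open, GFF3 1-based inclusive); all
internal coordinates are 0-based half-open.
"""

from __future__ import annotations

import math
import os

import numpy as np
import pandas as pd

from .model import (
    GENE_COLUMNS,
    AlignedReadSet,
    GenomeTag,
    Track,
    genes_to_frame,
    peaks_to_frame,
)

# ---------------------------------------------------------------------------
# alignments


def _reads_from_bed(path: str) -> pd.DataFrame:
    try:
        raw = pd.read_csv(
            path, sep="\t", header=None, comment="#", dtype={0: str},
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["chrom", "start", "end", "strand"])
    if raw.shape[1] < 3:
        raise ValueError(f"{path}: BED needs >=3 columns, found {raw.shape[1]}")
    df = pd.DataFrame(
        {
            "chrom": raw[0].astype(str),
            "start": pd.to_numeric(raw[1], errors="coerce"),
            "end": pd.to_numeric(raw[2], errors="coerce"),
            "strand": raw[5].astype(str) if raw.shape[1] >= 6 else ".",
        }
    )
    bad = df["start"].isna() | df["end"].isna()
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise ValueError(f"{path}: unparseable coordinates at line {line}")
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    bad = (df["start"] < 0) | (df["start"] >= df["end"])
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise ValueError(
            f"{path}: invalid interval at line {line} (need 0 <= start < end)"
        )
    bad = ~df["strand"].isin(["+", "-", "."])
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise ValueError(f"{path}: invalid strand at line {line}")
    return df


def _reads_from_bam(path: str) -> pd.DataFrame:
    import pysam

    chroms, starts, ends, strands = [], [], [], []
    # "rb" for BAM, "r" autodetects SAM text
    mode = "rb" if path.endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode) as fh:
        for aln in fh.fetch(until_eof=True):
            if aln.is_unmapped or aln.reference_end is None:
                continue
            chroms.append(aln.reference_name)
            starts.append(aln.reference_start)
            ends.append(aln.reference_end)
            strands.append("-" if aln.is_reverse else "+")
    return pd.DataFrame(
        {
            "chrom": pd.Series(chroms, dtype=str),
            "start": pd.Series(starts, dtype=np.int64),
            "end": pd.Series(ends, dtype=np.int64),
            "strand": pd.Series(strands, dtype=str),
        }
    )


def read_alignments(
    path: str,
    spikein_prefix: str = "dmel_",
    format: str | None = None,
    sample_id: str | None = None,
    condition: str = "",
    replicate: int = 1,
    role: str = "IP",
    target_chroms=None,
) -> AlignedReadSet:
    """Load aligned reads from BED (3+ columns) or SAM/BAM into an AlignedReadSet.

    Every read is tagged target/spike-in by chromosome-name prefix match.
    ``format`` is "BED" or "BAM"; inferred from the extension when omitted.
    """
    if format is None:
        ext = os.path.splitext(path)[1].lower()
        format = "BAM" if ext in {".bam", ".sam"} else "BED"
    fmt = format.upper()
    if fmt == "BED":
        reads = _reads_from_bed(path)
    elif fmt in {"BAM", "SAM"}:
        reads = _reads_from_bam(path)
    else:
        raise ValueError(f"unknown alignment format {format!r}")
    return AlignedReadSet(
        sample_id=sample_id or os.path.basename(path),
        condition=condition,
        replicate=replicate,
        role=role,
        reads=reads,
        genome_tag=GenomeTag(spikein_prefix),
        target_chroms=frozenset(target_chroms) if target_chroms is not None else None,
    )


def write_reads_bed(readset: AlignedReadSet, path: str) -> None:
    df = readset.reads
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"],
            "end": df["end"],
            "name": ".",
            "score": 0,
            "strand": df["strand"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# gene models


def read_gene_models(path: str, format: str | None = None) -> pd.DataFrame:
    """Read gene models from GFF3 or a TSV gene table.

    Both external formats are 1-based inclusive; the returned frame
    (gene_id/chrom/strand/tss/tes) is 0-based half-open with tss/tes
    oriented by strand. Duplicate gene ids and unknown strands are errors.
    """
    if format is None:
        ext = os.path.splitext(path)[1].lower()
        format = "GFF3" if ext in {".gff", ".gff3"} else "TSV"
    fmt = format.upper()
    if fmt == "GFF3":
        return _genes_from_gff3(path)
    if fmt == "TSV":
        return _genes_from_tsv(path)
    raise ValueError(f"unknown gene-model format {format!r}")


def _orient(start1: int, end1: int, strand: str, where: str) -> tuple[int, int]:
    """1-based inclusive (start1, end1) -> 0-based half-open (tss, tes)."""
    if strand == "+":
        return start1 - 1, end1
    if strand == "-":
        return end1, start1 - 1
    raise ValueError(f"{where}: unknown strand {strand!r}")


def _genes_from_gff3(path: str) -> pd.DataFrame:
    """Extract `gene` features from GFF3 (gene_id from ID= attribute)."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _src, ftype, start1, end1, _score, strand, _phase, attrs = fields
            if ftype != "gene":
                continue
            gene_id = None
            for item in attrs.split(";"):
                key, _, val = item.partition("=")
                if key.strip() == "ID":
                    gene_id = val.strip()
            if gene_id is None:
                raise ValueError(f"{path}:{lineno}: gene feature without ID attribute")
            tss, tes = _orient(int(start1), int(end1), strand, f"{path}:{lineno}")
            records.append(
                {"gene_id": gene_id, "chrom": chrom, "strand": strand, "tss": tss, "tes": tes}
            )
    return genes_to_frame(pd.DataFrame(records, columns=GENE_COLUMNS))


def _genes_from_tsv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    required = ["gene_id", "chrom", "strand", "start", "end"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: gene TSV missing columns {missing}")
    tss, tes = [], []
    for row in df.itertuples():
        a, b = _orient(int(row.start), int(row.end), row.strand, f"{path} gene {row.gene_id}")
        tss.append(a)
        tes.append(b)
    out = pd.DataFrame(
        {
            "gene_id": df["gene_id"],
            "chrom": df["chrom"],
            "strand": df["strand"],
            "tss": tss,
            "tes": tes,
        }
    )
    return genes_to_frame(out)


def write_gene_models_gff3(genes: pd.DataFrame, path: str, source: str = "chiprx") -> None:
    """Write gene models as GFF3 `gene` features (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples():
            if row.strand == "+":
                start1, end1 = row.tss + 1, row.tes
            else:
                start1, end1 = row.tes + 1, row.tss
            fh.write(
                f"{row.chrom}\t{source}\tgene\t{start1}\t{end1}\t.\t{row.strand}\t.\t"
                f"ID={row.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# narrowPeak

_NP_COLS = [
    "chrom", "start", "end", "name", "score",
    "strand", "signalValue", "pValue", "qValue", "peak",
]


def read_narrowpeak(path: str) -> pd.DataFrame:
    """Read ENCODE narrowPeak; column 9 (-log10 q) is converted to qvalue."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    except pd.errors.EmptyDataError:
        return peaks_to_frame(pd.DataFrame(columns=["chrom", "start", "end", "score", "qvalue"]))
    if df.shape[1] != 10:
        raise ValueError(f"{path}: narrowPeak needs exactly 10 columns, found {df.shape[1]}")
    df.columns = _NP_COLS
    out = pd.DataFrame(
        {
            "chrom": df["chrom"].astype(str),
            "start": df["start"].astype(np.int64),
            "end": df["end"].astype(np.int64),
            "score": df["signalValue"].astype(float),
            "qvalue": np.power(10.0, -df["qValue"].astype(float)),
        }
    )
    return peaks_to_frame(out)


def write_narrowpeak(peaks: pd.DataFrame, path: str, name_prefix: str = "peak") -> None:
    """Write peaks in 10-column narrowPeak; qvalue is stored as -log10(q)."""
    df = peaks_to_frame(peaks)
    q = df["qvalue"].to_numpy(dtype=float)
    neglog_q = np.where(q > 0, -np.log10(np.maximum(q, 1e-300)), 300.0)
    with open(path, "w") as fh:
        for i, row in enumerate(df.itertuples()):
            score_int = int(min(1000, round(10 * neglog_q[i])))
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{name_prefix}_{i + 1}\t{score_int}\t.\t"
                f"{row.score:.6g}\t-1\t{neglog_q[i]:.6f}\t-1\n"
            )


# ---------------------------------------------------------------------------
# bedGraph


def read_bedgraph(path: str) -> Track:
    """Read a 4-column bedGraph into a piecewise-constant Track.

    Overlapping intervals are rejected (Track validates per chromosome).
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=range(4))
    if df.shape[1] and df.shape[1] != 4:
        raise ValueError(f"{path}: bedGraph needs 4 columns, found {df.shape[1]}")
    if not len(df):
        return Track(pd.DataFrame(columns=["chrom", "start", "end", "value"]))
    return Track(
        pd.DataFrame(
            {
                "chrom": df[0].astype(str),
                "start": df[1].astype(np.int64),
                "end": df[2].astype(np.int64),
                "value": df[3].astype(float),
            }
        )
    )


def write_bedgraph(track: Track, path: str) -> None:
    seg = track.segments
    with open(path, "w") as fh:
        for row in seg.itertuples():
            val = row.value
            text = f"{val:.10g}" if not math.isnan(val) else "nan"
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{text}\n")


# ---------------------------------------------------------------------------
# sample sheets


SAMPLE_SHEET_COLUMNS = ["sample_id", "condition", "replicate", "role", "path"]


def read_sample_sheet(path: str) -> pd.DataFrame:
    """TSV sample sheet: sample_id, condition, replicate, role, path."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "condition": str, "role": str})
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: sample sheet missing columns {missing}")
    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].tolist()
        raise ValueError(f"{path}: duplicate sample_id(s) {dup}")
    bad_role = ~df["role"].isin(["IP", "input"])
    if bad_role.any():
        raise ValueError(f"{path}: role must be IP or input")
    return df
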