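"""End-to-end orchestration: reads -> Rx factors -> peaks -> marked genes -> DUGs.

:func:`analyze_chiprx` is the in-memory pipeline over AlignedReadSets;
:func:`run_pipeline` wraps it with file I/O, a YAML config, logging and a
run manifest for the command line.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import pandas as pd
import yaml

from . import io as cio
from .dug import (
    build_count_matrix,
    classify_dugs,
    count_reads_in_gene_regions,
    median_of_ratios_factors,
    nb_wald_test,
    rx_scale_counts,
    total_count_factors,
)
from .model import AlignedReadSet, deduplicate_reads
from .peaks import (
    PeakCallerParams,
    annotate_genes,
    call_peaks_poisson,
    compare_marked_sets,
    filter_peaks_fdr,
    intersect_replicate_peaks,
    union_peaks_by_gene,
)
from .spikein import (
    average_tracks,
    rx_factors_for_replicate,
    rx_factors_table,
    scale_track,
    track_from_reads,
)

logger = logging.getLogger("chiprx")


@dataclass(frozen=True)
class Thresholds:
    """The pipeline's filtering constants."""

    peak_fdr: float = 0.01
    min_frac: float = 0.10
    upstream: int = 250
    min_overlap_bp: int = 150
    dug_fdr: float = 0.01

    def validate(self) -> None:
        for name in ("peak_fdr", "dug_fdr", "min_frac"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name}={v} outside (0,1)")
        if self.upstream < 0 or self.min_overlap_bp < 0:
            raise ValueError("upstream and min_overlap_bp must be >= 0")


@dataclass
class ChipRxResult:
    rx_table: pd.DataFrame
    sample_peaks: dict
    condition_peaks: dict
    marked: dict
    membership: pd.DataFrame
    marked_counts: dict
    regions: pd.DataFrame
    counts: "object"
    dug_table: pd.DataFrame
    contrast: tuple


def analyze_chiprx(
    libraries: dict,
    genes: pd.DataFrame,
    contrast: tuple[str, str],
    thresholds: Thresholds = Thresholds(),
    caller_params: PeakCallerParams = PeakCallerParams(),
    chrom_lengths: dict | None = None,
    normalization: str = "rx",
    peak_files: dict | None = None,
) -> ChipRxResult:
    """Run the quantitative ChIP-Rx analysis on in-memory libraries.

    ``libraries`` maps (condition, replicate, role) -> AlignedReadSet with
    role in {"IP", "input"}. Peaks are called internally unless
    ``peak_files`` provides a narrowPeak path per (condition, replicate).
    ``normalization``: "rx" (spike-in factors, the default), "total"
    (matrix total-count factors) or "median-of-ratios" — the last two are
    comparison modes that re-center genome-wide shifts.
    """
    thresholds.validate()
    if normalization not in {"rx", "total", "median-of-ratios"}:
        raise ValueError(f"unknown normalization {normalization!r}")
    cond_b, cond_a = contrast
    conditions = sorted({c for c, _, _ in libraries})
    replicates = sorted({r for _, r, _ in libraries})
    for c in (cond_a, cond_b):
        if c not in conditions:
            raise ValueError(f"contrast condition {c!r} not among libraries")

    dedup = {key: deduplicate_reads(rs) for key, rs in libraries.items()}

    factors = []
    for cond in conditions:
        for rep in replicates:
            factors.append(
                rx_factors_for_replicate(dedup[(cond, rep, "IP")], dedup[(cond, rep, "input")])
            )
    rx_table = rx_factors_table(factors)

    sample_peaks = {}
    for cond in conditions:
        for rep in replicates:
            if peak_files is not None and (cond, rep) in peak_files:
                peaks = cio.read_narrowpeak(peak_files[(cond, rep)])
            else:
                peaks = call_peaks_poisson(
                    dedup[(cond, rep, "IP")], dedup[(cond, rep, "input")],
                    params=caller_params, chrom_lengths=chrom_lengths,
                )
            sample_peaks[(cond, rep)] = filter_peaks_fdr(peaks, thresholds.peak_fdr)
            logger.info("peaks %s rep%d: %d", cond, rep, len(sample_peaks[(cond, rep)]))

    condition_peaks = {}
    marked = {}
    for cond in conditions:
        reps = [sample_peaks[(cond, r)] for r in replicates]
        merged = reps[0]
        for other in reps[1:]:
            merged = intersect_replicate_peaks(merged, other, min_frac=thresholds.min_frac)
        condition_peaks[cond] = merged
        marked_df = annotate_genes(
            merged, genes, upstream=thresholds.upstream,
            min_overlap_bp=thresholds.min_overlap_bp,
        )
        marked[cond] = marked_df
        logger.info("marked genes %s: %d", cond, len(marked_df))

    membership, marked_counts = compare_marked_sets(
        {cond: df["gene_id"].tolist() for cond, df in marked.items()}
    )
    universe = membership.index[membership.any(axis=1)]

    regions = union_peaks_by_gene(
        list(sample_peaks.values()), genes, upstream=thresholds.upstream
    )
    regions = regions[regions["gene_id"].isin(universe)].reset_index(drop=True)

    ip_sets = [dedup[(cond, rep, "IP")] for cond in conditions for rep in replicates]
    if normalization == "rx":
        alphas = pd.Series(
            rx_table["alpha"].to_numpy(), index=rx_table["sample_id"].to_numpy()
        )
        counts = build_count_matrix(ip_sets, regions, alphas)
    else:
        raw = pd.DataFrame(
            {rs.sample_id: count_reads_in_gene_regions(rs, regions) for rs in ip_sets}
        )
        factors_fn = total_count_factors if normalization == "total" else median_of_ratios_factors
        counts = rx_scale_counts(raw, factors_fn(raw))

    design = pd.Series({rs.sample_id: rs.condition for rs in ip_sets})
    table = nb_wald_test(counts.scaled, design, contrast=(cond_b, cond_a))
    dug = classify_dugs(table, fdr_threshold=thresholds.dug_fdr)
    return ChipRxResult(
        rx_table=rx_table,
        sample_peaks=sample_peaks,
        condition_peaks=condition_peaks,
        marked=marked,
        membership=membership,
        marked_counts=marked_counts,
        regions=regions,
        counts=counts,
        dug_table=dug,
        contrast=(cond_b, cond_a),
    )


def scaled_average_tracks(libraries: dict, rx_table: pd.DataFrame) -> dict:
    """Rx-scaled IP pileups averaged across replicates, one track per condition."""
    alphas = dict(zip(rx_table["sample_id"], rx_table["alpha"]))
    out = {}
    conditions = sorted({c for c, _, role in libraries if role == "IP"})
    for cond in conditions:
        tracks = [
            scale_track(track_from_reads(rs), alphas[rs.sample_id])
            for (c, _r, role), rs in sorted(libraries.items())
            if c == cond and role == "IP"
        ]
        out[cond] = average_tracks(tracks) if len(tracks) > 1 else tracks[0]
    return out


# ---------------------------------------------------------------------------
# file-level run


@dataclass
class RunConfig:
    """A reproducible pipeline run loaded from YAML."""

    sample_sheet: str
    genes: str
    output_dir: str
    spikein_prefix: str = "dmel_"
    contrast: tuple[str, str] = ("treat", "ctrl")
    thresholds: Thresholds = field(default_factory=Thresholds)
    caller: PeakCallerParams = field(default_factory=PeakCallerParams)
    normalization: str = "rx"
    seed: int = 0
    write_tracks: bool = True

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        thr = Thresholds(**raw.pop("thresholds", {}))
        caller = PeakCallerParams(**raw.pop("caller", {}))
        contrast = tuple(raw.pop("contrast", ("treat", "ctrl")))
        return cls(thresholds=thr, caller=caller, contrast=contrast, **raw)

    def validate(self) -> None:
        self.thresholds.validate()
        for path in (self.sample_sheet, self.genes):
            if not os.path.exists(path):
                raise FileNotFoundError(path)
        sheet = cio.read_sample_sheet(self.sample_sheet)
        for p in sheet["path"]:
            if not os.path.exists(p):
                raise FileNotFoundError(p)


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def load_libraries(config: RunConfig) -> dict:
    sheet = cio.read_sample_sheet(config.sample_sheet)
    libraries = {}
    for row in sheet.itertuples():
        rs = cio.read_alignments(
            row.path,
            spikein_prefix=config.spikein_prefix,
            sample_id=row.sample_id,
            condition=row.condition,
            replicate=int(row.replicate),
            role=row.role,
        )
        libraries[(row.condition, int(row.replicate), row.role)] = rs
    return libraries


def run_pipeline(config: RunConfig) -> str:
    """Execute all stages, writing TSV/BED/bedGraph outputs and a manifest.

    Deterministic given config; a stage failure leaves completed outputs in
    place plus a FAILED marker naming the stage.
    """
    config.validate()
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    manifest: dict = {"config_hash": _config_hash(config), "stages": {}}
    stage = "load"
    try:
        libraries = load_libraries(config)
        genes = cio.read_gene_models(config.genes)
        manifest["stages"]["load"] = {"libraries": len(libraries), "genes": len(genes)}

        stage = "analysis"
        result = analyze_chiprx(
            libraries, genes,
            contrast=config.contrast,
            thresholds=config.thresholds,
            caller_params=config.caller,
            normalization=config.normalization,
        )
        result.rx_table.to_csv(os.path.join(out, "rx_factors.tsv"), sep="\t", index=False)
        for (cond, rep), peaks in result.sample_peaks.items():
            cio.write_narrowpeak(peaks, os.path.join(out, f"peaks_{cond}_r{rep}.narrowPeak"))
        for cond, peaks in result.condition_peaks.items():
            peaks[["chrom", "start", "end"]].to_csv(
                os.path.join(out, f"reproducible_peaks_{cond}.bed"),
                sep="\t", header=False, index=False,
            )
            result.marked[cond].to_csv(
                os.path.join(out, f"marked_genes_{cond}.tsv"), sep="\t", index=False
            )
        result.membership.to_csv(os.path.join(out, "marked_membership.tsv"), sep="\t")
        result.regions.rename(columns={"gene_id": "name"})[
            ["chrom", "start", "end", "name"]
        ].to_csv(os.path.join(out, "gene_regions.bed"), sep="\t", header=False, index=False)
        result.counts.raw.to_csv(os.path.join(out, "counts_raw.tsv"), sep="\t")
        result.counts.scaled.to_csv(os.path.join(out, "counts_scaled.tsv"), sep="\t")
        dug_out = result.dug_table.reset_index().rename(columns={"index": "gene_id"})
        dug_out.to_csv(os.path.join(out, "dug_table.tsv"), sep="\t", index=False)
        manifest["stages"]["analysis"] = {
            "marked_counts": result.marked_counts,
            "universe": int(len(result.dug_table)),
            "calls": result.dug_table["call"].value_counts().to_dict(),
        }

        if config.write_tracks:
            stage = "tracks"
            dedup = {k: deduplicate_reads(v) for k, v in libraries.items()}
            tracks = scaled_average_tracks(dedup, result.rx_table)
            for cond, track in tracks.items():
                cio.write_bedgraph(track, os.path.join(out, f"h2bub_{cond}.bedGraph"))
            manifest["stages"]["tracks"] = {"conditions": sorted(tracks)}
    except Exception as exc:
        with open(os.path.join(out, "FAILED"), "w") as fh:
            fh.write(f"stage {stage} failed: {exc}\n")
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
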