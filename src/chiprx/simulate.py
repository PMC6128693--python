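"""Synthetic ChIP-Rx experiments and histone-PTM XIC tables with known truth.

The read generator emulates a two-condition × two-replicate spike-in
ChIP-seq design: each library contains a fixed number of fixed-length
single-end reads drawn from a toy target genome plus an exogenous spike-in
genome. Input libraries sample the chromatin mix uniformly; IP libraries
sample the target genome with per-base weight 1 outside marked gene bodies
and weight ``enrichment × global_scale × gene_fc`` inside them — i.e. the
pulldown over a marked body is proportional to the amount of mark present,
so halving global mark abundance halves the body signal. Spike-in chromatin
is recovered in the IP at a constant relative efficiency, which is the
premise that makes Rx scaling factors comparable across samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import AlignedReadSet, GenomeTag

CONDITIONS = ("ctrl", "treat")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of a simulated ChIP-Rx experiment.

    ``global_scale_s`` multiplies the IP enrichment of every marked gene in
    the second condition ("treat"): the genome-wide mark-abundance change
    the spike-in exists to measure. ``spike_frac_input`` is the nominal
    spike-in proportion of input chromatin, jittered per replicate by a
    lognormal factor with ln-sd ``spike_jitter_sd``. ``ip_spike_recovery``
    is the pulldown efficiency of spike-in chromatin relative to the
    nonspecific recovery of unmarked target chromatin (constant across
    samples by default; a per-sample override exists to study violations).
    """

    seed: int = 0
    n_genes: int = 1000
    gene_length_mean: float = 2000.0
    gene_length_jitter: float = 300.0
    genome_length_target: int = 6_000_000
    genome_length_spikein: int = 500_000
    frac_marked: float = 0.5
    enrichment_mu: float = 8.0
    enrichment_jitter: float = 0.15  # ln-space sd of per-gene enrichment
    global_scale_s: float = 1.0
    spike_frac_input: float = 0.03
    spike_jitter_sd: float = 0.1
    ip_spike_recovery: float | dict = 1.0
    reads_per_library: int = 200_000
    frac_gene_specific_change: float = 0.0
    gene_specific_fc: float = 2.5
    read_length: int = 50
    spikein_prefix: str = "dmel_"
    target_chrom: str = "chr1"
    spikein_chrom_base: str = "chr2L"

    def validate(self) -> None:
        fracs = {
            "frac_marked": self.frac_marked,
            "spike_frac_input": self.spike_frac_input,
            "frac_gene_specific_change": self.frac_gene_specific_change,
        }
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} outside [0,1]")
        if self.global_scale_s <= 0:
            raise ValueError("global_scale_s must be > 0")
        if self.reads_per_library <= 0:
            raise ValueError("reads_per_library must be > 0")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.spike_jitter_sd < 0:
            raise ValueError("spike_jitter_sd must be >= 0")
        if self.gene_specific_fc <= 0:
            raise ValueError("gene_specific_fc must be > 0")
        if self.enrichment_mu <= 0:
            raise ValueError("enrichment_mu must be > 0")
        if self.read_length <= 0:
            raise ValueError("read_length must be > 0")
        min_span = self.n_genes * (self.gene_length_mean + 4 * self.gene_length_jitter)
        if self.genome_length_target < min_span:
            raise ValueError(
                "genome_length_target too small to place "
                f"{self.n_genes} genes of ~{self.gene_length_mean} bp"
            )

    def spike_recovery_for(self, condition: str, replicate: int) -> float:
        if isinstance(self.ip_spike_recovery, dict):
            return float(self.ip_spike_recovery[(condition, replicate)])
        return float(self.ip_spike_recovery)


@dataclass
class SimulationTruth:
    """Ground truth of one simulated experiment.

    ``genes``: per-gene marked flag, sampling-weight enrichment per
    condition and true log2 fold change (treat vs ctrl).
    ``replicates``: realized spike-in chromatin fraction per replicate.
    """

    genes: pd.DataFrame
    replicates: pd.DataFrame


@dataclass
class SimulatedExperiment:
    config: SimulationConfig
    genes: pd.DataFrame
    libraries: dict  # (condition, replicate, role) -> AlignedReadSet
    truth: SimulationTruth

    def library(self, condition: str, replicate: int, role: str) -> AlignedReadSet:
        return self.libraries[(condition, replicate, role)]


def _place_genes(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    lengths = rng.normal(cfg.gene_length_mean, cfg.gene_length_jitter, cfg.n_genes)
    lengths = np.maximum(lengths.round().astype(np.int64), 200)
    total_gap = cfg.genome_length_target - int(lengths.sum())
    if total_gap <= cfg.n_genes:
        raise ValueError("gene bodies exceed target genome length")
    gap_fracs = rng.dirichlet(np.ones(cfg.n_genes + 1))
    gaps = np.floor(gap_fracs * total_gap).astype(np.int64)
    starts = np.cumsum(gaps[:-1] + np.concatenate(([0], lengths[:-1])))
    ends = starts + lengths
    strands = rng.choice(["+", "-"], size=cfg.n_genes)
    return pd.DataFrame(
        {
            "gene_id": [f"g{i + 1:05d}" for i in range(cfg.n_genes)],
            "chrom": cfg.target_chrom,
            "strand": strands,
            "tss": np.where(strands == "+", starts, ends),
            "tes": np.where(strands == "+", ends, starts),
            "body_start": starts,
            "body_end": ends,
            "length": lengths,
        }
    )


def _uniform_reads(
    rng: np.random.Generator, n: int, chrom: str, length: int, read_len: int
) -> pd.DataFrame:
    starts = rng.integers(0, max(1, length - read_len), size=n)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": starts + read_len,
            "strand": rng.choice(["+", "-"], size=n),
        }
    )


def _reads_in_regions(
    rng: np.random.Generator,
    counts: np.ndarray,
    reg_starts: np.ndarray,
    reg_ends: np.ndarray,
    chrom: str,
    read_len: int,
    genome_len: int,
) -> pd.DataFrame:
    """Reads with starts uniform within their source region."""
    reg_idx = np.repeat(np.arange(len(counts)), counts)
    u = rng.random(reg_idx.size)
    span = (reg_ends - reg_starts)[reg_idx]
    starts = reg_starts[reg_idx] + np.floor(u * span).astype(np.int64)
    starts = np.minimum(starts, genome_len - read_len)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": starts + read_len,
            "strand": rng.choice(["+", "-"], size=reg_idx.size),
        }
    )


def simulate_chiprx_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Simulate 2 conditions × 2 replicates of IP+input spike-in libraries.

    Returns eight AlignedReadSets (before deduplication each holds exactly
    ``reads_per_library`` reads), the gene models, and the ground truth.
    Identical config (including seed) gives identical output.
    """
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    genes = _place_genes(cfg, rng)
    n = cfg.n_genes

    n_marked = int(round(cfg.frac_marked * n))
    marked_idx = rng.choice(n, size=n_marked, replace=False)
    marked = np.zeros(n, dtype=bool)
    marked[marked_idx] = True

    enrichment = np.ones(n)
    if n_marked:
        ln_mu = np.log(cfg.enrichment_mu) - cfg.enrichment_jitter**2 / 2
        enrichment[marked] = rng.lognormal(ln_mu, cfg.enrichment_jitter, n_marked)

    # gene-specific fold changes in the treat condition, half up / half down
    gene_fc = np.ones(n)
    n_changed = int(round(cfg.frac_gene_specific_change * n_marked))
    if n_changed:
        changed_idx = rng.choice(marked_idx, size=n_changed, replace=False)
        direction = rng.random(n_changed) < 0.5
        gene_fc[changed_idx] = np.where(
            direction, cfg.gene_specific_fc, 1.0 / cfg.gene_specific_fc
        )

    enr_eff = {
        "ctrl": np.where(marked, enrichment, 1.0),
        "treat": np.where(marked, enrichment * cfg.global_scale_s * gene_fc, 1.0),
    }

    truth_genes = genes[["gene_id", "chrom", "strand", "tss", "tes", "length"]].copy()
    truth_genes["marked"] = marked
    truth_genes["enrichment"] = enrichment
    truth_genes["enr_ctrl"] = enr_eff["ctrl"]
    truth_genes["enr_treat"] = enr_eff["treat"]
    truth_genes["gene_fc"] = gene_fc
    truth_genes["true_log2fc"] = np.log2(enr_eff["treat"] / enr_eff["ctrl"])

    body_starts = genes["body_start"].to_numpy()
    body_ends = genes["body_end"].to_numpy()
    lengths = genes["length"].to_numpy()
    marked_starts = body_starts[marked]
    marked_ends = body_ends[marked]
    marked_lengths = lengths[marked]
    # background = target genome minus marked bodies (unit weight)
    bg_len = cfg.genome_length_target - int(marked_lengths.sum())
    if marked_lengths.size:
        # complement intervals of the marked bodies
        cut = np.sort(np.concatenate((marked_starts, marked_ends)))
        edges = np.concatenate(([0], cut, [cfg.genome_length_target]))
        bg_seg_s, bg_seg_e = edges[0::2], edges[1::2]
    else:
        bg_seg_s = np.array([0], dtype=np.int64)
        bg_seg_e = np.array([cfg.genome_length_target], dtype=np.int64)
    keep = bg_seg_e > bg_seg_s
    bg_seg_s, bg_seg_e = bg_seg_s[keep], bg_seg_e[keep]

    spike_chrom = f"{cfg.spikein_prefix}{cfg.spikein_chrom_base}"
    tag = GenomeTag(cfg.spikein_prefix)

    libraries: dict = {}
    rep_rows = []
    for condition in CONDITIONS:
        for replicate in (1, 2):
            jitter = rng.lognormal(0.0, cfg.spike_jitter_sd) if cfg.spike_jitter_sd else 1.0
            p_rep = cfg.spike_frac_input * jitter
            rep_rows.append(
                {"condition": condition, "replicate": replicate, "spike_frac": p_rep}
            )

            # ---- input library: uniform sampling of the chromatin mix
            n_spike_in = rng.binomial(cfg.reads_per_library, p_rep)
            n_target_in = cfg.reads_per_library - n_spike_in
            reads_in = pd.concat(
                [
                    _uniform_reads(
                        rng, n_target_in, cfg.target_chrom,
                        cfg.genome_length_target, cfg.read_length,
                    ),
                    _uniform_reads(
                        rng, n_spike_in, spike_chrom,
                        cfg.genome_length_spikein, cfg.read_length,
                    ),
                ],
                ignore_index=True,
            )
            libraries[(condition, replicate, "input")] = AlignedReadSet(
                sample_id=f"{condition}_r{replicate}_input",
                condition=condition,
                replicate=replicate,
                role="input",
                reads=reads_in,
                genome_tag=tag,
            )

            # ---- IP library: weighted sampling
            enr = enr_eff[condition][marked]
            w_marked = marked_lengths * enr
            w_bg = float(bg_len)
            recovery = cfg.spike_recovery_for(condition, replicate)
            # spike chromatin mass relative to target mass (== genome length units)
            w_spike = recovery * cfg.genome_length_target * p_rep / (1.0 - p_rep)
            weights = np.concatenate(([w_bg], w_marked, [w_spike]))
            counts = rng.multinomial(cfg.reads_per_library, weights / weights.sum())
            n_bg, n_per_gene, n_spike_ip = counts[0], counts[1:-1], counts[-1]

            # background reads: uniform over the complement segments
            seg_lens = bg_seg_e - bg_seg_s
            seg_counts = rng.multinomial(n_bg, seg_lens / seg_lens.sum())
            bg_reads = _reads_in_regions(
                rng, seg_counts, bg_seg_s, bg_seg_e, cfg.target_chrom,
                cfg.read_length, cfg.genome_length_target,
            )
            gene_reads = _reads_in_regions(
                rng, n_per_gene, marked_starts, marked_ends, cfg.target_chrom,
                cfg.read_length, cfg.genome_length_target,
            )
            spike_reads = _uniform_reads(
                rng, n_spike_ip, spike_chrom, cfg.genome_length_spikein, cfg.read_length
            )
            reads_ip = pd.concat([bg_reads, gene_reads, spike_reads], ignore_index=True)
            libraries[(condition, replicate, "IP")] = AlignedReadSet(
                sample_id=f"{condition}_r{replicate}_IP",
                condition=condition,
                replicate=replicate,
                role="IP",
                reads=reads_ip,
                genome_tag=tag,
            )

    truth = SimulationTruth(genes=truth_genes, replicates=pd.DataFrame(rep_rows))
    gene_models = genes[["gene_id", "chrom", "strand", "tss", "tes"]].copy()
    return SimulatedExperiment(config=cfg, genes=gene_models, libraries=libraries, truth=truth)


# ---------------------------------------------------------------------------
# histone-PTM XIC tables


def simulate_ptm_table(
    n_peptides: int = 20,
    n_replicates_per_genotype: int = 3,
    effect_log2fc=0.0,
    noise_sd: float = 0.1,
    sample_offsets=None,
    reference_peptide_id: str = "YNKKPTITSR",
    seed: int = 0,
    baseline_log2: float = 20.0,
    genotypes: tuple[str, str] = ("wt", "mut"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a peptide × run XIC-area table for two genotypes.

    log2 area(p, run) = baseline_p + effect_p·[run is mutant] + offset_run
    + Normal(0, noise_sd). Offsets apply equally to every peptide of a run,
    so per-run reference-peptide normalization removes them exactly. The
    reference peptide always has effect 0. Returns (raw-area table with the
    peptide index and one column per run, truth table).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_replicates_per_genotype < 2:
        raise ValueError("need >= 2 replicates per genotype")
    rng = np.random.default_rng(seed)

    peptide_ids = [reference_peptide_id] + [
        f"pep{i + 1:04d}" for i in range(n_peptides - 1)
    ]
    effects = np.broadcast_to(
        np.asarray(effect_log2fc, dtype=float), (n_peptides,)
    ).copy()
    effects[0] = 0.0  # reference peptide is stable by construction

    runs = [
        f"{g}_{r + 1}" for g in genotypes for r in range(n_replicates_per_genotype)
    ]
    design = pd.Series(
        [g for g in genotypes for _ in range(n_replicates_per_genotype)],
        index=runs,
        name="genotype",
    )
    n_runs = len(runs)
    if sample_offsets is None:
        offsets = np.zeros(n_runs)
    else:
        offsets = np.broadcast_to(np.asarray(sample_offsets, dtype=float), (n_runs,))

    baselines = baseline_log2 + rng.normal(0.0, 1.0, n_peptides)
    is_mut = (design == genotypes[1]).to_numpy()
    log2 = (
        baselines[:, None]
        + np.outer(effects, is_mut.astype(float))
        + offsets[None, :]
        + (rng.normal(0.0, noise_sd, (n_peptides, n_runs)) if noise_sd else 0.0)
    )
    table = pd.DataFrame(np.exp2(log2), index=pd.Index(peptide_ids, name="peptide_id"), columns=runs)
    truth = pd.DataFrame(
        {
            "peptide_id": peptide_ids,
            "effect_log2fc": effects,
            "true_ratio": np.exp2(effects),
            "is_reference": [i == 0 for i in range(n_peptides)],
        }
    )
    truth.attrs["design"] = design
    return table, truth


def ptm_design(table: pd.DataFrame, genotypes: tuple[str, str] = ("wt", "mut")) -> pd.Series:
    """Run→genotype mapping recovered from `<genotype>_<rep>` column names."""
    mapping = {run: run.rsplit("_", 1)[0] for run in table.columns}
    bad = {g for g in mapping.values() if g not in genotypes}
    if bad:
        raise ValueError(f"unknown genotype label(s) {sorted(bad)} in run names")
    return pd.Series(mapping, name="genotype")
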