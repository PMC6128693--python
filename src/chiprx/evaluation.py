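"""Benchmark runs on synthetic data with known truth.

These functions regenerate a simulated experiment from scratch, run the
full pipeline on it and score the result against the generator's truth
tables. They back both the test suite and `scripts/acceptance.py`.
"""

from __future__ import annotations

import numpy as np

from .pipeline import analyze_chiprx
from .ptm import normalize_xic, ptm_differential
from .simulate import (
    SimulationConfig,
    ptm_design,
    simulate_chiprx_experiment,
    simulate_ptm_table,
)


def _run(cfg: SimulationConfig, normalization: str = "rx"):
    exp = simulate_chiprx_experiment(cfg)
    result = analyze_chiprx(
        exp.libraries, exp.genes, contrast=("treat", "ctrl"),
        chrom_lengths={cfg.target_chrom: cfg.genome_length_target},
        normalization=normalization,
    )
    return exp, result


def global_shift_recovery(
    seed: int, global_scale_s: float = 0.4, normalization: str = "rx"
) -> dict:
    """Median log2FC of truth-marked genes under a genome-wide mark shift.

    Simulates 2 conditions × 2 replicates (1000 genes, 500 marked, 3%
    spike-in, 2e5 reads/library) with ``global_scale_s`` applied to the
    second condition, runs the full pipeline and reports the median
    per-gene log2FC over the truth-marked genes present in the tested
    universe.
    """
    cfg = SimulationConfig(seed=seed, global_scale_s=global_scale_s)
    exp, result = _run(cfg, normalization=normalization)
    truth = exp.truth.genes.set_index("gene_id")
    marked = truth.index[truth["marked"]]
    common = result.dug_table.index.intersection(marked)
    median = float(np.nanmedian(result.dug_table.loc[common, "log2FC"]))
    return {"median_log2fc": median, "n_genes": int(cfg.n_genes), "n_marked_tested": len(common)}


def dug_benchmark(
    seeds,
    frac_gene_specific_change: float = 0.10,
    gene_specific_fc: float = 2.5,
    fdr: float = 0.01,
) -> dict:
    """Sensitivity and empirical false-discovery proportion for DUG calling.

    Pools true/false discoveries at the given FDR threshold over the
    simulation seeds; the two conditions share the same global level
    (s = 1), so only the gene-specific changes are true positives.
    """
    tp = fn = fp = 0
    for seed in seeds:
        cfg = SimulationConfig(
            seed=int(seed), global_scale_s=1.0,
            frac_gene_specific_change=frac_gene_specific_change,
            gene_specific_fc=gene_specific_fc,
        )
        exp, result = _run(cfg)
        truth = exp.truth.genes.set_index("gene_id")
        dug = result.dug_table
        changed = set(truth.index[truth["gene_fc"] != 1.0]) & set(dug.index)
        called = set(dug.index[dug["call"].isin(["hyper", "hypo"])])
        tp += len(called & changed)
        fn += len(changed - called)
        fp += len(called - changed)
    discoveries = tp + fp
    return {
        "sensitivity": tp / (tp + fn) if (tp + fn) else float("nan"),
        "fdp": fp / discoveries if discoveries else 0.0,
        "n_seeds": len(list(seeds)),
        "n_discoveries": discoveries,
    }


def null_dug_rate(seeds, fdr: float = 0.01) -> dict:
    """Fraction of tested genes called differential when nothing changes."""
    called = total = 0
    for seed in seeds:
        cfg = SimulationConfig(seed=int(seed), global_scale_s=1.0)
        _exp, result = _run(cfg)
        dug = result.dug_table
        called += int(dug["call"].isin(["hyper", "hypo"]).sum())
        total += int((~dug["all_zero"]).sum())
    return {"fraction_called": called / total, "n_genes_tested": total}


def ptm_recovery(
    seed: int,
    n_repeats: int = 200,
    effect_log2fc: float = -1.0,
    noise_sd: float = 0.05,
) -> dict:
    """Recovery of a true fold change by the PTM statistic over repeats.

    Each repeat simulates a fresh 3+3 replicate table whose non-reference
    peptides carry ``effect_log2fc``; reports the mean estimated ratio and
    the fraction of repeats where the peptide lands in the two-fold band
    [0.4, 0.6] and is flagged significant.
    """
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=n_repeats)
    ratios = []
    hits = band = 0
    for s in sub_seeds:
        table, _ = simulate_ptm_table(
            n_peptides=2, effect_log2fc=effect_log2fc, noise_sd=noise_sd, seed=int(s)
        )
        res = ptm_differential(normalize_xic(table), ptm_design(table))
        row = res.drop(index="YNKKPTITSR").iloc[0]
        ratios.append(row["ratio"])
        if 0.4 <= row["ratio"] <= 0.6:
            band += 1
            if row["significant"]:
                hits += 1
    return {
        "mean_ratio": float(np.mean(ratios)),
        "recovery_rate": hits / n_repeats,
        "ratio_in_band_rate": band / n_repeats,
        "n_repeats": n_repeats,
    }


def ptm_null_rate(seed: int, n_peptides: int = 1000, noise_sd: float = 0.1) -> dict:
    """Fraction of null peptides flagged significant (p<0.001 and >2-fold)."""
    table, _ = simulate_ptm_table(
        n_peptides=n_peptides + 1, effect_log2fc=0.0, noise_sd=noise_sd, seed=seed
    )
    res = ptm_differential(normalize_xic(table), ptm_design(table))
    res = res.drop(index="YNKKPTITSR")
    return {"flag_fraction": float(res["significant"].mean()), "n_peptides": len(res)}
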