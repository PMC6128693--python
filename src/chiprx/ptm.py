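"""Label-free differential histone-PTM statistics from peptide XIC tables.

Workflow: per-run normalization of log2 XIC areas to a stable unmodified
reference peptide (for H2B, YNKKPTITSR), per-genotype means with 95%
confidence intervals stated at their 5% alpha level, a two-sided Welch
t-test per peptide, and the significance filter p < 0.001 together with a
fold change beyond 2 in either direction. Ratios are mutant/wild-type with
the wild type set to 1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_REFERENCE_PEPTIDE = "YNKKPTITSR"


def normalize_xic(
    table: pd.DataFrame, reference_peptide_id: str = DEFAULT_REFERENCE_PEPTIDE
) -> pd.DataFrame:
    """Per-run reference-peptide normalization of raw XIC areas.

    normalized(p, run) = log2 area(p, run) − log2 area(reference, run); the
    reference row becomes identically 0, and any run-wide multiplicative
    loading factor cancels. Raw areas must be positive and the reference
    peptide measured in every run.
    """
    if reference_peptide_id not in table.index:
        raise ValueError(f"reference peptide {reference_peptide_id!r} not in table")
    values = table.to_numpy(dtype=float)
    bad = ~(values > 0) & ~np.isnan(values)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-positive XIC area for {table.index[i]!r} in run {table.columns[j]!r}"
        )
    ref = table.loc[reference_peptide_id]
    missing = ref.index[ref.isna()].tolist()
    if missing:
        raise ValueError(
            f"reference peptide {reference_peptide_id!r} missing in run(s) {missing}"
        )
    return np.log2(table) - np.log2(ref)


def welch_test(group_a, group_b) -> tuple[float, float, float]:
    """Welch two-sided t-test on log2 values.

    Returns (mean_a − mean_b, two-sided p, Welch–Satterthwaite df). When
    both groups have zero variance: p = 1 if the means are equal, else the
    comparison is degenerate and p is reported as 0 with a warning.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 values per group")
    diff = a.mean() - b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if diff == 0.0:
            return 0.0, 1.0, float(a.size + b.size - 2)
        warnings.warn(
            "degenerate Welch test: zero variance in both groups with unequal means",
            stacklevel=2,
        )
        return float(diff), 0.0, float(a.size + b.size - 2)
    sa, sb = va / a.size, vb / b.size
    t = diff / math.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (
        sa**2 / (a.size - 1) + sb**2 / (b.size - 1)
    )
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(diff), float(p), float(df)


def _ci_halfwidth(values: np.ndarray, ci_alpha: float) -> float:
    n = values.size
    if n < 2:
        return float("nan")
    s = values.std(ddof=1)
    return float(stats.t.ppf(1.0 - ci_alpha / 2.0, n - 1) * s / math.sqrt(n))


def average_technical_replicates(table: pd.DataFrame, run_to_biorep) -> pd.DataFrame:
    """Average technical injections into one column per biological replicate.

    ``run_to_biorep`` maps each run column to its biological-replicate id;
    values are averaged in the (log2 or raw) space of the table.
    """
    mapping = pd.Series(run_to_biorep)
    return table.T.groupby(mapping).mean().T


def ptm_differential(
    normalized: pd.DataFrame,
    design: pd.Series,
    wt_label: str = "wt",
    alpha: float = 0.001,
    min_fold: float = 2.0,
    ci_alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-peptide differential-modification statistics between two genotypes.

    ``normalized`` is the reference-normalized log2 table; ``design`` maps
    run -> genotype (exactly two, one equal to ``wt_label``). Per peptide:
    genotype means with t-based CIs at ``ci_alpha``, ratio =
    2^(mean_mut − mean_wt) (wild type set to 1), Welch p-value, and
    significant ⇔ p < alpha and fold change > min_fold in either direction.
    Peptides missing in more than one run of a genotype are excluded with
    a reason in the ``status`` column.
    """
    genotypes = sorted(set(design))
    if len(genotypes) != 2 or wt_label not in genotypes:
        raise ValueError(f"design must have exactly two genotypes incl. {wt_label!r}")
    mut_label = next(g for g in genotypes if g != wt_label)
    runs_wt = design.index[design == wt_label]
    runs_mut = design.index[design == mut_label]
    if len(runs_wt) < 3 or len(runs_mut) < 3:
        raise ValueError("need >= 3 replicates per genotype")

    rows = []
    for peptide, row in normalized.iterrows():
        vals_wt = row[runs_wt].to_numpy(dtype=float)
        vals_mut = row[runs_mut].to_numpy(dtype=float)
        n_miss_wt = int(np.isnan(vals_wt).sum())
        n_miss_mut = int(np.isnan(vals_mut).sum())
        rec = {"peptide_id": peptide}
        if n_miss_wt > 1 or n_miss_mut > 1:
            rec.update(
                mean_wt=np.nan, mean_mut=np.nan, ci_wt=np.nan, ci_mut=np.nan,
                ratio=np.nan, pvalue=np.nan, df=np.nan, significant=False,
                status=f"excluded: missing in {max(n_miss_wt, n_miss_mut)} runs of a genotype",
            )
            rows.append(rec)
            continue
        vw = vals_wt[~np.isnan(vals_wt)]
        vm = vals_mut[~np.isnan(vals_mut)]
        diff, p, df = welch_test(vm, vw)  # mut − wt
        ratio = float(2.0**diff)
        significant = bool(p < alpha and (ratio > min_fold or ratio < 1.0 / min_fold))
        rec.update(
            mean_wt=float(vw.mean()),
            mean_mut=float(vm.mean()),
            ci_wt=_ci_halfwidth(vw, ci_alpha),
            ci_mut=_ci_halfwidth(vm, ci_alpha),
            ratio=ratio,
            pvalue=p,
            df=df,
            significant=significant,
            status="ok",
        )
        rows.append(rec)
    return pd.DataFrame(rows).set_index("peptide_id")
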