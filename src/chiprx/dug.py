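"""Gene-level counting, Rx scaling and differential-ubiquitination calling.

Counts of IP reads in per-gene peak regions are multiplied by each sample's
Rx factor before model fitting, and the negative-binomial Wald test runs
with size factors fixed to 1: median-of-ratios or total-count normalization
would re-center a genome-wide shift to zero and destroy exactly the signal
the spike-in exists to preserve. Both classic normalizations are available
as explicit comparison modes (:func:`total_count_factors`,
:func:`median_of_ratios_factors`).

The NB test uses a deliberately simple, documented dispersion estimator:
per-gene within-condition method-of-moments, a fitted a0 + a1/mu
mean–dispersion trend, and df-weighted shrinkage of the gene-wise estimate
toward the trend. Acceptance is by simulation calibration, not
bit-equivalence with any external differential-expression package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust
from .model import TARGET, AlignedReadSet

__all__ = [
    "bh_adjust",
    "count_reads_in_gene_regions",
    "build_count_matrix",
    "rx_scale_counts",
    "total_count_factors",
    "median_of_ratios_factors",
    "nb_wald_test",
    "classify_dugs",
    "join_expression",
    "CountMatrix",
]


@dataclass
class CountMatrix:
    """Genes × samples read counts, raw and Rx-scaled.

    ``raw``/``scaled``: DataFrames indexed by gene_id with one column per
    sample; ``alphas``: per-sample scaling factors (index = sample ids).
    """

    raw: pd.DataFrame
    scaled: pd.DataFrame
    alphas: pd.Series

    def __post_init__(self) -> None:
        if not self.raw.index.equals(self.scaled.index) or list(self.raw.columns) != list(
            self.scaled.columns
        ):
            raise ValueError("raw and scaled matrices must share genes and samples")
        if (self.alphas <= 0).any():
            raise ValueError("all scaling factors must be > 0")


def count_reads_in_gene_regions(
    readset: AlignedReadSet, regions: pd.DataFrame
) -> pd.Series:
    """IP reads overlapping each gene's peak regions (target genome).

    A read counts toward a gene iff it overlaps >=1 bp of any of that
    gene's regions; it contributes at most once per gene but may count for
    several genes. ``regions``: gene_id/chrom/start/end with
    non-overlapping intervals per gene.
    """
    reads = readset.subset(TARGET)
    gene_ids = regions["gene_id"].unique()
    counts = pd.Series(0, index=pd.Index(gene_ids, name="gene_id"), dtype=np.int64)
    by_chrom = {}
    for chrom, grp in reads.groupby("chrom"):
        starts = grp["start"].to_numpy(np.int64)
        order = np.argsort(starts, kind="stable")
        by_chrom[chrom] = (
            starts[order],
            grp["end"].to_numpy(np.int64)[order],
        )
    max_len = int((reads["end"] - reads["start"]).max()) if len(reads) else 0
    for (gene, chrom), grp in regions.groupby(["gene_id", "chrom"], sort=False):
        hit = by_chrom.get(chrom)
        if hit is None:
            continue
        rs, re = hit
        idx_seen = []
        for a, b in zip(grp["start"].to_numpy(np.int64), grp["end"].to_numpy(np.int64)):
            lo = np.searchsorted(rs, a - max_len, side="left")
            hi = np.searchsorted(rs, b, side="left")
            cand = np.arange(lo, hi)
            cand = cand[re[cand] > a]
            idx_seen.append(cand)
        if idx_seen:
            counts[gene] = np.unique(np.concatenate(idx_seen)).size
    return counts


def build_count_matrix(
    ip_readsets: list[AlignedReadSet], regions: pd.DataFrame, alphas: pd.Series
) -> CountMatrix:
    """Assemble the genes × samples matrix and apply Rx scaling."""
    raw = pd.DataFrame(
        {rs.sample_id: count_reads_in_gene_regions(rs, regions) for rs in ip_readsets}
    )
    return rx_scale_counts(raw, alphas)


def rx_scale_counts(raw: pd.DataFrame, alphas) -> CountMatrix:
    """Scaled counts = round(raw × alpha_sample), ties away from zero."""
    alphas = pd.Series(alphas)
    missing = [s for s in raw.columns if s not in alphas.index]
    if missing:
        raise ValueError(f"missing scaling factor for sample(s) {missing}")
    alphas = alphas[list(raw.columns)].astype(float)
    scaled_f = raw.to_numpy(dtype=float) * alphas.to_numpy()[None, :]
    # counts are non-negative, so floor(x + 0.5) rounds halves away from zero
    scaled = pd.DataFrame(
        np.floor(scaled_f + 0.5).astype(np.int64), index=raw.index, columns=raw.columns
    )
    return CountMatrix(raw=raw, scaled=scaled, alphas=alphas)


def total_count_factors(raw: pd.DataFrame) -> pd.Series:
    """Comparison mode: equalize each sample's total counts over the matrix.

    factor_s = (geometric mean of column totals) / column total_s. This is
    the classic library-size normalization that a pipeline without spike-in
    would use; it re-centers genome-wide shifts.
    """
    totals = raw.sum(axis=0).astype(float)
    if (totals <= 0).any():
        raise ValueError("sample with zero total counts")
    return np.exp(np.log(totals).mean()) / totals


def median_of_ratios_factors(raw: pd.DataFrame) -> pd.Series:
    """Comparison mode: median-of-ratios size factors (inverted to multipliers).

    factor_s = 1 / median_g(count_gs / geometric-mean_g), computed over
    genes with nonzero counts in every sample.
    """
    mat = raw.to_numpy(dtype=float)
    keep = (mat > 0).all(axis=1)
    if not keep.any():
        raise ValueError("no gene with nonzero counts in every sample")
    logs = np.log(mat[keep])
    log_geo = logs.mean(axis=1, keepdims=True)
    size = np.exp(np.median(logs - log_geo, axis=0))
    return pd.Series(1.0 / size, index=raw.columns)


# ---------------------------------------------------------------------------
# negative-binomial Wald test


def _dispersion_trend(mu: np.ndarray, disp: np.ndarray) -> tuple[float, float]:
    """Fit disp ~ a0 + a1/mu by least squares with one outlier-trimming pass."""
    use = mu > 1.0
    if use.sum() < 10:
        center = float(np.clip(np.nanmedian(disp), 1e-8, None))
        return center, 0.0
    x = 1.0 / mu[use]
    y = disp[use]
    for _ in range(2):
        X = np.column_stack([np.ones_like(x), x])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        mad = np.median(np.abs(resid - np.median(resid))) or np.std(resid) or 1.0
        ok = np.abs(resid) < 5 * 1.4826 * mad
        if ok.all():
            break
        x, y = x[ok], y[ok]
    a0, a1 = float(coef[0]), float(coef[1])
    return max(a0, 1e-8), max(a1, 0.0)


def nb_wald_test(
    scaled: pd.DataFrame,
    design: pd.Series,
    contrast: tuple[str, str],
    prior_df: float = 8.0,
) -> pd.DataFrame:
    """Per-gene NB Wald test of condition B vs A with size factors fixed to 1.

    ``design`` maps sample id -> condition; ``contrast`` = (B, A) so
    positive log2FC means higher in B. Requires >=2 replicates per
    condition. Genes with zero counts in every sample get NaN statistics
    and are excluded from any downstream FDR universe.

    Per gene the two condition means are estimated, the gene-wise
    dispersion comes from within-condition moments shrunk toward the
    fitted a0 + a1/mu trend with ``prior_df`` pseudo-degrees of freedom,
    and the Wald statistic is log2FC / SE with a two-sided normal p-value.
    """
    cond_b, cond_a = contrast
    samples_a = [s for s in scaled.columns if design.get(s) == cond_a]
    samples_b = [s for s in scaled.columns if design.get(s) == cond_b]
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError(
            f"need >=2 replicates per condition, got {len(samples_a)} in "
            f"{cond_a!r} and {len(samples_b)} in {cond_b!r}"
        )
    ya = scaled[samples_a].to_numpy(dtype=float)
    yb = scaled[samples_b].to_numpy(dtype=float)
    na, nb = ya.shape[1], yb.shape[1]

    ma, mb = ya.mean(axis=1), yb.mean(axis=1)
    va, vb = ya.var(axis=1, ddof=1), yb.var(axis=1, ddof=1)
    base_mean = np.concatenate([ya, yb], axis=1).mean(axis=1)
    all_zero = (ma == 0) & (mb == 0)

    # within-condition method-of-moments dispersion (may be negative)
    dfa, dfb = na - 1, nb - 1
    num = dfa * (va - ma) + dfb * (vb - mb)
    den = dfa * ma**2 + dfb * mb**2
    with np.errstate(divide="ignore", invalid="ignore"):
        disp_mom = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)

    ok = ~np.isnan(disp_mom) & ~all_zero
    a0, a1 = _dispersion_trend(base_mean[ok], disp_mom[ok])
    disp_trend = np.clip(a0 + a1 / np.maximum(base_mean, 1e-8), 1e-8, None)
    df_total = dfa + dfb
    disp_gene = np.clip(np.nan_to_num(disp_mom, nan=0.0), 0.0, None)
    disp = (df_total * disp_gene + prior_df * disp_trend) / (df_total + prior_df)
    disp = np.clip(disp, 1e-8, None)

    # continuity floor so a zero group mean yields a finite fold change
    ma_f = np.maximum(ma, 0.5 / na)
    mb_f = np.maximum(mb, 0.5 / nb)
    beta = np.log(mb_f / ma_f)
    se = np.sqrt((1 + disp * ma_f) / (na * ma_f) + (1 + disp * mb_f) / (nb * mb_f))
    stat = beta / se
    pvalue = 2.0 * stats.norm.sf(np.abs(stat))

    out = pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FC": beta / np.log(2.0),
            "lfcSE": se / np.log(2.0),
            "stat": stat,
            "pvalue": pvalue,
            "dispersion": disp,
        },
        index=scaled.index,
    )
    out.loc[all_zero, ["log2FC", "lfcSE", "stat", "pvalue", "dispersion"]] = np.nan
    out["all_zero"] = all_zero
    return out


def classify_dugs(table: pd.DataFrame, fdr_threshold: float = 0.01) -> pd.DataFrame:
    """BH-adjust p-values and classify genes as hyper / hypo / ns.

    hyper: FDR < threshold and log2FC > 0; hypo: FDR < threshold and
    log2FC < 0; all-zero (flagged) genes stay outside the FDR universe and
    are labelled "flagged".
    """
    out = table.copy()
    out["FDR"] = bh_adjust(out["pvalue"].to_numpy())
    sig = out["FDR"] < fdr_threshold
    call = np.where(
        out["pvalue"].isna(),
        "flagged",
        np.where(sig & (out["log2FC"] > 0), "hyper", np.where(sig & (out["log2FC"] < 0), "hypo", "ns")),
    )
    out["call"] = call
    return out


def join_expression(dug_table: pd.DataFrame, expression: pd.DataFrame) -> pd.DataFrame:
    """Inner join of H2Bub fold changes with an external expression table.

    ``expression``: gene_id, log2FC, FDR (as from an RNA-seq differential
    analysis). Both fold-change columns are reported side by side.
    """
    required = ["gene_id", "log2FC", "FDR"]
    missing = [c for c in required if c not in expression.columns]
    if missing:
        raise ValueError(f"expression table missing columns {missing}")
    left = dug_table.reset_index()
    if "gene_id" not in left.columns:
        left = left.rename(columns={left.columns[0]: "gene_id"})
    joined = left.merge(
        expression[required].rename(
            columns={"log2FC": "expression_log2FC", "FDR": "expression_FDR"}
        ),
        on="gene_id",
        how="inner",
    )
    if not len(joined):
        import warnings

        warnings.warn("empty join: no shared gene ids", stacklevel=2)
    return joined
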