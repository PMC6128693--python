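# Methods

## Coordinate conventions and formats

All internal interval arithmetic is 0-based, half-open. GFF3 and TSV gene
tables (1-based, inclusive) are converted on read; `tss` always denotes the
transcription start, so `tss < tes` on the + strand and `tes < tss` on the
− strand. narrowPeak column 9 is −log10(q) and round-trips q-values to six
significant digits; bedGraph tracks are piecewise-constant with
non-overlapping segments per chromosome (overlap is an error, not a merge).
Duplicate reads are defined positionally as identical
(chrom, start, end, strand), the usual convention for single-end 1×50 bp
libraries. Spike-in chromosomes are recognized by a configurable name
prefix (default `dmel_`), the common idiom for concatenated references.
Alignments can be supplied as BED as well as SAM/BAM so the whole pipeline
runs without binary formats.

## Spike-in (Rx) scaling

Each biological replicate is scaled by α = r/N<sub>d,IP</sub> with
r = 100·N<sub>d,in</sub>/(N<sub>a,in</sub> + N<sub>d,in</sub>), all counts
in millions. Measuring r per replicate corrects for technical variation in
the amount of spike-in chromatin actually added to each input; the variant
that assumes invariant spike-in loading (1/N<sub>d,IP</sub>) is available
as `compute_rx_factor_original` for comparison only. No library-size
normalization is layered on top of α: α already embeds input-composition
correction, and re-centering per-sample totals is precisely what the
spike-in exists to avoid. The method's core premise is that spike-in
chromatin is recovered in the IP with the same efficiency in every sample;
the simulator exposes a per-sample override of that efficiency to study
violations.

Signal tracks are per-base read pileups; scaling multiplies segment values
by α and replicate averaging takes the arithmetic mean on the union of
segment boundaries, treating uncovered positions as 0 signal (pileups are
dense over covered regions; absence means no reads). bedGraph is the
output format; bigwig conversion is deliberately out of scope.

## Peak calling and marked genes

The bundled caller exists so the pipeline is self-contained; it does not
attempt to reproduce MACS2's model, and per-sample narrowPeak files from
any external caller can be substituted. Windows (200 bp, step 50 bp) are
scored by the Poisson upper-tail probability of the IP read count under
λ = max(global IP rate, input-local rate scaled to IP depth) per window;
window p-values are Benjamini–Hochberg adjusted genome-wide, significant
windows (q < 0.01) within 100 bp are merged, and each peak carries its
minimum window q-value.

Reproducibility filtering keeps a peak iff its total overlap with the
other replicate's peaks is strictly greater than 10% of its own length.
The rule is applied to the peaks of both replicates (symmetric, preserving
replicate exchangeability; a one-sided mode exists), and kept peaks are
interval-merged. Gene annotation uses the window from 250 bp upstream of
the TSS through the TES (clipped at position 0); a gene is marked when the
summed overlap between its window and the merged peaks is strictly greater
than 150 bp — summed, because several peak fragments can jointly cover a
gene. Per-gene quantification regions are the union of all samples' peaks
overlapping the window, clipped to the window so that counts remain
attributable to the gene; a peak may mark several overlapping genes.

## Differential ubiquitination

Counting is region-first: per-gene peak regions are unified across all
samples before reads are counted, so a read spanning two adjacent peaks of
one gene counts once (it may count for several genes). Raw counts are
multiplied by each sample's α and rounded to integers (ties away from
zero) to keep the count likelihood well-defined; the effect is negligible
at realistic counts.

The Wald test models scaled counts per gene as negative-binomial with a
condition effect and **size factors fixed to 1**. This is the only
self-consistent choice after Rx scaling: median-of-ratios or total-count
size factors would re-center a genome-wide shift to zero and destroy the
signal the spike-in preserves. Both classic normalizations remain
available as explicit comparison modes (`normalization="total"` /
`"median-of-ratios"` in `analyze_chiprx`), which is also how the package
demonstrates the re-centering artifact.

Dispersion estimation is deliberately simpler than DESeq2's MAP estimator
and is validated by simulation calibration rather than bit-equivalence:
per-gene within-condition method-of-moments estimates (which may be
negative and are kept so for unbiased trend fitting), a mean–dispersion
trend a0 + a1/μ fitted by least squares with one 5×MAD trimming pass, and
shrinkage of the non-negative gene-wise estimate toward the trend weighted
by residual degrees of freedom against a prior weight of 8 — at 2 residual
df (2+2 replicates) the trend dominates, which is what makes the test
calibrated there (null type-I error ≈ 5% at p < 0.05 in NB simulations).
A group with mean zero is floored at 0.5/n so the fold change stays
finite; genes with zero counts in every sample are flagged and excluded
from the FDR universe. The Wald statistic is log2FC/SE with SE from the NB
Fisher information, two-sided normal p-values, BH adjustment over the
tested universe (genes with a peak region in at least one condition), and
hyper/hypo/ns calls at FDR < 0.01. Cook's-distance outlier handling and
independent filtering are out of scope. Expression changes are consumed
only as an external gene-keyed table and inner-joined for H2Bub-vs-
expression comparisons.

## Histone-PTM statistic

Raw XIC areas are log2-transformed and normalized **per run** by
subtracting that run's reference-peptide log2 area (unmodified H2B peptide
YNKKPTITSR by default; the reference is configurable per histone since
only the H2B reference is canonical). Per-run subtraction is the reading
under which normalization removes run-level loading differences exactly —
the package verifies this invariance on synthetic tables. Per peptide and
genotype, the mean and a 95% confidence interval (stated by its 5% α
level: mean ± t(0.975, n−1)·s/√n) are computed; the mutant/wild-type
ratio is 2^(mean difference) with the wild type set to 1; the two-sided
Welch t-test (Welch–Satterthwaite df) gives the p-value; and a peptide is
flagged significant when p < 0.001 and the fold change exceeds 2 in either
direction. Technical injections, when present, are averaged into one value
per biological replicate before testing (a helper treats injections as
units if preferred). Peptides missing in more than one run of a genotype
are excluded with a reason.

At the boundary — a true fold change of exactly 2 — the strict >2-fold
filter necessarily fires in only about half of noisy replicate sets; the
flag is reliable for effects clearly beyond 2-fold, and the estimated
ratio itself is accurate far below that (see the benchmark outputs of
`scripts/acceptance.py`).

## The synthetic-data generator

`simulate_chiprx_experiment` emulates a two-condition × two-replicate
spike-in design. Genes (default 1000, half marked, bodies 2000 ± 300 bp)
are placed on a 6 Mb target chromosome with Dirichlet-distributed gaps.
Input libraries sample the chromatin mix uniformly: the spike-in fraction
is nominally 3% with per-replicate lognormal jitter (ln-sd 0.1), shared by
the IP of the same replicate. IP libraries sample the target genome with
per-base weight 1 outside marked bodies and weight
enrichment × global_scale × gene_fc inside them — the pulldown over a
marked body is proportional to the amount of mark present, so a
genome-wide scale of 0.4 reduces every marked gene's IP signal to 40%.
Per-gene enrichment is lognormal around 8-fold (ln-sd 0.15). Spike-in
chromatin is recovered in the IP at a constant efficiency relative to the
nonspecific recovery of unmarked target chromatin (default 1.0 — the real
efficiency is not identifiable from published counts, and only its
constancy across samples matters for α; a per-sample override exists).
Reads are fixed-length 50 bp, uniform within their source region, with
exactly `reads_per_library` (default 2×10^5) reads per library before
deduplication.

What the generator does **not** model: fragment-size distributions and
read shifting, GC/mappability bias, PCR-duplicate structure, sequence
content (no FASTQ), chromatin-state heterogeneity within gene bodies, and
partial mark loss localized to sub-regions. Passing tests therefore
demonstrate that the quantification, scaling and testing machinery recover
known count-level truth — not that peak shapes or other read-level
artifacts of real libraries are handled.

`simulate_ptm_table` generates log2 areas as peptide baseline + genotype
effect + per-sample offset + Gaussian noise, with the reference peptide's
effect fixed at 0 and offsets applied equally to all peptides of a run so
reference normalization removes them exactly.

## Problem sizes and numerical choices

The benchmark runs behind the test suite and `scripts/acceptance.py` use
1000 genes and 2×10^5 reads per library; differential-calling performance
is pooled over 20 simulation seeds and PTM recovery over 200 replicate
tables — sizes at which every quantity of interest is stable while a full
run stays in the minutes range on one CPU. Known limitations worth
restating: with two replicates per condition, the per-seed Rx factors
carry ~2% sampling noise that shifts all genes of a run coherently, so
occasional clustered false positives appear near the FDR threshold
(pooled false-discovery proportion ≈ 4% at nominal 1% in the benchmark);
genes immediately adjacent to a marked domain can be marked through the
upstream annotation window, which is a property of the published
annotation rule on compact genomes rather than a caller error; and the
normal reference for the Wald statistic is an approximation at two
replicates that the trend-dominated dispersion shrinkage keeps calibrated
in simulation but that real, more dispersed data could strain.
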