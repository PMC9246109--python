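# Methods

This note documents the models and procedures implemented in `embryoarrest`,
the defaults that matter, and what the synthetic cohorts do and do not
establish.

## Synthetic cohorts

The generator (`embryoarrest.simulate`) emulates a combined single-embryo /
single-cell RNA-seq study of human preimplantation development with arrested
and treated embryos. One cohort consists of 8 presumed-normal embryos at each
of 11 stages (oocyte, zygote, 2-/4-/8-cell, morula, E3–E7), 23 arrested
embryos planted as Types I/II/III = 10/7/6, and 4 treated embryos; 6000 genes
split near-equally over chr1–chr22, chrX, chrY plus 400 genome-wide
transposable-element (TE) aggregate features.

**Expression model.** Each feature has a baseline log2 abundance
(genes ~ N(3, 1.5), TEs ~ N(1.5, 1.5)). The baseline spread is deliberately
moderate: it yields a log-normal expression distribution in which no single
gene dominates a chromosome's tag share, so same-stage embryos differ in
per-chromosome share by only a few percent — the regime expression
karyotyping operates in on real data. Per-stage program deviations follow a
mean-reverting walk in log2: marginal sd `stage_profile_sd` (default 1.0)
with correlation 0.5 between adjacent stages, damped to 0.3× through the
8-cell stage. The damping encodes the biology of the cleavage window, where
transcriptome dynamics are dominated by the two explicitly planted programs
rather than by lineage differentiation:

* **maternal decay** (10% of genes): log-linear monotone decline from oocyte
  to 8-cell totalling 2.2–4.0 log2 (≥4.6-fold), flat afterwards;
* **major ZGA** (10% of genes): flat through the 4-cell stage, a 2.2–4.0
  log2 step at the 8-cell stage, maintained afterwards.

A mean-reverting rather than cumulative walk keeps the dynamic range bounded
along the trajectory while still separating adjacent stages by ~1 log2 per
gene — the property that makes morula-like and E4-like arrest classes
distinguishable by correlation clustering, as they are in real embryos.

Stage profiles are scaled by one global constant (geometric mean of stage
totals to the nominal depth of 10⁶); per-stage renormalization would dilute
the planted ZGA fold change below the 4-fold derivation rule.

**Noise.** Counts are negative binomial with variance μ + φμ² (gamma–Poisson
mixture; φ = `nb_dispersion` = 0.1, φ = 0 degrades to Poisson). Library
depth is log-normal (sd 0.3). GC bias multiplies each gene's mean by a
scaled logistic in GC fraction centered at 0.5 with amplitude 0.3
(multiplier 1.0 exactly at amplitude 0); TE aggregates carry no GC value and
no bias.

**Arrest classes.** Type I uses the 4-cell profile (maternal and ZGA genes
frozen at their 4-cell levels) with all TE features ×2² — an MZT-failure
state with epigenetic derepression. Type II uses the morula profile with
ribosomes and nucleosomes −1.5 log2, glycolysis −1, MYC targets −1, OXPHOS
+1, p53 targets +1.5, and the marker genes CDKN1A (p21) +2 / CCNA2 −2 on top
of their set effects. Type III uses the E4 profile with ribosomes −1.5,
glycolysis −1, OXPHOS −1, p53 targets +1.5. Treated embryos are
Type III-like but with glycolysis at normal levels and the fatty-acid
program +1 — a metabolically rescued state. Effect sizes are free
parameters of the generator (the arrest literature reports directions, not
magnitudes); they are chosen large enough to be unambiguous at single-embryo
depth and are all recorded in the ground truth.

**Aneuploidy.** Six samples (four normal, two arrested by default) receive a
whole-chromosome dosage of 1.5 (gain) or 0.5 (loss) applied multiplicatively
to every gene on one autosome. Mosaic (sub-embryo) events are out of scope.

**What the cohorts are not.** No read-level phenomena (mapping, multimapping
TE assignment), no zero-inflation/dropout beyond NB sampling, no batch
structure between the combined public datasets, no cell-level heterogeneity
within an embryo, and stage labels are exact. Passing recovery tests on
these cohorts demonstrates the pipeline's statistical machinery is correct
and calibrated under its stated model — not that the biological conclusions
transfer to any particular real dataset.

## Normalization

Size factors are plain median-of-ratios over genes positive in all samples,
rescaled to geometric mean 1. GC correction is within-sample full-quantile
normalization across 10 equal-occupancy GC bins: each bin's value
distribution is mapped onto the pooled distribution of all GC-annotated
genes in that sample (ranks preserved within bins, per-sample binned total
preserved exactly; features without GC pass through). Full-quantile binning
was chosen over loess regression as deterministic and hyperparameter-free.
One consequence worth knowing: with B-gene bins the quantile map perturbs
each gene by order-statistic noise of roughly σ·√(p(1−p)/B)/φ(z) even when
no bias exists (≈6% median at 600 genes/bin), so the transform is
near-identity only in distribution, not gene-by-gene. log2 NTC uses
pseudocount 1 (zeros stay 0). Z-scores are per feature against the reference
mean and population sd (ddof = 0); zero-variance features get Z = 0 with a
logged warning.

## Differential expression

The NB Wald test operates on size-factor-normalized counts: group means
floored at 0.5, per-gene dispersion by method of moments pooled across the
two groups (floored at 10⁻⁸), delta-method SE of the log fold change from
the NB variance of each group mean, two-sided normal p, BH q over tested
features; all-zero features are excluded and reported. The DE flag is
|log2FC| ≥ 2 and q ≤ 0.01. There is deliberately no dispersion shrinkage,
outlier filtering, or LFC shrinkage — downstream logic consumes only the
fold/q flag, and the simplification keeps the test reproducible from this
document alone. Null simulations at n = 8 vs 8 show the q ≤ 0.01 family
stays essentially empty (fraction ≈ 0.002), and genes planted above the
4-fold rule (2.2–4.0 log2) are flagged at ≈98% — note that a gene planted
*exactly* at 4-fold is flagged only ~half the time, since its estimate is
centered on the threshold; no test can do better under symmetric noise.

## MZT scoring

ZGA and maternal-clearance sets come from the normal 2-cell vs 8-cell
contrast under the standard DE rule (genes only; TEs are analyzed
separately). The completion index is mean Z over ZGA genes minus mean Z over
maternal genes. The failure cutoff is the midpoint of the median completion
index of normal 4-cell and normal 8-cell embryos — an explicit, testable
stand-in for a threshold the source analyses display but do not state; it is
exposed as an override. Eligibility: normal embryos are candidates only from
the 8-cell stage onward (pre-MZT embryos are never "failures"); arrested and
treated embryos are always candidates because they are collected days after
the MZT should have completed, even though their transcriptomes place
earlier — that is precisely the failure mode being detected.

## Arrest typing

Typing clusters only the arrested embryos: top-2000 most variable genes by
log2 NTC variance (deterministic lexicographic tie-break; the count is a
config knob — recovery holds for 1000–4000), pairwise Pearson correlation,
Euclidean distance between correlation-matrix rows, complete linkage,
optimal leaf ordering, cut at k = 3. Each cluster's nearest stage is the
candidate stage (2-cell through E4) minimizing the DE-gene count against the
cluster, ties toward the earlier stage. Labels follow developmental order of
nearest stage: earliest → Type I, then II, III; stage ties break by cluster
size. Distance is computed on correlation-matrix rows (not 1 − r directly),
matching the co-correlation-heatmap construction.

## Expression karyotyping

Per sample, each chromosome's proportion of placed-gene normalized signal is
compared with the normal embryos of the same stage: z = (p − median)/
(1.4826·MAD), falling back to the sd when the MAD is 0; |z| > 3 calls a gain
or loss, and a sample is aneuploid if any chromosome is non-neutral. Robust
center/scale is used because real reference stages contain true aneuploids.
Planted 1.5×/0.5× dosages are recovered with sensitivity 1.0 and a
per-chromosome false-call rate ≈0.05. **Known limitation:** the per-sample
aneuploid flag is anticonservative by construction. Even a perfectly
Gaussian-calibrated z flags 1 − 0.9973²⁴ ≈ 6% of euploid samples at
threshold 3, and estimating the scale from 8 stage-matched references
inflates the per-chromosome tail to 3–7%, so a majority of euploid samples
show at least one flagged chromosome. Meaningful per-sample calls on small
reference groups need either much larger references, a higher threshold, or
a multiplicity-aware rule; the package reports the per-chromosome z table so
users can apply their own.

## Signatures and GSEA

Set scores are sums (or means) of per-gene Z over present members (≥50% of
a set required). Metabolic coordinates are pass-throughs of two sum-scores
(glycolysis on x, OXPHOS on y). TE fraction is 100 × TE tags / all tags on
the normalized matrix. Preranked GSEA ranks features by a supplied metric
(default: signed Wald statistic) with lexicographic tie-breaks; ES is the
maximal deviation of the weighted running sum (hit weight |metric|^p,
p = 1 by default; miss penalty 1/(N − m)); the null is n_perm random
same-size gene sets (gene-label permutations — sample permutations are
impossible from a ranking alone); NES divides ES by the mean same-sign null
magnitude; p uses the same-sign tail with a +1 correction; q is BH across
the tested sets. Default n_perm = 1000 (a config knob; larger values
sharpen small p-values at linear cost). Fixed seeds make results
bit-reproducible.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` evaluate 20 generator seeds at
the full default cohort for typing/MZT/aneuploidy/GSEA recovery, 10 seeds
for the all-euploid specificity cohort, 50 seeds × 10 genes for DE power,
and 3 strongly biased cohorts (amplitude 1.0) for GC-bias removal — sizes at
which every reported median is stable run-to-run while the whole suite
completes in well under a minute on one CPU.
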