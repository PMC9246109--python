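# embryoarrest

Around 60% of in-vitro-fertilized human embryos irreversibly arrest before
compaction. Single-embryo RNA-seq of such embryos shows they are not a single
state: some never complete the maternal-to-zygotic transition (MZT), while
others traverse it and settle into a senescent-like program with distinct
metabolic profiles. `embryoarrest` is a reusable, tested re-implementation of
that analysis for anyone working with staged single-embryo or single-cell
count matrices:

* **Normalization** — median-of-ratios size factors, then within-sample
  full-quantile normalization across GC-content bins producing normalized tag
  counts (NTC), log2 NTC, and per-gene Z-scores.
* **Differential expression** — a simplified negative-binomial Wald test with
  Benjamini–Hochberg correction; a feature is called DE when it changes at
  least 4-fold with q ≤ 0.01. Welch's two-sided *t* is provided for gene- and
  set-level comparisons.
* **MZT scoring** — major-ZGA genes are those significantly up-regulated
  >4-fold from the 2-cell to the 8-cell stage, maternal-clearance genes those
  significantly down-regulated; each embryo gets a completion index
  (mean Z over ZGA genes − mean Z over maternal genes) and embryos past the
  8-cell stage that fall below the 4-cell/8-cell midpoint are flagged as MZT
  failures.
* **Arrest typing** — arrested embryos are clustered on their pairwise
  Pearson co-correlation matrix (Euclidean distance, complete linkage,
  optimal leaf ordering) into three classes; each class is assigned the
  developmental stage with the fewest DE genes against it (Type I ≈ 4-cell,
  Type II ≈ morula, Type III ≈ E4).
* **Expression karyotyping** — each chromosome's share of a sample's
  normalized signal is scored against stage-matched references with a robust
  Z (median center, 1.4826·MAD scale); |z| beyond the threshold calls a
  whole-chromosome gain or loss.
* **Signatures** — gene-set activity as the sum or mean of per-gene Z-scores
  (ribosome / nucleosome / p53-target rankings, glycolysis-vs-OXPHOS
  metabolic coordinates), percent of normalized tags mapping to transposable
  elements, and preranked GSEA (weighted Kolmogorov–Smirnov enrichment score,
  gene-label permutation NES and p, BH q).
* **Synthetic cohorts** — a generator that emulates the full study design
  (11 stages from oocyte to E7, negative-binomial counts with library-size
  and GC bias, planted maternal/ZGA programs, three arrest classes, a treated
  state, whole-chromosome dosages) and records the complete ground truth, so
  every stage of the pipeline is verifiable without downloading anything.

## Worked example

```python
import embryoarrest as ea
from embryoarrest.pipeline import run_pipeline

params = ea.GeneratorParams(seed=1)          # the default study conditions
m, ann, st, truth = ea.simulate_dataset(params)
res = run_pipeline(m, ann, st)

res.typing.type_label.value_counts()         # I 10, II 7, III 6
res.typing.nearest_stage                     # {I: c4, II: morula, III: E4}
int(res.mzt_table["mzt_failed"].sum())       # 10  (exactly the Type I embryos)
res.te_percent[truth.samples_of_type("I")].mean()   # 8.6 (% TE tags, vs 2.3 at 4-cell)
res.dosage_z.loc["E5_02", "chr14"]           # -6.7 (planted chr14 loss, called)
```

On this cohort the three recovered clusters coincide exactly with the planted
arrest types and sit nearest the 4-cell, morula and E4 stages; all ten
planted Type I embryos — and no Type II/III embryo — are flagged as MZT
failures; and all six planted chromosome dosages exceed |z| = 3 with the
correct sign (e.g. the planted chr14 loss at z = −6.7). The same pipeline
runs from the shell:

```bash
embryoarrest --seed 1 --out-dir data simulate
embryoarrest --out-dir out run-all data
# or stage by stage: normalize, de, mzt, type, aneuploidy, score, gsea
```

To analyze the study's deposited matrix instead, download it manually from
the figshare record referenced by the study, place it in the dataset-
directory layout (`matrix.mtx` + `features.tsv` + `samples.tsv` +
`feature_annotation.tsv` + `sample_table.tsv`, or dense TSV), and run the
same subcommands; the loader accepts either gene symbols or stable IDs as
long as the annotation table uses the same identifiers.

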