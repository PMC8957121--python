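# gbmseesaw

Does changing a gene's body methylation change its transcription? In
invertebrates (corals, anemones, insects), gene body methylation (GBM) is
bimodal — genes fall into a lowly and a highly methylated class — and
baseline GBM correlates positively with expression level and negatively
with expression variability. Whether *changes* in GBM between conditions
drive *changes* in transcription, including the "seesaw" idea that the two
methylation classes shift reciprocally, is the open question this package
operationalizes.

`gbmseesaw` is a tested, reusable pipeline for whole-genome bisulfite
(WGBS), MBD-seq, mdRAD, and RNA-seq summaries of that question. It starts
from the standard upstream outputs (per-CpG cytosine reports, gene models,
gene×sample count matrices) and computes:

* **GBM level** per gene and sample: percent methylation pooled over the
  gene's CpG sites, `pct = 100 · Σ meth / Σ (meth + unmeth)`, reported on
  the log₂ scale with zeros assigned the dataset's smallest non-zero value;
  promoter levels over strand-aware 1 kb upstream windows; MBD-scores
  (log₂ captured/unbound RPKM) and mdRAD RPKM as capture-based proxies.
* **Differential methylation**: per-gene binomial GLM of the per-sample
  (methylated, total) counts on condition, closed-form likelihood-ratio
  test against χ²₁, optional Pearson overdispersion correction,
  Benjamini–Hochberg FDR.
* **Differential expression**: median-of-ratios normalization, per-gene
  negative-binomial dispersion by method of moments, Wald test on the log₂
  fold change with a delta-method standard error, BH FDR.
* **Class and seesaw analysis**: a hard 2.5 % cutoff splits genes into
  low/high GBM classes; baseline correlations (GBM vs expression, vs
  |Δexpression|, vs CV across control replicates); the correlation of
  per-gene ΔGBM with Δexpression (all genes, or FDR ≤ 0.1 subsets); and a
  bootstrap test of the three seesaw components — (1) reciprocal class
  shifts in GBM, (2) reciprocal class shifts in transcription, (3)
  transcription moving opposite to GBM within each class.
* **Synthetic studies**: a fully parameterized generator (bimodal Beta
  mixture of methylation levels, Poisson/binomial CpG counts, NB
  expression tied to GBM, tunable ΔGBM–Δexpression coupling ρ, plantable
  class-level seesaw shifts) with a truth table, so every stage is
  verified by parameter recovery without downloading anything.

## Worked example

Simulate a 500-gene study with *no* planted methylation–expression
coupling and run the full analysis:

```bash
printf '[sim]\nn_genes = 500\nn_contigs = 5\nseed = 42\n' > sim.toml
gbmseesaw simulate --config sim.toml --outdir data
gbmseesaw run --config data/study.toml --outdir results
```

`results/correlations.tsv` then contains (seed 42):

```
variable_x        variable_y            n    r            method   subset
log2_gbm          mean_log2_rpkm        500  0.899711688  pearson  all
log2_gbm          abs_log2_fold_change  497  -0.00380483  pearson  all
log2_gbm          cv                    500  -0.55009346  pearson  all
log2_meth_ratio   log2_fold_change      497  0.09647610   pearson  all
log2_meth_ratio   log2_fold_change      144  0.16803855   pearson  de_only
log2_meth_ratio   log2_fold_change      327  0.08738322   pearson  dm_only
```

Read: baseline GBM strongly predicts expression level (r = 0.90) and
expression variability (r = −0.55 with CV), while the change–change
correlation is near zero (r = 0.10 at n = 497; at the default 2,000-gene
study size this settles around |r| < 0.05) — the generator planted ρ = 0
and the pipeline says so. `results/seesaw_components.tsv` reports all
three seesaw components `not_supported`: with no planted class shifts the
bootstrap CIs of the class-level mean changes span zero.
`results/classes.tsv`, `diff_gbm.tsv`, `diff_expr.tsv`, `diff_promoter.tsv`
and `seesaw_summary.tsv` hold the per-gene and per-class detail. Rerunning
with the same config and seed reproduces every file byte for byte.

Real data enter the same way: a sample sheet pointing at Bismark-style
cytosine reports, gene models as GFF3 or BED, and FeatureCounts-style
count tables (see `data/study.toml` written by `simulate` for the layout).

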