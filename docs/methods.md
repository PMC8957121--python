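# Methods

## Quantities and models

**GBM level.** For gene *g* and sample *s*, methylated and total read
counts are summed over every CpG record whose position lies within the
gene's 1-based inclusive bounds (both strands pooled, no symmetric-CpG
collapsing; overlapping genes each receive all CpGs in their own bounds):

    pct(g, s) = 100 · Σ meth / Σ (meth + unmeth)

Cells with summed coverage below `min_gene_cov` (default 10 reads;
0 disables) are missing, as are genes with no covered CpG. The per-gene
level is the mean of per-sample percents over non-missing samples. For
log₂ display and correlation, zeros are first assigned the smallest
non-zero value in the dataset; an all-zero dataset is an error because
that substitute is undefined. Promoter windows are the 1 kb immediately
upstream of the 5′ end (strand-aware), clipped to the contig and never
overlapping their own gene body; they are quantified by the same rules.

**Capture-based proxies.** The MBD-score is the log₂ ratio of
captured-fraction to unbound-fraction RPKM, averaged over library pairs;
one read is added to every cell before RPKM so the score is finite and
antisymmetric under swapping the fractions. mdRAD methylation is plain
RPKM = count / (length_kb · libsize/10⁶). Genomic coverage is estimated
as mean deduplicated reads × combined pair length / genome length.

**Differential methylation.** Per gene, the per-sample (meth, total)
pairs follow a binomial GLM with a condition indicator. Because the
group-wise MLEs are the condition-pooled proportions, the
likelihood-ratio statistic against the intercept-only model is computed
in closed form and referred to χ² with 1 df (verified against an
iterative GLM fit in the test suite). Complete separation (a pooled
proportion at 0 or 1) leaves the boundary log-likelihood finite and
exact; such genes are flagged `separated`. With
`overdispersion="pearson"`, the statistic is divided by the null-model
Pearson dispersion when it exceeds 1, which can only make p-values more
conservative. Effects are reported as percentage-point differences of
pooled percents and as the log₂ ratio of pseudocounted pooled
proportions (0.5 reads added to each of the methylated and unmethylated
pools). Genes need `min_samples_per_condition` (default 2) eligible
samples per condition to be tested. Under a pure binomial null
(coverage ~Poisson(30)/CpG, 3 samples per condition, 20,000 genes) the
measured type-I error at α = 0.05 is ≈ 0.051–0.053.

**Differential expression.** Counts are normalized by median-of-ratios
size factors (per sample, the median over genes of count divided by the
gene's geometric mean across samples; when no gene is positive
everywhere, geometric means use each gene's positive entries and the
median runs over genes positive in that sample). Note that scaling one
column scales factor *ratios* exactly, not the individual factors,
because the geometric means move too. The effect is
log₂((m₂+0.5)/(m₁+0.5)) of normalized condition means. The per-gene NB
dispersion α is a method-of-moments estimate pooled across the two
conditions, floored at 10⁻⁸, giving the plug-in variance of a condition
mean (m + α m²)/n. The Wald statistic divides the log₂ fold change by a
delta-method standard error whose per-condition variance is the larger
of the NB plug-in and the empirical variance of the group mean, and is
referred to a t distribution with n₁+n₂−2 df. The empirical floor and
the t reference are deliberate: with the plug-in variance alone and a
normal reference the test is badly anticonservative at 3–6 replicates
(measured type-I ≈ 0.088 at α = 0.05 under the NB null with n = 6,
mean 100, dispersion 0.2); the floored-variance t version measures
0.041–0.049 across seeds at n = 3 and n = 6. No independent filtering
and no dispersion shrinkage are applied. Genes with total raw count
below `min_total` (default 10) are untested. Both differential tables
are Benjamini–Hochberg adjusted over their tested genes, separately per
contrast and assay.

**Classes, correlations, seesaw.** Genes are classed `high` iff mean
percent methylation ≥ 2.5 % (a closed upper class makes the tie
deterministic). Correlations default to Pearson on the log₂-scaled
quantities that are plotted in this field; Spearman is available by
flag. The change–change correlation pairs the methylation effect
(default `log2_meth_ratio`) with the expression log₂ fold change on the
gene intersection, optionally restricted to expression- or
methylation-significant genes (q ≤ 0.1). The seesaw test reports, per
class × variable, the mean shift over all genes with a non-missing
effect and a seeded percentile bootstrap 95 % CI over genes
(B = 2000); classes under 20 genes give no verdict. Component (1) is
`supported` iff both classes' ΔGBM CIs exclude zero with opposite
signs; (2) likewise for Δexpression; (3) iff within each class the GBM
and expression verdicts are non-null and opposite; any missing verdict
makes a component `inconclusive`. Bootstrapping operationalizes what is
otherwise a visual density-shift judgement; values are processed in
gene-id order so results are independent of input row order.

## The synthetic generator

`simulate_study` builds a complete study from one seed. Genes (default
2,000 on 20 contigs) get log-normal lengths (median 2 kb, log-sd 0.6)
and are laid head-to-tail with log-normal intergenic gaps. Each gene
draws a mixture component (P(high) = 0.4) and a baseline methylation
probability from Beta(mean 1 %, concentration 50) or Beta(mean 60 %,
concentration 10) — reproducing the bimodal GBM histogram (the valley
between the log₂ modes spans ≈ 4–6 log₂ units at defaults). CpG sites
are uniform within genes at 20/kb, plus ~10 % intergenic sites; per
sample, site coverage is Poisson(30) and methylated counts are binomial
at the gene's probability. Condition-2 shifts act on the logit scale so
probabilities stay in (0,1): ΔGBM = class seesaw mean + 1.0 × gene
noise; Δlog₂-expression = class seesaw mean + 1.5 × gene noise. The two
noises share a latent standard normal with loading √|ρ| each, so their
correlation converges to `delta_coupling_rho` (realized 0.50 ± 0.01 at
10,000 genes for ρ = 0.5). Baseline mean log₂ RPKM is
3.0 + 0.35 · log₂(percent methylation), and NB dispersion is 0.4 for
the low class vs 0.1 for the high class, which yields the positive
GBM–expression correlation (r ≈ 0.9) and the negative GBM–CV
correlation (r ≈ −0.5) seen in real studies. MBD captured/unbound and
mdRAD counts have expectations increasing in the methylation
probability. The truth table records, per gene, the mixture component,
the class label (the 2.5 % cutoff applied to the gene's average
methylation probability across the two conditions — the estimand of the
all-samples mean percent the classifier uses), the baseline probability,
and both planted shifts.

Randomness flows through named substreams derived from the single seed,
one per variable, so enlarging a study extends rather than reshuffles
earlier genes' draws.

The planted-change spreads (logit sd 1.0 for methylation, log₂ sd 1.5
for expression) were chosen for detectability — large enough that the
per-gene effect estimates retain most of the planted signal (measured
reliabilities ≈ 0.80 and 0.92) — not as estimates of real effect sizes;
published invertebrate GBM responses are, if anything, smaller. What
passing tests show is therefore that the pipeline recovers structure the
generator actually planted at these magnitudes; they do not show power
at weaker, more realistic magnitudes, and the generator omits batch
effects, mapping bias, bisulfite conversion error, and read-level
artefacts entirely.

## Known limitations of the seesaw readout

Two quantitative caveats, both measured with this package's own tools:

1. **Boundary selection (regression to the mean).** Classes are assigned
   from methylation averaged over *all* samples of both conditions, as
   the field's figures do. Genes near the 2.5 % cutoff are therefore
   sorted partly by the sign of their own methylation change: a
   borderline gene that went up lands in the high class, one that went
   down stays low. Under a null with per-gene methylation noise (logit
   sd 1.0) this biases the class-mean ΔGBM by about −0.1 log₂ (low
   class) and +0.03 (high class). At the default 2,000-gene size the
   bootstrap CIs usually span these biases, but in roughly 10–40 % of
   seeds (batch-dependent) — and systematically at 10,000 genes, where
   CIs are tighter than the bias — component (1) is spuriously
   "supported". A reciprocal class-level GBM
   shift alone is thus weak evidence; classifying on control samples
   only would remove the artefact but departs from the standard
   procedure, so it is not the default here.

2. **Attenuation of change–change correlations.** The recovered
   Pearson r between estimated ΔGBM and Δexpression is the planted ρ
   times the product of the two measurement reliabilities. At the
   default coverage (20 CpG/kb × 30× × 3 samples) roughly a third of
   low-class genes carry fewer than ~5 methylated reads, capping the
   methylation-effect reliability at ≈ 0.80; with expression reliability
   ≈ 0.92, a planted ρ = 0.5 is recovered as r ≈ 0.35–0.37. Observed
   change–change correlations understate the latent coupling, and a
   near-zero observed r bounds the latent coupling only up to this
   attenuation factor.

## Numerical and interface choices

Internal coordinates are 1-based inclusive everywhere; BED is converted
at the boundary and round-trips exactly. Only CpG-context records
("CpG"/"CG", case-insensitive) are retained. Floats are written with 9
significant digits so tables round-trip to 10⁻⁹ relative; missing values
serialize as `NA`. Every output carries a `#` provenance line with the
package version and resolved parameters; `run` writes a deterministic
`run.log` with parameter values, input checksums, and per-stage row
counts. All analysis randomness (the bootstrap) and all generator
randomness are seeded; reruns are byte-identical. The acceptance script
sizes its simulations at 2,000 genes for rate estimates over 10 seeds
and 10,000 genes for correlation estimates, and 20,000 genes for the
calibration nulls, the sizes at which the respective quantities are
stable to the precision reported.
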