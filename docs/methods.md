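# Methods

## Problem and approach

`scallele` analyses allele-specific expression in single-cell RNA-seq when no
genotypes are available. The key idea: because the two alleles of a gene are
often expressed in different single cells, pooling reads across all cells of
one individual exposes heterozygous SNPs (hetSNPs) directly — each allele
accumulates reads from the cells in which it happened to be active. Once
hetSNPs are known, per-cell allelic read depths at those sites quantify
monoallelic (MA) versus biallelic (BA) expression, per site, per gene, and
per cell type.

The pipeline stages are:

1. **hetSNP calling.** Reads of all cells of an individual are pooled per
   candidate site (a dbSNP-style list). A site is heterozygous when each of
   the two candidate alleles has at least `pooled_depth_cutoff` reads
   (default 20). Sites whose reference allele is effectively absent from the
   pooled pileup — the reference base unobserved, or both the alternative
   allele and the "neither allele" reads strictly out-supporting it — are
   excluded first. With truth genotypes (an F1 cross, or a simulation) the
   cutoff sweep yields a calibration curve of positive predictive value
   (PPV) and true-positive rate per cutoff.
2. **Per-cell classification.** For every (hetSNP, cell) with
   n = ref + alt ≥ 1 reads, an exact binomial test of k = ref against
   Binomial(n, ½) is computed; p-values of one individual are adjusted
   jointly by Benjamini–Hochberg. The verdict is **MA** if the adjusted
   p < `ma_fdr` (0.05) and strictly more than `ma_ratio` (95%) of reads come
   from one allele; otherwise **BA** if both alleles have at least
   `ba_min_allele_reads` (2) reads; otherwise **Unknown**. MA precedes BA by
   construction. Reads matching neither candidate allele are never counted.
3. **Gene level.** SNPs mapping to exactly one gene are aggregated per
   (gene, cell) with the hierarchy BA > MA > Unknown: any BA SNP makes the
   gene BA; only-MA (plus Unknowns) makes it MA. Genes with exactly two
   determinate SNPs provide an internal consistency audit (MA–MA / BA–BA vs
   MA–BA).
4. **Cell-type level.** Per cell, expressed genes (FPKM > 0) are ranked and
   the top `expr_percentile` (30%) retained; ties are broken by gene id so
   results are deterministic. A gene is cell-type MA when at least
   `min_supporting_cells` (4) cells support it (gene MA *and* inside that
   cell's top-percentile mask) and *no* cell of the type shows it BA; any BA
   cell makes the gene cell-type BA regardless of expression rank; Unknown
   calls neither support nor veto.
5. **Pseudo-bulk pooling.** Reads pooled per individual (× cell type) give
   per-site reference-allele ratios; their histogram in 0.1-wide bands and
   the fraction inside [0.4, 0.6] summarise how random monoallelic
   expression averages out as cells are pooled. Imprinted genes are the
   control that must *not* average out.
6. **Disrupted alleles.** Per annotation scheme (SNV class S/N/L/G; SIFT
   S/T/D; PolyPhen HDIV/HVAR S/B/P/D), two views: cells expressing each
   allele (≥ 2 reads) per hetSNP, and reference-read fractions at
   observations with both alleles ≥ 2 reads and total ≥ 10. Contrasts use
   one-sided Wilcoxon rank-sum tests (exact null when both samples ≤ 25 and
   tie-free, normal approximation with tie correction otherwise; no
   continuity correction, so identical samples give p = 0.5 exactly).
7. **Specificity statistics.** Within-type vs between-type overlap of MA
   gene sets under cell resampling (`n_permutations` = 1000 draws, two-sample
   t-test of overlap means), split-half overlap, subsampling saturation
   curves (exact enumeration when C(n, k) ≤ the iteration budget), and
   shared-MA-allele percentages between cell pairs.

## Synthetic-data generator

Every analysis is driven end-to-end by a generator with known ground truth.
Per gene: 1–3 truly heterozygous sites (default 80/14/6%) plus a Poisson
number of homozygous candidate sites tuned so a fraction `frac_het_sites`
(default 0.5) of candidates is heterozygous. Gene modes: `random_MA` (one
allele chosen uniformly per cell; default 55% of genes), `biallelic` (each
allele independently active per cell; 35%), `imprinted` (one fixed parental
allele; 10%). Allele activity is Bernoulli with `burst_prob_active_allele`
(0.9) — a deliberately simple stand-in for two-state bursting kinetics that
keeps every downstream expectation analytically checkable. A `random_MA`
gene can be tied to specific cell types (`celltype_specific_ma_frac`),
behaving biallelically elsewhere; this is what gives the specificity
permutation test a known signal.

Read depths: per (gene, cell, allele) a transcript-pool depth is drawn from
a negative binomial with mean `depth_mean` (30) × a log-normal per-gene
scale (σ = 1.5, giving the orders-of-magnitude FPKM spread of real data) and
dispersion 2.0. All heterozygous sites of a gene read from that shared pool,
so with zero technical noise two SNPs of one gene agree exactly — the
property behind the two-SNP consistency audit. Technical layers, applied per
site: allelic dropout (`dropout_prob`, default 0.1, zeroes one allele's
reads at one site), reference mapping bias (`ref_bias` ≤ 1 binomially thins
alternative reads), and sequencing error at homozygous sites (`seq_error`,
default 0.002 per read, spread uniformly over the three non-template bases
so only ~⅓ of errors match the recorded second allele; the remainder
surfaces as `other_depth`). Homozygous-site errors are the sole source of
false heterozygous candidates and hence the fuel for PPV calibration; they
are symmetric in hom-ref/hom-alt so the false calls do not bias allelic
ratios. FPKM is transcript-depth-proportional with a log-normal per-cell
factor (σ = 0.3), preserving the within-cell ranks that the top-30% filter
consumes.

Annotation classes are assigned **per gene allele** (one SNV consequence
class for a gene's alternative haplotype, inherited by all its sites; HVAR
agrees with HDIV 80% of the time). Alternative alleles flagged deleterious
(stopgain, SIFT-D or PolyPhen-HDIV-D) have their transcript pool divided by
`deleterious_penalty` (4), an NMD-style degradation. The per-gene assignment
is a simplification with two desirable consequences: the penalty acts on
whole transcripts, and synonymous sites never share a gene with a penalised
allele, keeping class S a clean 0.5 negative control (a residual reference
bias in class S appears only when `ref_bias` < 1 is configured).

Truth genotypes are global across simulated individuals (an F1-cross-like
cohort), which matches the calibration use case and keeps the truth tables
in the shape the recovery analyses need.

What the generator does **not** emulate: UMI chemistry, doublets, splice
isoforms, kinetic (two-state) bursting, positional coverage bias along
transcripts, and genotype differences between individuals. Passing tests
therefore demonstrate correctness of the inference rules under the stated
generative assumptions, not performance on any particular real dataset.

## Numerical choices

* Exact binomial p-values use the closed form min(1, 2·P(X ≤ min(k, n−k)))
  valid under the symmetric null; it matches `scipy.stats.binomtest` to
  1e-10 over the full grid n ≤ 40 and vectorises over all tests of an
  individual. A one-sided variant is available via `binom_alternative`.
* The BH family is all (site, cell) tests of one individual (configurable to
  per-cell). "> 95%" is implemented strictly: a ratio of exactly 0.95 is not
  MA.
* Overlap percentages between MA gene sets divide by the union
  (Jaccard × 100) by default; `min` and (for shared alleles) `both` are
  configurable. Draws whose denominator is empty are reported NaN and
  excluded from summaries.
* The reference-absent exclusion treats the pooled `other_depth` bucket as a
  single pseudo-base: a site is excluded when `pooled_ref == 0`, or when
  both `pooled_alt` and `pooled_other` strictly exceed `pooled_ref`. Ties
  keep the site.
* Saturation curves enumerate all C(n, k) subsets whenever that count does
  not exceed the iteration budget, and sample otherwise.
* All randomised procedures take explicit seeds; a fixed seed makes every
  output byte-identical across runs, including the CLI.

## Problem sizes

The bundled analyses and the reproduction script run on: a calibration
cohort of ~2000 candidate sites × 8 cells with 1% sequencing error; a main
cohort of 300 genes (~740 candidate sites) × 62 cells in five cell types; a
recovery cohort of 200 genes × 60 cells (20 per type, dropout 0.2); and a
specificity cohort of 150 genes with 24 + 12 cells. These sizes give stable
statistics (binomial standard errors on reported percentages of ≲ 1–2
points) while every driver finishes in seconds.

## Recovery evaluation

Recall of cell-type MA genes is computed over *assessable* truth-MA
(gene, cell type) pairs: the gene must lie in the top-30% expression mask
with a covered hetSNP call in at least `min_supporting_cells` cells of the
type. The expression-percentile filter is an explicit detectability gate of
the method — with realistic log-normal expression spread roughly a third of
truth-MA genes can ever clear it, for any caller — so unconditional recall
would measure the filter, not the caller. The false-call rate (truth-BA
genes called MA) is reported without any assessability condition.

## Known limitations

* The within- vs between-type permutation comparison fixes the second cell
  type's full cell set while resampling the first 1000 times. The two-sample
  t-test on the resulting overlap distributions is therefore
  pseudo-replicated: the "between" draws share one realised cell set, and as
  the number of draws grows the test statistic diverges even when the two
  cell types are statistically exchangeable. The *direction* of the
  difference is meaningful and is what the bundled analyses report; the
  p-value should be read as descriptive, not calibrated. A null-calibrated
  alternative would resample both cell types, which the design (one type
  exhausted by the comparison) does not permit.
* Gene-level MA status does not require the supporting SNPs to agree on the
  expressed allele (phasing is unavailable); allele concordance is exposed
  separately through the shared-MA-allele statistics.
* The binomial model ignores overdispersion of allelic ratios; a
  beta-binomial extension is out of scope.
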