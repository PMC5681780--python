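# scallele

Genotype-free allele-specific expression analysis for single-cell RNA-seq.

Most scRNA-seq datasets come without genotypes, yet allele-specific
expression needs heterozygous markers. `scallele` implements a pipeline that
discovers heterozygous SNPs (hetSNPs) directly from the scRNA-seq reads —
pooling all cells of an individual so that alleles expressed in *different*
cells both accumulate coverage — and then quantifies monoallelic (MA) versus
biallelic (BA) expression per site, per gene, and per cell type. It is aimed
at computational biologists studying random monoallelic expression,
imprinting, and the cellular expression of damaging alleles in
SMART-seq-style single-cell data.

## The statistics at the core

* A site is heterozygous when, after pooling an individual's cells, both
  alleles have ≥ c reads (default c = 20, chosen by calibrating PPV against
  truth genotypes over c = 1..30).
* Per (hetSNP, cell) with n = n_ref + n_alt ≥ 1 reads, an exact binomial
  test of n_ref ~ Binomial(n, ½) is BH-adjusted across the individual;
  **MA** requires FDR < 0.05 and max(n_ref, n_alt)/n > 0.95, **BA** requires
  min(n_ref, n_alt) ≥ 2 and not MA, the rest is **Unknown**.
* A gene is MA in a cell if its single-gene hetSNPs show only MA (any BA SNP
  makes it BA); a gene is MA in a cell type if ≥ 4 cells support it while the
  gene ranks in each supporting cell's top 30% of expressed genes, and no
  cell of the type shows it BA.
* Disrupted-allele contrasts (stopgain, SIFT/PolyPhen deleterious vs
  synonymous) use one-sided Wilcoxon rank-sum tests on expressing-cell
  counts and reference-read fractions; cell-type specificity uses
  within-type vs between-type overlap of MA gene sets under 1000-fold cell
  resampling.

A fully parameterised synthetic generator (gene modes random-MA / biallelic
/ imprinted, allelic dropout, transcriptional bursting, reference mapping
bias, homozygous-site sequencing error, NMD-style penalties on deleterious
alleles) produces every input format with ground truth, so the whole
pipeline is testable without external data. See `docs/methods.md`.

## Worked example

The numbered drivers under `analysis/` run the full study on simulated
cohorts and write tables under `results/`:

```bash
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_calibrate_hetsnp_cutoff.py
python analysis/03_classify_allelic_expression.py
```

which prints:

```
PPV rises with the pooled-depth cutoff: 70.72% at cutoff 1, 92.91% at 6,
99.28% at 20 (n_called 691, TPR 68.46%).
367 hetSNPs at cutoff 20; 19255 covered (site, cell) observations:
60.3% MA, 23.8% BA, 15.9% Unknown.
pseudo-bulk pooling: 41.9% of pooled hetSNP sites fall in the balanced
0.4-0.6 reference-ratio band.
```

Read: raising the pooled-depth cutoff trades sensitivity for precision —
at ≥ 20 reads per allele, 99.3% of called hetSNPs are truly heterozygous in
the simulated truth. At single-cell resolution most observations are
monoallelic (60%), yet pooling the same cells pushes 42% of sites into the
balanced 0.4–0.6 band: the two alleles are expressed in different cells,
mostly at random. Drivers 04–07 continue with the gene-level consistency
audit (93.0% of two-SNP genes agree), cell-type MA calling with saturation
and split-half stability, disrupted-allele contrasts (deleterious alleles:
median reference-read fraction 79% vs 50% at synonymous sites), and the
cell-type specificity permutation test.

The same stages are exposed as a CLI for file-based use:

```bash
scallele simulate --seed 5 --out-prefix sim
scallele call-hetsnps --counts sim.counts.tsv --metadata sim.metadata.tsv \
    --sites sim.sites.vcf --individual ind1 --out sim.hetsnps.tsv
scallele classify --counts sim.counts.tsv --hetsnps sim.hetsnps.tsv --out sim.calls.tsv
```

## Layout

```
src/scallele/       library: io, simulate, hetsnp, classify, genes,
                    celltype, disruption, stats, config, cli
analysis/           numbered drivers reproducing the study's analyses
tests/              pytest suite (unit, property and acceptance tests)
scripts/acceptance.py   end-to-end reproduction of the headline numbers
docs/methods.md     model, generator, numerical choices, limitations
```
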