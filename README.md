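# sweepenrich

Polygenic enrichment analysis of GWAS summary statistics in selected genomic
regions. The pipeline asks whether association signal for a trait is
concentrated in a set of annotated intervals (e.g. regions under recent
positive selection), using:

- **LD-weighted region annotation** — per-SNP sum of r² (values < 0.2 zeroed,
  self r² = 1) to reference-panel SNPs inside a region set, so SNPs that tag
  a region without lying in it are scored too.
- **Genomic control from intergenic SNPs** — λ_GC estimated as the median
  squared z-score of LD-pruned intergenic SNP sets (median over 100 pruning
  iterations) divided by the χ²(1) median 0.4549.
- **Conditional Q-Q and fold-enrichment curves** — stratified curve
  statistics restricted to −log10(p) < 7.3; the fold curve is the ratio of
  complementary ECDFs of −log10(p) (stratum vs. all SNPs), so enrichment
  shows as fold > 1.
- **Stratified LD-score enrichment regression** — E[χ²ⱼ] = 1 + N·a +
  N·Σ_c τ_c·ℓ(j,c) fit by two-step weighted least squares with a free
  intercept; per-category LD scores use the bias-adjusted estimator
  r̃² = r² − (1−r²)/(n−2), the extended MHC and its LD partners (r² > 0.1)
  are excluded, and a delete-a-block jackknife (200 contiguous blocks)
  provides coefficient and enrichment-fold standard errors.
- **Fisher meta-combination** — −2Σln p ~ χ²(2k) over trait groups.
- **A synthetic-data generator** — block-LD reference panels (Gaussian
  copula haplotypes), annotation tracks covering configured genome
  fractions, and z-scores drawn from the exact partitioned polygenic model
  the regression inverts, with ground truth returned for recovery tests.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (closed-form Fisher
checks, simulation-based fold recovery, null calibration, λ_GC recovery,
dense brute-force LD oracles, curve identities).

## CLI

```bash
# simulate a full synthetic dataset (panel, BED tracks, sumstats, truth)
sweepenrich simulate -c config.yaml -o outdir

# stratified curves
sweepenrich qq   --sumstats outdir/sumstats.tsv --bed HD=outdir/tracks/HD.bed --out qq.tsv
sweepenrich fold --sumstats outdir/sumstats.tsv --bed HD=outdir/tracks/HD.bed --out fold.tsv

# genomic control from intergenic SNPs
sweepenrich lambda-gc --sumstats outdir/sumstats.tsv --panel outdir/panel.tsv \
    --bed exon=outdir/tracks/exon.bed --bed intron=outdir/tracks/intron.bed \
    --bed utr3=outdir/tracks/utr3.bed --bed utr5=outdir/tracks/utr5.bed \
    --context genes=outdir/tracks/genes.bed

# stratified enrichment regression
sweepenrich regress --sumstats outdir/sumstats.tsv --panel outdir/panel.tsv \
    --bed HD=outdir/tracks/HD.bed --target HD --out enrichment

# Fisher meta-combination of per-phenotype p-values
sweepenrich fisher --input pvalues.tsv --out meta.tsv
```

Example simulation config:

```yaml
M: 20000            # SNPs
n_blocks_ld: 1000   # LD blocks (heterogeneous sizes)
block_rho: 0.5      # within-block latent correlation
n_panel: 300        # reference panel samples
N_gwas: 50000       # GWAS sample size
intercept_inflation: 1.0
rng_seed: 11
categories:
  base:   {fraction: 1.0,  tau: 2.63e-5}
  HD:     {fraction: 0.05, tau: 2.63e-5}
  exon:   {fraction: 0.04, tau: 0.0}
  intron: {fraction: 0.12, tau: 0.0}
```

## Conventions

- BED intervals are 0-based half-open; SNP positions 1-based (VCF style);
  a SNP is inside an interval iff `start < pos <= end`.
- LD windows are symmetric ±1 Mb by position (configurable).
- The 0.2 r² floor applies only to the LD-weighted region annotation
  scores; partitioned LD scores for the regression use unthresholded
  bias-adjusted r̃².
- Enrichment fold = (share of SNP-heritability in a category) / (share of
  SNPs in it); its standard error is obtained by jackknifing the ratio
  directly.
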