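# Methods

This note documents the statistical model behind `pathscore`, the design
choices made where several constructions were defensible, the synthetic
data generator's assumptions, and the problem sizes used by the test suite
and `scripts/acceptance.py`.

## Data model and QC

Genotypes are held as a subjects × SNPs dosage matrix counting copies of
the **minor allele**, determined empirically per dataset (ties at allele
frequency 0.5 keep the VCF ALT allele). Missing calls stay in the matrix
as NaN and are handled per operation (mean imputation inside the scoring
steps), never globally imputed. Coordinates are 1-based with closed
intervals; BED input is converted at the boundary.

QC applies the subject filter first (subjects with > 6% missing calls
removed), then the SNP filters on the surviving subjects: missing rate
< 10%, Hardy–Weinberg equilibrium p > 0.001, MAF > 1%. All three SNP
thresholds are strict inequalities. Subject-first ordering keeps SNP
statistics from being driven by low-quality subjects; the minor-allele
coding is re-derived after any subject removal. The HWE test is the 1-df
Pearson chi-square against expected genotype frequencies from the sample
allele frequency, without continuity correction, computed on all subjects
(cases and controls); a monomorphic SNP returns p = 1. For removal logging
the rules are applied in a fixed order (missingness → HWE → MAF) so each
removed SNP carries one deterministic reason.

SNP→gene assignment is purely positional: a SNP belongs to every gene
whose interval extended by a ±10 kb flank (closed on both ends) contains
it; strand is ignored and a SNP may belong to several overlapping genes or
to none.

## Gene scores

**PCA regression.** Per gene: mean-impute, drop SNPs monomorphic in the
analysis sample, standardise, eigendecompose the SNP correlation matrix,
and keep the smallest number *k* of leading components whose cumulative
eigenvalue fraction reaches the variance threshold (default 0.85; the
component that crosses the threshold is retained), capped at
min(n_snps, n_subjects − 2) and at the numerically positive spectrum.
Component signs are fixed by making each component's largest-magnitude
loading positive, so repeated runs are bit-identical. The gene score is
the overall F-test p-value of the OLS regression of the phenotype on the
*k* component scores plus intercept, against the intercept-only model.

A deliberate simplification: **ordinary least squares is used for both the
binary status and the continuous residual phenotype**. The conditioned
analysis feeds residuals through the identical machinery, and a single
linear framework keeps conditioned and unconditioned runs commensurable;
under the null the F-test on a 0/1 outcome is very close to uniform at the
sample sizes involved (the null-calibration tests check this directly). A
logistic variant is out of scope.

**Best SNP.** The raw statistic is the smallest per-SNP regression p-value
in the gene; the score is the add-one permutation estimator
(1 + r)/(B + 1), where r counts phenotype permutations whose within-gene
minimum p is at least as small. One permutation stream is generated per
phenotype and shared across genes, preserving between-gene score
correlation and fixing the cost. Because only the ordering of the per-SNP
statistic enters the comparison, the score is invariant to monotone
transformations of that statistic (|r|, t, chi-square or p all give the
same score); the suite asserts this. The add-one estimator keeps every
score strictly positive, which the RS log-statistic requires.

**Conditioning.** Regressing the 0/1 status on all of one gene's
mean-imputed SNP dosages (raw dosages, not the gene's PCs; intercept
included; rank deficiency resolved by the least-norm solution) and keeping
the residuals removes that gene's linear contribution from every
downstream score. The residual vector is a first-class phenotype: scoring
and enrichment accept it unchanged, and the FDR layer permutes residuals
exactly as it would permute case-control labels.

**Pathway-level PCA** applies the same seven-step recipe to the pooled SNP
set of a pathway's genes (shared SNPs entering once).

## Pathway enrichment

**Random Set (RS).** Statistic T = −Σ ln pᵢ over the pathway's scored
genes (natural log; the permutation p-value is base-invariant). The null
draws random same-size gene sets without replacement from all scored
genes. When the subset space is small — C(N, m) up to `exhaustive_limit`
(default 5,000) — the null is enumerated exactly and the p-value is the
tail fraction over all subsets; otherwise `n_perm_genes` Monte-Carlo draws
are used with the add-one estimator. Draw indices depend only on
(universe, pathway size, seed), so equal-size pathways reuse draws, the
result does not depend on the order pathways are tested, and the FDR layer
can re-apply the same draws to permuted score vectors.

Genes sitting in several pathways contribute to each independently; no
overlap correction is applied. Pathway genes absent from the scored
universe are dropped from the pathway size m rather than counted as
non-significant; a pathway with no scored genes is flagged untested.

**BIN.** x = #(pathway genes with score < 0.05); the p-value is the exact
upper binomial tail P(X ≥ x) with success probability π₀ = the significant
fraction of the whole scored universe (x = 0 gives p = 1). This
approximates the Fisher/hypergeometric tail well in the geometry the
method is meant for — a universe of thousands of genes, pathways up to
~80 genes, tail probabilities down to ~10⁻³ — and is verified there to be
within a factor of 1.1 of the exact tail. In deeper tails or for pathways
that are a large fraction of the universe the relative error grows; this
is one reason pathway significance is decided by permutation (RS) or by
the FDR layer rather than by the raw tail value.

**Two-step FDR.** Step one permutes the phenotype `n_perm_pheno` times and
recomputes all gene scores per permutation; step two recomputes all
pathway p-values for each permuted score set. For observed pathway i,

    ev_null(i) = mean_b #{ j : p_b(j) < p_obs(i) }          (strict <)
    fdr(i)     = min(1, ev_null(i) / #{ j : p_obs(j) ≤ p_obs(i) })

followed by a cumulative-minimum pass from least to most significant so
the estimate is monotone in p_obs. The expected-exceedance numerator is
the natural reading of "average number of pathways beating the observed
p-value"; the denominator (observed discovery count) and the monotonicity
pass are the standard empirical-FDR completion — the construction is
otherwise underdetermined, so **both** `ev_null` and `fdr` are emitted and
the reporting threshold (FDR < 0.01) applies to `fdr`. Defaults are 1,000
phenotype × 10,000 gene-set permutations; the test suite runs scaled-down
at 50 × 500 (and 50 × 50 for the hero study) with fixed seeds.

Under phenotype permutation the genotype side of every gene score is
fixed, so the implementation precomputes per gene either the orthonormal
basis of its retained components (PCA) or its unit-norm dosage columns and
the inner permutation null of max |r| (best SNP); each permutation then
costs a few matrix products. For the best-SNP score the inner
standardisation null is likewise reused across outer permutations, which
is exact because the permutation distribution of max |r| does not depend
on which permutation of the phenotype is being scored.

## Synthetic data generator

The generator emulates the structure the analysis exploits, not human
genetics in detail:

* **LD**: per gene, two independent haplotypes per subject are drawn from
  a latent Gaussian AR(1) process (parameter `ld_rho`, default 0.7)
  thresholded at each SNP's MAF quantile; the dosage is the haplotype sum.
  This gives direct control of the within-gene correlation the PCA step
  consumes. Hardy–Weinberg holds by construction, so default fixtures pass
  the HWE filter; HWE-violating fixtures are built explicitly in tests.
  Genes are independent blocks on one synthetic chromosome with
  non-overlapping ±10 kb windows (plus optional overlapping pairs for
  mapper tests). Missingness is completely at random (default 1%).
* **Phenotype**: P(case) = logistic(β₀ + Σ log(OR)·dosage) over the
  designated causal SNPs; β₀ is tuned by bisection to a target prevalence
  (default 0.10, an enriched sampling frame rather than true population
  prevalence — retrospective sampling makes the analysis insensitive to
  this choice) and cases/controls are sampled to exact quotas from a
  larger simulated pool.
* **Pathways**: sizes are log-normal with median 28; the dispersion is set
  from the median/mean pair (28, 47) of a realistic curated annotation,
  σ = √(2 ln(47/28)) ≈ 1.02. One designated pathway collects all
  distributed-signal causal genes, one collects the hero gene; the
  remaining pathways draw only signal-free genes, so truth labels
  partition pathways into {distributed, hero, null}.

What passing tests on this generator do **not** show: behaviour under
population stratification, realistic human LD maps (long-range LD,
varying block sizes), genotyping error beyond random missingness, or
gene-gene correlation across loci. Between-gene independence in
particular makes the RS null draws slightly conservative relative to real
data, where neighbouring genes share LD.

## Problem sizes used by the suite and the acceptance script

* Null calibration: 40 replicates (test) / 10 replicates (script) of a
  no-signal study — 200 genes, 30 pathways, 500 cases / 500 controls,
  50 phenotype × 500 gene-set permutations.
* Power ordering: 50 / 12 replicates of a distributed signal — 10 causal
  genes at OR 1.3, 1,000/1,000 subjects, same permutation counts. At this
  effect size individual gene scores hover around 0.05, the regime in
  which score-weighted enrichment (RS) should beat threshold counting
  (BIN).
* Hero conditioning: 9 / 3 replicates — 2,500 genes with 2–4 SNPs each,
  hero OR 2.5, distributed OR 1.5 × 10 genes, 1,000/1,000 subjects,
  50 × 50 permutations. The large gene universe keeps the
  pathway-to-universe ratio (≈ 28/2,500) in the range of a real curated
  annotation (≈ 28/5,464); with a small universe a random gene set
  contains the hero gene too often for a single dominant gene ever to
  make its pathway significant under a random-set null. The reduced
  gene-set permutation count matches the granularity at which a
  single-pathway discovery is decidable with 30 pathways.

## Numerical choices and degenerate inputs

* Permutation p-values use the add-one estimator; exhaustive RS mode uses
  the exact tail fraction (the observed subset counts itself, so p > 0).
* Eigenvalue ties at the variance threshold retain the crossing component;
  numerically null eigenvalues (< 1e-10) are never retained.
* F-test designs are rank-checked via QR with a relative 1e-10 pivot
  threshold; a design collinear with the intercept raises an error naming
  the gene.
* Conditioning raises when residual variance falls below 1e-12 ("phenotype
  fully explained by conditioning gene").
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng` with fixed stream tags per stage; results are
  independent of the `threads` setting because permutation work is
  precomputed and each permutation's task is pure.

## Known limitations

* OLS-on-binary is an approximation; effect-size estimates are not
  interpretable as odds ratios (only p-values are consumed downstream).
* The FDR estimator is an empirical plug-in, not a proven-conservative
  procedure; with few pathways its granularity is limited by the
  permutation counts.
* BIN's tail approximation degrades for pathways that are a sizable
  fraction of the scored universe.
* No covariates, no population-structure correction, no sex-chromosome
  handling, no LD pruning, no imputation to a reference panel.
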