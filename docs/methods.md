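# Methods

`hapreml` estimates the trait variance attributable to haplotype-block-sized
genomic regions (regional heritability mapping) and tests each region with
three nested mixed models. This note records the models, the numerical
choices, and what the synthetic-data generator does and does not emulate.

## Models

### Regional relationship matrices

For a set of N SNPs, the SNP-based relationship between individuals i and j
uses the VanRaden scaling applied marker by marker:

    A_ij = (1/N) Σ_k (s_ik − 2p_k)(s_jk − 2p_k) / (2p_k(1 − p_k))

where s_ik ∈ {0,1,2} counts reference-allele copies and p_k is the
reference-allele frequency in the analyzed sample. A is invariant under
swapping reference and alternate labels at any SNP (each standardized column
only changes sign), so the choice of orientation is immaterial; the test
suite asserts this.

For a haplotype block, the distinct phased SNP-allele strings observed in
the sample define h haplotype alleles with frequencies p_k and per-individual
diplotype codes d_ik ∈ {0,1,2} (copies carried). The haplotype-based matrix
applies the same scaling to the codes:

    H_ij = (1/h) Σ_k (d_ik − 2p_k)(d_jk − 2p_k) / (2p_k(1 − p_k))

Only observed alleles are enumerated, so every p_k is positive, and no
frequency floor is applied: rare haplotype alleles are the point of the
haplotype model (they tag rare causal variants that typed SNPs miss). A
block whose sample carries a single allele (h = 1) has no defined H and is
skipped. For a single-SNP region A and H coincide exactly — which is why
single-SNP blocks are excluded from scanning: the SNP and haplotype models
become indistinguishable and the joint model would fit two identical
matrices.

### Pre-correction

Genome-wide signal, fixed effects and non-genetic random effects are removed
before scanning by fitting, for each chromosome c, the model

    y = Xβ + Σ_r Z_r u_r + W g_LOCO + ε,  g_LOCO ~ MVN(0, M_c σ²_gLOCO)

where M_c is the leave-one-chromosome-out (LOCO) GRM built from all SNPs not
on c. The pre-corrected phenotype is the residual ε̂; for repeated-measures
traits it is the permanent-environment BLUP plus the mean of the
individual's record residuals. A block on chromosome c is always tested
against the variant that excluded c, so its SNPs are never modeled twice.

### Regional testing

Per block, four models are fitted to the pre-corrected phenotype (an
intercept is always included; pre-corrected values are near-centered but
collapsing repeated records can shift the mean, and the intercept is
harmless when the mean is zero):

    null   y_pre = e
    SNP    y_pre = g_snp + e,          g_snp ~ MVN(0, A σ²_rSNP)
    Hap    y_pre = g_hap + e,          g_hap ~ MVN(0, H σ²_rHap)
    SNHap  y_pre = g_snp + g_hap + e

Five likelihood-ratio statistics are formed (SNP, Hap, SNHap each vs null;
SNHap vs SNP; SNHap vs Hap). Because variances are constrained non-negative,
the null distribution of each statistic is a boundary mixture: 0.5·χ²₁ for
the four one-parameter comparisons and 0.25·χ²₂ + 0.5·χ²₁ for SNHap vs null
(the remaining mass sits at zero). Significance is Bonferroni-controlled at
α divided by the number of blocks scanned for the trait, one family per
scan.

**Finite-rank conservativeness.** The mixture weights are asymptotic. For a
regional GRM of fixed small rank r (a block of ~8 SNPs), the probability
that the REML estimate sits exactly at zero is P(score at the boundary ≤ 0)
≈ P(a weighted χ²_r falls below its mean), which exceeds 1/2 for small r at
any sample size. Measured at n = 500 over 1,000 null replicates, the
empirical sizes at nominal 0.05 are ≈ 0.030 (SNP vs null), 0.036 (Hap vs
null) and 0.021 (SNHap vs null). The two nested comparisons are further
conservative under a complete null because the nested model itself sits on
a boundary — outside the regularity conditions of the mixture result —
giving sizes ≈ 0.000–0.004. All five tests are conservative, never
anti-conservative, so Bonferroni control of false positives holds; power
comparisons between methods remain meaningful because both tests are biased
in the same direction.

### Variance-explained accounting

Significant blocks on one chromosome closer than 1 Mb (configurable) are
merged into loci, and only the block with the largest regional variance per
locus contributes; the per-method sum is reported as a percentage of the
total genetic variance. The denominator is estimated once per trait from a
whole-genome GRM model on the uncorrected phenotype — the only denominator
computable from the pipeline's own inputs. For the joint model the regional
variance is σ̂²_rSNP + σ̂²_rHap.

## REML

All models are fitted by exact REML with the convention

    ℓ_R = −½ [ log|V| + log|XᵀV⁻¹X| + yᵀPy + (n−p) log 2π ].

Three paths share this definition and agree to optimizer tolerance (asserted
in tests):

* **general dense** — average-information updates with step-halving, an EM
  fallback when the AI solve fails, and projection of negative proposals
  onto the boundary at zero; convergence at |Δℓ| < 1e−6 and relative
  parameter change < 1e−6, cap 200 iterations; aliased fixed-effect columns
  are dropped by pivoted QR and near-singular AI matrices are reported as
  likely component aliasing;
* **single-component eigendecomposition** — profile likelihood in the
  variance ratio on a bounded interval, with the zero boundary checked
  explicitly;
* **low-rank Woodbury** — when every component carries an n×r factor with
  r ≪ n (regional GRMs always do: r = #SNPs or #alleles), the profiled
  likelihood is evaluated in O(r³) per point after one O(nr²) precomputation
  and maximized by bounded quasi-Newton. This is what makes thousand-
  replicate calibration studies run in about a minute.

Boundary projection (estimates returned as exact zeros) is required for the
mixture null distributions above to be the correct reference.

**Boundary corners.** The SNP and haplotype matrices of one block are
strongly correlated, so the restricted likelihood of the joint model can
have two local boundary optima (σ²_rSNP = 0 vs σ²_rHap = 0) with different
heights. Single-start optimizers were observed to land in the worse corner
(a loglik gap of ~0.09 on a small fixture, enough to corrupt an LRT). The
dense path therefore restarts once per zero-pinned component from an
interior point, and the low-rank path uses multi-start quasi-Newton (one
start per corner); the scan additionally refits with the general path if a
comparison still produces a negative LRT beyond tolerance (−1e−4; smaller
violations are clamped to zero).

## Synthetic data

The generator emulates the structure the analysis assumes, with known truth:

* **Genotypes.** Each block's haplotypes are drawn from a pool of F founder
  strings with Dirichlet-distributed frequencies; individuals draw two
  founders per block independently. This creates strong within-block LD, a
  realistic haplotype-allele spectrum, and linkage equilibrium across blocks
  (blocks are spaced 700 kb apart, beyond the 500 kb gap rule). Default
  desk-scale dimensions: 500–2,000 individuals, 2 chromosomes, 8 SNPs and 6
  founders per block — the founder count bracketing the source study's mean
  of ~8 SNPs per block.
* **Phenotypes.** y = μ + fixed effects + polygenic value + regional value
  + iid random effects (+ permanent environment for repeated designs) +
  residual, with total variance 1. Every component is rescaled to its exact
  target share of the realized sample variance, so recovery tests have exact
  expectations. The polygenic value is drawn through a matrix square root of
  the GRM of non-causal chromosomes (exact share control at desk scale;
  avoids overlap with the regional component).
* **Architectures.** `snp_additive` places iid effects on standardized
  dosages of causal SNPs inside one block — the architecture under which the
  SNP-based regional model is exact. `hap_allele` attaches one effect to a
  single founder haplotype whose SNP alleles are each shared with at least
  one other founder, so no typed SNP privately tags it; with more founder
  alleles than SNP degrees of freedom (16 founders over 6 SNPs in the
  shipped scenario) the founder indicator lies outside the span of SNP
  dosages, which is precisely what gives the haplotype model its power
  advantage. With fewer founders than SNPs the SNP matrix spans the founder
  space and the advantage disappears — a useful negative control, not a bug.
* **Effect sizes** in the shipped power scenarios are fixed at a 2% regional
  share (n = 1,000): large enough for both methods to have non-trivial
  power, small enough that neither saturates, so the ordering between
  methods is observable.

What the generator does **not** emulate: coalescent LD decay across blocks,
pedigree/family structure, selection, genotyping or phasing error, and the
real study's scale (≈8,500 individuals × 419k imputed SNPs). A green test
therefore establishes correctness of the estimators and tests under the
assumed covariance structures, not robustness to misspecified LD or phase.

## Block estimation

Blocks follow the Gabriel strong-LD criterion computed from phased two-SNP
haplotype counts: the likelihood of |D′| is profiled on a 1,001-point grid
(allele frequencies at their MLEs, sign of D fixed at its estimate) and
integrated to a 90% interval; a pair is strong LD when the interval lower
bound ≥ 0.70 and upper ≥ 0.98, strong recombination when the upper < 0.90.
A candidate window is a block when its end pair is strong LD and ≥ 95% of
informative pairs are; candidates are accepted greedily by span. Hard rules
on top: gaps > 500 kb between consecutive SNPs always break blocks, SNPs
with MAF < 0.01 never enter, and single-SNP blocks are dropped. Bit-exact
parity with PLINK `--blocks` is not promised; block files computed elsewhere
can be loaded instead (BED dialect, 0-based half-open).

## Degenerate inputs

Monomorphic SNPs are rejected in GRM construction (named in the error);
blocks reduced below two polymorphic SNPs in the phenotyped subsample are
skipped with a flag and the scan continues; h = 1 blocks are skipped
likewise; individuals with phenotype but no genotype are dropped with a
logged count; a response with zero variance is an input error; REML
non-convergence is flagged on the result, never silent.
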