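# Methods

## The model

Phenotypes are pre-adjusted residuals (fixed non-genetic effects already
removed), one record per individual, so the mixed model is

    y = 1·mu + Σ_i u_i + e,      u_i ~ N(0, σ²_i S_i),   e ~ N(0, σ²_e I),

with f genetic effect types, each contributing an n×n genomic relationship
matrix (GRM) S_i. The phenotypic covariance is V = Σ_i σ²_i S_i + σ²_e I.
Heritability of effect i is h²_i = σ²_i / (Σ_j σ²_j + σ²_e); "total
heritability" is the sum over genetic components.

## Relationship matrices

* **Additive (A)** — VanRaden method 1: W = X − 2p (X the 0/1/2 dosage of
  the counted allele, p its sample frequency), S_A = WW′ / Σ_j 2p_j q_j.
* **Dominance (D)** — orthogonal coding h = −2p² / 2pq / −2q² for
  x = 0/1/2, S_D = HH′ / Σ_j (2p_j q_j)². Under HWE this coding is
  uncorrelated with the additive one, keeping the A/D variance partition
  interpretable.
* **Epistasis (AA, AD, DD, AAA, AAD, ADD, DDD)** — Hadamard products of
  the *unnormalized* cross-products K_A = WW′ and K_D = HH′ (e.g.
  AA = K_A∘K_A, AAD = K_A∘K_A∘K_D), each divided once by its mean
  diagonal so mean(diag) = 1. These are the standard approximate epistasis
  GRMs; elementwise, (K_A∘K_A)_{ii'} = Σ_{j,k} w_ij w_ik w_i'j w_i'k, i.e.
  exactly the cross-product of the n×m² ordered-SNP-pair covariate matrix —
  the identity the test suite verifies by brute force. The Schur product
  theorem guarantees the products stay PSD. Taking Hadamard products of
  unnormalized (rather than normalized) cross-products changes only the
  scalar a variance component multiplies, not the model fit; the single
  mean-diagonal normalization makes σ²_i comparable across effect types.
* **Intra/inter-chromosome A×A** — with per-chromosome cross-products K_c
  (K_A = Σ_c K_c), intra = Σ_c K_c∘K_c and inter = K_A∘K_A − intra, an
  exact identity before each part's own mean-diagonal normalization.
* **Haplotype (H)** — blocks of consecutive SNPs (fixed SNP count, fixed
  physical distance, or sliding windows with a one-SNP step; distance bins
  are half-open and anchored at 0 bp). Each block is one locus whose
  distinct observed haplotypes are alleles; per block the centered allele-
  dosage matrix W_b (dosage − 2·frequency) enters K_H = Σ_b W_b W_b′,
  normalized to mean diagonal 1. Monomorphic blocks carry no variance and
  are dropped (counted). A trailing one-SNP block under the SNP-count
  scheme is merged into its predecessor, avoiding one-SNP "haplotypes".

Allele frequencies always come from the full analyzed sample (training and
validation combined), matching the use of whole-sample GRMs across folds.

## GREML

The restricted log-likelihood −½[log|V| + log(1′V⁻¹1) + y′Py] is maximized
over non-negative components by EM-REML warm-up (three iterations of the
inversion-free ascent update σ²_i ← σ²_i + σ²_i²(y′PS_iPy − tr(PS_i))/n)
followed by average-information (AI) steps with step halving; an AI
proposal is accepted only if it does not decrease the likelihood, else the
iteration falls back to EM, so the recorded trace is monotone. No GRM is
ever inverted — every solve is against V, which the residual term keeps
positive definite — so rank-deficient GRMs (e.g. additive with n > m) are
handled without special casing. Convergence requires relative change
< 1e-6 in every free component and < 1e-8 in the likelihood. Components
driven below 1e-10 × var(y) are pinned to the zero boundary with up to
three re-entry chances, then frozen and flagged. The residual variance has
a floor of 1e-8 × var(y) to keep V positive definite. Starting values put
half the phenotypic variance in the residual and split the rest equally —
a symmetric start that favours no effect type. Near-proportional GRMs in
one model trigger a collinearity warning: only their sum is identifiable.
Dense factorizations of V make this a desk-scale implementation (n up to a
few thousand), a deliberate trade against the distributed solvers needed
for six-figure cohorts.

Standard errors of h² are not computed; cross-validation reports
across-fold SDs instead.

## GBLUP

With components estimated on training individuals t, V_t = Σ σ²_i S_i[t,t]
+ σ²_e I, the GLS mean is mu = (1′V_t⁻¹1)⁻¹1′V_t⁻¹y_t and each effect's
BLUP for any individuals p is the covariance projection
u_i[p] = σ²_i S_i[p,t] V_t⁻¹ (y_t − 1·mu); the total genetic value is the
sum. Validation phenotypes never enter the predictor. For a single
additive component this reduces exactly to ridge/SNP-BLUP with penalty
σ²_e/(σ²_A/Σ2pq) — a closed-form identity the tests verify against
Henderson's mixed-model equations.

## Cross-validation

Individuals are randomly permuted (seeded) into k = 10 groups: the first
nine of exactly ⌊n/k⌋, the last holding the remainder. GRMs are built once
on the full sample; per fold, variance components are re-estimated on the
training individuals by default (a documented flag reuses one whole-sample
fit for speed). Accuracy is the Pearson correlation between predicted
total genetic values and phenotypes, reported as mean ± sample SD (k−1
denominator) across folds; model comparisons report
100·(acc − baseline)/baseline percent, with the additive model as the
default baseline. A fold whose accuracy is undefined (constant vector) is
recorded as missing and excluded from summaries with a warning — not
imputed as zero, which would bias them. Rounding (3 decimals for
accuracies and heritabilities, 2 for percent increases) happens only at
presentation.

Effect screening retains, from a full-model fit, the effect types whose
heritability strictly exceeds 0.5%.

## Rank diagnostics

Numerical rank counts eigenvalues above n·ε·λ_max. Two exact consequences
of the constructions are worth stating because they refine the naive
"rank = min(n, m)" law:

* Centering at *sample* frequencies puts the ones vector in the null space
  of K_A (column sums of W are exactly zero), so the additive GRM has rank
  min(n−1, m): m when n > m, but n−1 when n ≤ m. The dominance covariate
  is quadratic in the dosage and not exactly centered, so S_D has rank
  min(n, m) in both regimes.
* The A×A GRM is the cross-product of the ordered-pair covariate matrix,
  whose distinct columns number m(m+1)/2; it reaches full rank n only once
  m(m+1)/2 ≥ n (not m² — the ordered pairs double-count).

Duplicated individuals (identical genotype rows) cost every GRM exactly
one rank each, which is why observed ranks on real cohorts sit slightly
below the law's prediction.

## Synthetic data

The generator emulates a genotyped dairy-cattle evaluation cohort at desk
scale. Genotypes: per chromosome, a pool of F founder haplotypes with
per-SNP allele frequencies uniform on [MAF floor, 1 − floor] and
first-order Markov dependence between adjacent SNPs (copy probability 0.5)
for LD; each individual's two haplotypes are founder mosaics with
Poisson(1) crossovers per chromosome at uniform positions. Founder
identity persists across chromosome boundaries, and founder usage is
skewed (geometric weights with ratio `founder_concentration` = 0.45 over
F = 10 founders): a few dominant ancestors contribute most of the genome.
This is the deliberate caricature of an intensively selected closed
population — enormous paternal half-sib families, effective size of order
tens — and it serves a statistical purpose: the off-diagonal dispersion of
the relationship matrices (SD ≈ 0.13 for S_A under the defaults) is what
makes a small A×A variance estimable at n = 2000. A cohort of unrelated
individuals would need the six-figure sample sizes of a national
evaluation for the same precision (the per-replicate SE of σ̂²_AA scales as
√2/(n·rms off-diagonal of S_AA)); scaling n down requires scaling kinship
up to preserve information. With uniform founder usage
(`founder_concentration` = 1) the generator produces the weakly structured
alternative. Columns violating the 5% sample-MAF floor have their founder
alleles redrawn (the mosaic is kept), so the delivered panel honours the
floor exactly while the spectrum above it stays broad.

Phenotypes are drawn from exactly the covariance model the estimator fits:
u_i ~ N(0, c_i S_i) per requested component (A, D, AA, AA_intra, AA_inter,
H), residual variance 1 − Σc_i, mean zero. Additive, dominance and
haplotype components are sampled exactly through their design matrices
(u = √(c/d)·Wz, no eigendecomposition); epistasis components use a
symmetric eigenfactorization with negative round-off eigenvalues clipped.
Because the S_i have mean diagonal ≈ 1, the fractions c_i are the target
heritabilities. This model-faithful generator makes parameter recovery a
clean check of the estimator; what passing does **not** show is robustness
to model misspecification (real epistasis acts through individual SNP
pairs, not literally through the Hadamard covariance), to genotyping or
imputation error, or to pedigree features the mosaic lacks (inbreeding
trends, selection, distinct maternal/paternal pools).

## Problem sizes and defaults

Defaults: n = 2000, 20 chromosomes × 200 SNPs (m = 4000) — both n < m and
n > m regimes are exercised by tests with other shapes; variance fractions
(h²_A, h²_AA) = (0.05, 0.06), the low-heritability fertility regime;
10-fold CV; 5% MAF floor (boundary inclusive — kept if MAF equals the
threshold); haplotype blocks of 7.5 Mb fixed distance unless configured
otherwise. The analysis drivers under `analysis/` run a lighter cohort
(n = 1000, m = 1000) so the full narrative executes in minutes; the
parameter-recovery experiments use the full default profile. The GRM
binary writer uses the GCTA lower-triangle layout with float64 elements
(exact round trips); true float32 GCTA files are auto-detected on read.

## Known limitations

Dense O(n³) REML and GBLUP limit cohorts to a few thousand; the LD profile
is qualitative; the MAF spectrum above the floor is shaped by founder
frequencies and usage skew rather than fitted to a site-frequency
spectrum; no missing genotypes (the upstream evaluation pipeline is
assumed to have imputed them); haplotype dominance and exact (non-Hadamard)
epistasis GRMs are out of scope.
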