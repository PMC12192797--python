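# epiblup

Multifactorial genomic prediction and heritability estimation with SNP,
epistasis and haplotype effects — the modelling stack used to dissect
lowly heritable dairy-fertility traits (e.g. daughter pregnancy rate),
where additive markers explain little and additive×additive epistasis
turns out to carry most of the predictable signal.

The package is aimed at quantitative geneticists who want to run the full
pipeline at desk scale on real or simulated data: build genomic
relationship matrices (GRMs) for many effect types, estimate their
variance components jointly, predict total genetic values, and compare
prediction models by cross-validation.

## The model

One record per (pre-adjusted) individual:

    y = 1·µ + Σᵢ uᵢ + e,    uᵢ ~ N(0, σᵢ² Sᵢ),    e ~ N(0, σₑ² I)

where each effect type i contributes an n×n relationship matrix Sᵢ:

| effect | construction |
|---|---|
| A | VanRaden centered dosages, WW′/Σ2pq |
| D | orthogonal dominance coding, HH′/Σ(2pq)² |
| AA, AD, DD, AAA, AAD, ADD, DDD | Hadamard products of unnormalized WW′ and HH′, mean diagonal scaled to 1 |
| AA_intra / AA_inter | per-chromosome partition of the AA Hadamard product (exact identity) |
| H | multi-allelic haplotype blocks: centered allele dosages per block, summed |

Variance components are estimated by GREML (EM warm-up + average-
information updates, no GRM inversions, so singular GRMs are fine);
genetic values by GBLUP (covariance projection onto held-out
individuals); models are compared by k-fold cross-validated Pearson
accuracy between predicted total genetic values and phenotypes. A
founder-mosaic simulator generates phased genotypes with LD and
strong family structure plus phenotypes with known variance fractions.
Details and design choices: [docs/methods.md](docs/methods.md).

## Worked example

```python
import epiblup as eb

cfg = eb.SimConfig(seed=20260926, n=1000, n_chrom=10, snps_per_chrom=100)
g = eb.simulate_genotypes(cfg)            # phased panel, 5% MAF floor
pheno, truth = eb.simulate_phenotypes(g, cfg)   # h2_A=0.05, h2_AA=0.06

A  = eb.additive_grm(g)
AA = eb.epistasis_grms(g, ("AA",))["AA"]

fit = eb.fit_greml(eb.ModelSpec(grms=[A, AA], y=pheno.y))
print(eb.heritability_table(fit).round(3))

folds = eb.make_folds(g.individual_ids, k=10, seed=20260926)
rA  = eb.run_cv([A],     pheno.y, folds, model="A")
rAA = eb.run_cv([A, AA], pheno.y, folds, model="A+AA")
print(eb.model_report({"A": rA, "A+AA": rAA}, baseline="A").round(3))
```

which prints

```
     effect  sigma2     h2
0         A   0.035  0.037
1        AA   0.036  0.038
2  residual   0.883    NaN
3     total   0.955  0.075

       train_acc_mean  train_acc_sd  val_acc_mean  val_acc_sd  train_increase_pct  val_increase_pct  total_h2_mean
A               0.293         0.019         0.125       0.108               0.000             0.000          0.038
A+AA            0.496         0.041         0.139       0.104              69.415            10.883          0.073
```

Reading: the two-component GREML fit splits the (simulated) genetic
variance between additive and A×A structures; in 10-fold validation the
epistasis model predicts held-out phenotypes better than the additive
baseline (0.139 vs 0.125, +10.9%), and its training-population accuracy is
far higher (+69%) because the A×A relationship matrix lets the model fit
genuine epistatic variance rather than noise.

The numbered scripts under `analysis/` run the full narrative end to end
(simulate → GRMs + ranks → full-model GREML + screening → 10-fold CV) on
a 1500-cow cohort and write their tables under `results/`:

```bash
python analysis/01_simulate_data.py
python analysis/02_build_grms.py
python analysis/03_estimate_heritability.py
python analysis/04_cross_validate.py
```

That run prints, among others:

* `grm_ranks.tsv` — additive/dominance GRM ranks 995/996 against
  n = 1500, m = 1000 (the n–m confounding law: SNP GRMs cannot exceed
  rank min(n, m), and a handful of perfectly correlated SNPs plus
  frequency centering shave a few more), while every epistasis GRM is
  full rank 1500.
* `heritability_full_model.tsv` — the nine-effect GREML fit pins all
  seven non-AA epistasis types and dominance at the zero boundary
  (h² = 0.000) and keeps A at 0.061 and AA at 0.018, so the 0.5% screen
  returns the A + AA model.
* `cv_model_comparison.tsv` — training accuracy rises from 0.315 (A) to
  0.381 (A+AA, +21%) wherever A×A variance is real, while the validation
  gain at n = 1500 (0.203 vs 0.201, SD ≈ 0.08 across folds) is inside
  fold noise — a desk-scale echo of the finding that resolving a
  few-percent accuracy gain takes very large cohorts. The test suite's
  seeded ten-cohort replication at n = 2000 shows A+AA beating A in
  10 of 10 cohorts.

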