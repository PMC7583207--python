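# famclock

Familial correlation and variance-components modelling of epigenetic age
(DNAm age) across the lifespan.

## The problem

DNA-methylation age is a biological-age estimate computed from methylation
levels at clock CpG sites. Its informative component — *epigenetic age
acceleration*, the residual of DNAm age regressed on chronological age — runs
in families, and the classic twin-study question is whether that familial
resemblance is genetic (additive effects shared in proportion to kinship) or
environmental (effects shared while relatives live together). Studies
restricted to a single age band cannot separate the two; pooling relative
pairs whose ages span birth to old age can, because genetic and
cohabitation-environmental hypotheses predict different *age trajectories* of
the familial correlation for MZ twin, DZ twin, sibling, parent–offspring and
spouse pairs.

`famclock` implements that analysis for family-structured phenotype tables:

* **Cohabitation clock.** Every pair gets a shared-life position `(t, t0)`:
  years of shared life accrued so far and the point where cohabitation ended
  (twins and parent–offspring switch at age 18 of the child; siblings when
  the older sibling turns 18; spouses marry at a mean age of 24 and separate
  only if a separation time is recorded).
* **Lifespan correlation model.** For relatives *i, j*,

      rho_ij = theta − exp(−lambda·t)                          t ≤ t0
      rho_ij = (theta − exp(−lambda·t0))·exp(−nu·(t − t0))     t > t0

  with 0 ≤ theta ≤ 2 and lambda, nu ≥ 0: the correlation is theta − 1 when
  cohabitation starts, builds at rate lambda while living together, and
  decays at rate nu after separation. theta and lambda may differ by pair
  group ({MZ}, {DZ + sibling}, {parent–offspring}, {spouse}).
* **Variance-components models.** The pair covariance

      COV_ij = alpha·sigma_A² + beta_A·(1 − exp(−lambda_A·t))
                              + beta_C·(1 − exp(−lambda_C·t))   (cohabiting;
                              after separation each kernel decays at nu_A, nu_C)

  decomposes variance into additive-genetic (A), cohabitation-shared
  environmental (C) and individual (E) parts. Five constrained variants are
  fitted by maximum likelihood and compared by AIC: constant-A `AE`,
  cohabitation-dependent `COHAB_AE` and `COHAB_ACE`, the `COHAB_CE` model in
  which the shared-environment multiplier beta_C is freed for MZ and
  parent–offspring pairs (a direct test of the equal-environment
  assumption), and `COHAB_CE_PLUS_A` which adds a constant genetic term.
* **Likelihood machinery.** Zero-mean multivariate-normal family likelihood
  with study-specific residual variances, batched over family blocks;
  constrained ML via smooth transforms with multi-start L-BFGS-B; Wald
  standard errors from the observed information; AIC and likelihood-ratio
  tests.
* **Synthetic cohorts.** A generator that inverts the models: it assembles
  each family's covariance from a chosen kernel, samples phenotypes jointly,
  and emits the exact table formats the pipeline reads — including a
  ready-made multi-study cohort of ~4,200 people aged 0–92 mirroring a
  realistic pooled twin/family design.

## Worked example

```python
from famclock import (FamilyDataset, VarianceModelSpec, Variant,
                      fit_variance_model, generate_cohort,
                      multi_study_cohort, compare_variants)

cfg = multi_study_cohort(scale=0.5, seed=11)        # CE generating model
pheno, pairs, truth = generate_cohort(cfg)
ds = FamilyDataset.from_frames(pheno, pairs, value_col="phenotype")
fits = [fit_variance_model(VarianceModelSpec(v), ds, seed=11, n_starts=2,
                           compute_se=(v == Variant.COHAB_CE))
        for v in Variant]
print(compare_variants(fits)[["variant", "n_params", "aic", "delta_aic"]])
```

prints (2,124 individuals in 990 families, 1,395 modelled pairs):

```
        variant  n_params         aic  delta_aic
       COHAB_CE        19 5644.453209   0.000000
COHAB_CE_PLUS_A        20 5646.316091   1.862882
      COHAB_ACE        19 5672.557745  28.104536
       COHAB_AE        17 5713.161899  68.708691
             AE        16 5716.938791  72.485583
MZ:(DZ,SIB) shared-environment ratio = 1.47 (95% CI 1.23 to 1.74)
(DZ,SIB):PO shared-environment ratio = 3.86
```

The cohort was generated under the cohabitation-dependent CE kernel with an
MZ multiplier of 1.41, and the CE variant indeed wins the AIC comparison; the
fitted MZ:(DZ,SIB) ratio 1.47 (CI 1.23–1.74) brackets the generating 1.41.
The (DZ,SIB):PO ratio is poorly determined at this scale (parent–offspring
pairs occur only inside the adolescent family blocks), which is why its
confidence interval is reported alongside it in the full output.

The same ladder is available from the shell:

```bash
famclock simulate --scale 0.5 --seed 11 --out sim/
famclock compare --phenotypes sim/phenotypes.csv --pairs sim/pairs.csv \
         --seed 11 --out comparison.tsv
```

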