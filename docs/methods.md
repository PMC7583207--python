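# Methods

## Phenotype construction

The analysis phenotype is *epigenetic age acceleration*: the residual of DNAm
age on chronological age from an ordinary least-squares fit with intercept and
slope, computed separately within each regression stratum (by default the
study; longitudinal waves or generations can be named as extra stratum
columns). Residuals therefore have exactly zero mean and zero age-correlation
within strata. Strata with fewer than three members or with a single age
value fall back to intercept-only centering with a warning.

When one person contributes measurements from several biological samples, the
per-tissue values are first standardized to zero mean and unit variance
(sample, n−1 convention) and averaged within person before residualization.
The residuals are then adjusted for sex — and optionally for seven estimated
blood-cell proportions (naive CD8+ T, exhausted CD8+ T, plasmablasts, CD4+ T,
NK, monocytes, granulocytes) — by a second per-stratum OLS. The seven
fractions sum to ~1 and are collinear with the intercept, so the last one is
dropped automatically. Whether sex adjustment is pooled or per-stratum is a
config switch; per-stratum is the default because the downstream likelihood
estimates study-specific variances.

## Family likelihood

Families are zero-mean multivariate normal: the diagonal of each family's
covariance matrix holds study-specific residual variances sigma²_s (estimated
jointly by ML; the phenotype is residualized first, so no mean parameters are
fitted by default), and the off-diagonals come from a pairwise kernel.
Pairwise-specified covariances do not guarantee positive definiteness for
families of three or more, so a parameter point yielding a non-PD family
matrix scores −inf and is simply rejected by the optimizer; at every reported
optimum the likelihood is finite, i.e. every family matrix passed a Cholesky
factorization. Families are evaluated in batches grouped by size (closed
forms for singletons and pairs, batched Cholesky above that), which keeps a
full pooled-cohort likelihood evaluation near a millisecond.

## Correlation and covariance kernels

The correlation of a pair with cohabitation clock (t, t0) is
theta − e^(−lambda·t) while cohabiting and (theta − e^(−lambda·t0))·
e^(−nu·(t−t0)) afterwards, with 0 ≤ theta ≤ 2, lambda, nu ≥ 0. Both branches
agree at t = t0, so the kernel is continuous there for every parameter
setting; spouses with unknown separation time have t0 = +inf and never enter
the decay regime. The covariance kernel adds a constant genetic term
alpha·sigma_A² (alpha = doubled kinship: 1 for MZ, 0.5 for DZ/sibling/
parent–offspring, 0 for spouses) and separate genetic and shared-environment
build-up/decay kernels with multipliers beta_A (fixed to the doubled kinship
where used) and beta_C. Model variants and their constraints:

| variant            | free parameters (besides study variances)        |
|--------------------|--------------------------------------------------|
| `AE`               | sigma_A²                                         |
| `COHAB_AE`         | lambda_A, nu_A (shared over non-spouse pairs)    |
| `COHAB_ACE`        | lambda_A, nu_A, lambda_C, nu_C (beta_C = 1 all)  |
| `COHAB_CE`         | beta_C(MZ), beta_C(PO), lambda_C, nu_C           |
| `COHAB_CE_PLUS_A`  | the CE set plus sigma_A²                         |

Under `COHAB_CE`, beta_C = 1 for DZ, sibling and spouse pairs; the freed MZ
and parent–offspring multipliers quantify departures from the
equal-environment assumption (their headline summaries are the MZ:(DZ,SIB)
ratio beta_C(MZ) and the (DZ,SIB):PO ratio 1/beta_C(PO)). Spouses carry no
genetic kernel in any variant (doubled kinship 0, rates zeroed). Because
beta_C is pinned to 1 for DZ/sibling/spouse pairs, the covariance scale is
meaningful only if phenotypes are close to standardized; the synthetic
cohorts therefore use study variances near 1.

Pair groups default to {MZ}, {DZ, SIB}, {PO}, {SPOUSE} with nu shared across
groups, and every merge/share is an argument, so the whole model ladder
(theta free → theta = 1 → shared lambda; the five covariance variants) can be
run as nested likelihood-ratio tests. Whether spouses share nu with
biological relatives is not determined by the data we emulate; the default
shares it, with an override.

## Estimation and inference

Maximization runs on an unconstrained scale (log for rates, variances and
multipliers; scaled logistic for interval parameters such as theta on [0, 2]
and correlations on (−0.99, 0.99)) with L-BFGS-B from five jittered starts by
default. If the default starting point is infeasible (a small study's
empirical variance below the initial kernel covariance), kernel start values
are shrunk deterministically until the start is feasible. Standard errors
come from the numerically differentiated observed information on the
transformed scale, mapped back by the delta method; confidence intervals are
Wald on the transformed scale mapped back, so they respect the bounds — for a
correlation this is exactly the Fisher-z interval (the logistic(−1, 1)
transform is 2·atanh). AIC is −2·loglik + 2·(free parameters); nested models
are compared by likelihood-ratio tests with chi-square reference
distributions and two-sided alpha = 0.05. The sigma_A² = 0 test in
`COHAB_CE_PLUS_A` vs `COHAB_CE` sits on the parameter boundary; the naive
chi-square(1) reference is used deliberately (it is conservative) and noted
in the comparison output. Reported within-study correlations are clamped to
(−0.99, 0.99) at the optimizer bound and flagged when they hit it; no clamp
is ever applied inside a likelihood.

## Synthetic cohorts

The generator inverts the analysis models. Each block of a cohort
configuration creates members and within-family pair edges (independent
pairs; two-parent twin households with optional extra siblings; sibships);
the generating kernel supplies every edge covariance; each family's matrix is
Cholesky-factorized (a non-PD configuration aborts with a message naming the
offending parameters) and phenotypes are drawn jointly. DNAm age is emitted
as intercept + slope·age + sex effect + residual (slope 1, intercept 0 and
zero sex effect by default, so acceleration reproduces the residual exactly;
non-unit slopes exercise the residualization stage). Same seed, same bytes.

`multi_study_cohort(scale)` mirrors a realistic pooled multi-study design: at
scale 1 it holds 4,217 individuals in 15 study blocks — newborn and
18-month-old twins, an adolescent twin/family study with 59 five-member
households (both parents, a twin pair, one extra sibling) plus extra twin and
sibling pairs, a large 18-year-old twin cohort, adult and elderly twin
cohorts up to age 92, 54 four-sister sibships, and spouse pairs — with study
residual variances spread over 0.8–1.3. The household and sibship structures
approximate the real studies' overlapping pair counts rather than reproducing
them exactly. What the generator deliberately does not emulate: longitudinal
within-person trajectories, CpG-level data, assortative mating, age-varying
residual variance within a study, and missingness. Passing tests therefore
demonstrate correctness of the estimation machinery under the model's own
assumptions, not robustness to real-data violations of them.

## Experiment sizes and numerical choices

Recovery experiments use pooled independent-pair cohorts with ages uniform on
0–90 (spouse mean ages uniform on 24–90) and unit study variance: 2,000 pairs
per relationship group for the correlation-rate recovery, 6,000 per type for
the CE and CE-plus-A recoveries (the (DZ,SIB):PO ratio and the constant
genetic share are the most weakly identified quantities), and 2,000 per type
for AE heritability. The acceptance script averages a handful of independent
replicates of each experiment at those same sizes; the estimators are
unbiased, so averaging only reduces Monte-Carlo noise. Rate estimates carry a
small positive finite-sample bias (a few percent at 2,000 pairs per group)
that shrinks with cohort size, as the bias-shrinkage test documents.
Calibration checks use 500 null replicates for the likelihood-ratio test's
type-I error and 200 replicates of a scale-2 multi-study cohort (fits started
at the generating values, single start) for Wald-interval coverage of the
build-up rate and MZ multiplier. Model-selection checks use 50 scale-0.5
cohorts generated under the CE kernel.

Optimizer tolerances: ftol 1e−11, projected-gradient tolerance 1e−7, at most
500 iterations; convergence is the optimizer's success flag, with gradient
norms and per-start logs kept in the fit diagnostics. Hessian steps are 1e−4
relative central differences. Overflowing log-scale proposals are clamped at
exp(700) and rejected by the likelihood rather than raising.

## Known limitations

* The equal-age assumption for twin pairs is taken from the data design
  (twins measured at the same wave); discordant twin ages are not modelled.
* Wald intervals for ratio summaries (e.g. (DZ,SIB):PO) are computed on the
  log of the underlying multiplier; strongly skewed likelihoods (few
  parent–offspring pairs) can make them optimistic.
* Boundary hypotheses (variance components at zero) use naive chi-square
  references, matching common practice but conservative.
* Half-siblings, avuncular and grandparental pairs, inbreeding and dominance
  components are out of scope.
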