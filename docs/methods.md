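# Methods

## The liability threshold model

Every individual carries a latent liability
`Y = Σ_k β_k g_k (+ interaction) + 0.015·age + 0.45·sex + γ + ε`,
and is a case when `Y` exceeds a threshold chosen so that a fraction
`K = 0.3` of the simulated population is affected. Individual liability
components:

| term | meaning | default | nominal variance share |
|---|---|---|---|
| `β_k g_k` | eight causal variants, MAF 0.01–0.50 | `β_k = sqrt(pve / 2·MAF·(1−MAF))` | 1% each (causal model), 0.5% each (interaction model) |
| `0.02·age·Σβ_k g_k` | age-by-genotype interaction (interaction model only) | coefficient 0.02 | ≈ 4% (see below) |
| `0.015·age` | age in years, uncentered | 0.015 | ≈ 10% |
| `0.45·sex` | sex coded female = 1, male = 0 | 0.45 | ≈ 5% |
| `γ` | polygenic effect, `Cov = 2Φ·σ_G²` within a family | `σ_G² = 0.2` | 20% |
| `ε` | iid Gaussian residual | `σ_E²` = 0.65 / 0.57 / 0.57 by model | remainder |

Heritability on the liability scale is `h² = 0.28` (8% causal variants + 20%
polygenic). The polygenic covariance uses the numerator relationship matrix
`2Φ` (diagonal 1), not the kinship matrix `Φ` itself: with `Φ` (diagonal 0.5)
the individual polygenic variance would be 0.1 and total heritability 0.18,
inconsistent with `h² = 0.28`. Sampling is by the exact recursive
construction for non-inbred pedigrees (founders `N(0, σ_G²)`, non-founders =
parental mean + `N(0, σ_G²/2)` segregation deviate), which is the stated
multivariate normal without any per-family Cholesky factorizations.

**Interaction-model residual.** The nominal budget 4% (genotype) + 4%
(interaction) + 10% + 5% + 20% leaves `σ_E² = 0.57`, the same residual as the
causal model, and that value is used. The budget treats the terms as
orthogonal; because age and the genotype sum are uncentered, the realized
interaction share is ≈ 5.7% of a total variance ≈ 1.19 (see
`realized_variance_shares`). The empirical dichotomization threshold absorbs
the overall scale. An alternative — calibrating `σ_E²` so `Var(Y) = 1`
exactly — was rejected: it shrinks the residual to ≈ 0.37 and inflates every
genotype-linked share well beyond the stated 4%.

**Dichotomization** uses the empirical `(1−K)` quantile of `Y` over the whole
replicate (parents and offspring together), so the case fraction is exactly
`K` in every replicate; `Y` is not exactly Gaussian (uniform-mixture age
term), so a theoretical quantile would not achieve that. Ties at the
threshold are broken by individual id. A consequence of the shared threshold
and the age gradient is that prevalence rises steeply with age: offspring
case rate ≈ 0.22, parents ≈ 0.40, grandparents higher still — the regime in
which family history is most informative.

## Pedigree simulation

Nuclear cohorts: 200 two-child + 200 three-child families (N = 1800, 1000
offspring). Child ages are uniform on [18, 45]; the mother is 20–45 years
older than her oldest child; the father is within five years of the mother
and at least 20 years older than the oldest child (enforced by clamping,
which cannot violate the five-year rule). Three-generation cohorts add both
parents of each parent (N = 3400) with the same rules applied one generation
up, treating each parent as the oldest child of their own parents — the
generation rules do not specify grandparent ages, and this recursion is the
only reading consistent with them.

Founder genotypes are drawn under Hardy–Weinberg equilibrium with
`P(2 minor) = MAF²` — the standard orientation, so the expected sample
minor-allele frequency equals the nominal MAF — and descendants receive
alleles by gene dropping (each parent transmits a uniformly chosen allele).
Per-family kinship matrices come from the standard recursion and are verified
in the tests against a brute-force identity-by-descent gene-dropping oracle.

## Association testing and family-clustered inference

* **CC-GWAS**: logistic regression of offspring status on offspring genotype,
  adjusting for age and sex (the two simulated confounders); only the 1000
  offspring enter, as if parental genotypes were unavailable.
* **LT-FH**: the posterior-mean-liability table is built once per
  `(h², K, n_mc, seed)` by rejection sampling from the joint liability MVN
  (default `n_mc = 10⁶`; cells are exact Monte-Carlo conditional means with
  stored standard errors; the table is cached as TSV when a cache directory
  is given). Multiple siblings extend the MVN with exchangeable unit-variance
  rows at covariance `0.5h²` with the genetic component, each parent and each
  other sibling. The association test is a linear regression of the score on
  genotype + age + sex over offspring.
* **Fam-meta**: the proband stream is CC-GWAS; the relatives stream is a
  logistic regression of relative status on the family-mean proband genotype,
  adjusting for family-mean proband phenotype and the relative's age and sex
  (the covariate recipe of the method's cohort application, which the
  simulation description does not restate). `T_meta` combines the two with
  the kinship weight; a non-converged stream flags the variant, which counts
  as a non-rejection.

**Why not iid regressions.** Siblings within a family share both parents'
statuses, half their genotypes, and a polygenic component. Ordinary
standard errors are therefore anti-conservative — drastically so for LT-FH,
whose sibling scores correlate at ≈ 0.5 (parents-only history) because they
are functions of the same parental statuses; iid OLS yields a type-I error
of ≈ 0.12 at α = 0.05. All cohort-level regressions therefore use
generalized estimating equations with an exchangeable within-family working
correlation and model-based covariance; for the offspring regressions family
members are genuinely exchangeable (full siblings), making this the family
random-intercept mixed model. The working correlation is bounded above by
0.5, the maximum an additive-kinship covariance can express for full
siblings. Model-based (rather than sandwich) covariance matters for the
MAF 0.01 variant, where only ~20 offspring carry the allele and per-cluster
empirical variances are unstable. With this inference all three methods hold
the nominal levels at α ∈ {0.05, 0.01, 0.005} (measured pooled rates 0.046–
0.052 at 40,000 null tests per method).

**LT-FH family-history scope.** By default the score conditions on the
individual's own status and both parents' statuses (`include_siblings=False`).
Conditioning additionally on siblings raises the within-family score
correlation to ≈ 0.85; the extra information is family-level and is
discounted again by any family-clustered inference, which in practice lowers
LT-FH power rather than raising it. The sibling mode remains available as a
flag.

**Known divergence.** In the original study LT-FH is reported as both more
powerful than our implementation achieves (increase over CC-GWAS ≈ +0.05 vs
our ≈ +0.02) and conservative under the null, a combination we could not
reproduce under any defensible inference choice: counting the parents'
statuses once per family (as clustered inference must) caps the LT-FH edge.
Its exact mixed-model implementation is not specified. Our LT-FH is exactly
calibrated (type-I ≈ 0.050) and its power lies between CC-GWAS and Fam-meta
at most allele frequencies, a few points below the published LT-FH column.
All CC-GWAS, Fam-meta, grandparent and interaction-model results reproduce
the published tables within Monte-Carlo error.

## The transmission coefficient 2φ

`T_meta`'s weight assumes the relative regression recovers `2φ` times the
proband effect. On the liability scale this is exact:
`E[g_relative | g_proband] = 2φ·g_proband + const`, and
`genetic_attenuation(scale="liability")` recovers 0.50 (parents) and 0.25
(grandparents) within a few percent at ≥ 10⁵ pooled records. On the observed
binary scale the ratio is compressed below `2φ` (≈ 0.45 parents, ≈ 0.21
grandparents as single-proband regressions; ≈ 0.44 / 0.32 for the production
regression with proband averaging and phenotype conditioning) because each
generation has a different case rate and hence a different logistic slope
per unit liability. The kinship weight is therefore an approximation on the
observed scale; it affects efficiency, not validity, since `T_meta` is a
fixed linear combination of two asymptotically normal statistics.

## Experiments

Per replicate everything is re-simulated — ages, sexes, genotypes, polygenic
effects, phenotypes (the conservative reading of a per-iteration protocol).
Under the null, eight variants with the same MAFs are generated independently
of the phenotype and tested. Power/type-I for a (MAF, method) cell is the
fraction of replicates with `p < α`, with Clopper–Pearson 95% intervals;
non-converged fits count as non-rejections and are reported as a rate. The
study-scale protocol is 50,000 null replicates (model 1) and 5,000 power
replicates; the bundled acceptance script uses 5,000 and 2,000 respectively
and the test suite 5,000 and 1,000, sizes at which Monte-Carlo error
(±0.01–0.015 per cell) is small relative to the effects of interest. The
master seed spawns independent per-replicate, per-stage substreams
(`numpy.random.SeedSequence`), so any table is bit-reproducible from its
seed and replicates are independently reproducible.

λ_GC is the median of the implied 1-df chi-square statistics divided by
0.4549; it is exercised property-based (uniform p-values give λ ≈ 1), as the
real-data application that reports λ_GC requires controlled-access data.

## What the simulator does and does not emulate

It reproduces the benchmark's study conditions: fixed family topologies,
independent variants (no linkage disequilibrium), HWE founders, random
mating, a single shared environment-free liability, complete and error-free
phenotypes and family history, and age distributions tied to generation.
Real cohorts add LD, assortative mating, shared family environment,
ascertainment, missing and misreported family history, and age-of-onset
censoring — none of which are modeled, so passing benchmarks here says
nothing about robustness to those features. Rare-variant behavior below
MAF 0.01 and non-European-style allele-frequency spectra are untested.

## Numerical choices

* Logistic IRLS: convergence `|Δ log-likelihood| < 10⁻⁸`, max 50 iterations;
  separation detected by a coefficient bound (30 on the standardized design)
  or perfectly reproduced responses; failures flagged, never raised, inside
  experiment loops.
* GEE: correlation re-estimated each scoring step by method of moments on
  Pearson residuals, clipped to [0, min(0.5, 0.99)] as above; fitted
  probabilities clipped at 10⁻¹² for weight stability.
* Posterior table cells with zero Monte-Carlo mass are NaN and raise a
  KeyError naming the configuration on lookup.
* Exact-fit linear regressions (zero residual variance) report a degenerate
  p-value rather than dividing by zero.
* Wald p-values are floored at the smallest subnormal double to keep them in
  (0, 1].
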