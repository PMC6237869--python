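# Methods note

## Causal model and estimators

Let $G_j \in \{0,1,2\}$ be the effect-allele dosage at variant $j$,
$X_j$ the perceived intensity of its bitter stimulus (standardized),
and $Y$ a beverage phenotype. The structural model is

$$X_j = \beta_{1j} G_j + \varepsilon_X, \qquad
  Y = \sum_j \theta_j X_j + \gamma^\top C + \varepsilon_Y,$$

with covariates $C$ (age, sex, principal components) and, under the
exclusion restriction, no direct path $G_j \to Y$. Estimating
$\hat\beta_{1j}$ (SD/allele) in sample 1 and $\hat\beta_{2j}$
(units of $Y$/allele) in sample 2 gives the Wald ratio

$$\hat\theta_j = \hat\beta_{2j} / \hat\beta_{1j},$$

the causal effect of a 1 SD increase in perceived intensity.

**Standard errors.** Two delta-method variants are implemented:

- *first-order*: $\mathrm{se}(\hat\theta) = \mathrm{se}(\hat\beta_2)/|\hat\beta_1|$,
  which ignores instrument uncertainty; when the outcome association
  carries published CI bounds, the bounds are rescaled directly so a
  printed interval divides through exactly.
- *full delta*:
  $\mathrm{se}(\hat\theta)^2 = \mathrm{se}(\hat\beta_2)^2/\hat\beta_1^2
  + \hat\beta_2^2\,\mathrm{se}(\hat\beta_1)^2/\hat\beta_1^4$,
  with zero cross-covariance (the samples are independent).

Both are validated in the test suite against a Monte-Carlo oracle
(10,000 parametric replicates of the ratio) at instrument $z > 10$, and
by a 500-replicate coverage experiment (the 95% CI must cover the
configured causal effect 93–97% of the time).

**Binary outcomes.** Heavy-vs-light drinker contrasts are logistic
regressions; the per-allele log OR divided by $\hat\beta_1$ and
exponentiated is the causal OR per SD. CIs are formed on the log scale
and exponentiated. `linear_to_logOR(β, μ) = β/(μ(1−μ))` provides the
first-order bridge from a linear-probability slope.

**Auxiliary statistics.** Instrument strength
$F = (n-2)R^2/(1-R^2)$; power for a two-sided level-$\alpha$ Wald test
uses non-centrality $\sqrt{nR^2}\,\theta$. Sex differences use the
two-sample z-test $z = (\hat\theta_f - \hat\theta_m)/
\sqrt{\mathrm{se}_f^2 + \mathrm{se}_m^2}$, with sex-specific SEs
reconstructed from CI half-widths. The primary family of nine tests
(3 stimuli × 3 beverages) uses the Bonferroni threshold
$0.05/9 \approx 0.00556$.

## Synthetic cohort generator

Published cohort-level data are access-controlled, so validation uses a
generator whose defaults are calibrated to published summary
quantities.

**Genotypes.** Hardy-Weinberg binomial(2, p) dosages. The effect-allele
frequency is solved from the variance-explained target:
$2p(1-p)\beta_1^2 = R^2 \Rightarrow p \in (0, 0.5]$. Defaults: PROP
$p = 0.445$ ($R^2 = 0.46$), quinine $p = 0.411$ ($R^2 = 0.055$),
caffeine $p = 0.174$ ($R^2 = 0.02$). The quinine target is 0.055 rather
than the published ≈0.06 because $2p(1-p) \le 0.5$ makes
$R^2 = 0.06$ unattainable with $\beta_1 = 0.337$; 0.055 is the nearest
feasible round value, and the configuration class raises a clear error
for any infeasible pair rather than silently clamping.

**Sample 1 (taste test, n = 1,757).** Ratings are generated on a
square-root-transformed scale and standardized empirically, matching
the convention of reporting instrument effects in SD units of
transformed intensity.

**Sample 2 (consumption, n = 50,000 default).** Coffee and tea are
censored-and-rounded latent normals:
$Y = \max(0, \mathrm{round}(Y^*))$, $Y^* \sim N(\mu, \sigma^2)$.
The latent $(\mu, \sigma)$ are solved by root-finding on the exact
censored-rounded moment sums so that the *observed* marginals hit their
targets (coffee mean 2.13, SD 2.24; tea mean 3.52, SD 2.77). The
coffee-tea correlation target (−0.30) is mapped to a latent correlation
through a second-order Hermite expansion of the rounding/censoring
transform; the realized observed correlation is −0.301 at large n.
Causal and covariate effects are injected on the latent scale, with the
residual covariance completing the calibrated totals so marginals stay
on target regardless of the configured effects. Alcohol frequency is an
ordered probit over six categories calibrated to target category
probabilities, recodable to occasions/month (0, 1, 2, 6, 15, 30).

**Default per-SD causal effects** (units of cups/day or
occasions/month per SD of perceived intensity): coffee — PROP −0.021,
quinine −0.081, caffeine +0.146; tea — PROP +0.035, quinine +0.083,
caffeine −0.171; alcohol — PROP −0.136, quinine +0.03, caffeine −0.047.
Tea and alcohol defaults are per-allele published values divided by the
instrument's per-allele SD effect; the quinine-alcohol value is a
representative small positive effect where no per-allele point estimate
with compatible precision was available.

**Determinism.** All randomness flows from one
`numpy.random.SeedSequence(seed)` split into independent child streams
per sample; identical configurations are bit-identical, which the
pipeline manifest records via a configuration hash.

## Numerical and design choices

- **Rounding/censoring attenuation.** The observed-scale per-allele
  slope is attenuated relative to the latent slope by a factor
  $c_1 \cdot \mathrm{sd}(Y)/\sigma$ (first Hermite coefficient of the
  transform): ≈0.74 for coffee, ≈0.83 for tea. Consequently the CI
  *coverage* experiment runs on the latent beverage scale, where the
  estimand equals the configured effect exactly; on the rounded scale
  the estimand is the attenuated slope and coverage of the configured
  value would conflate bias with interval quality.
- **Sign-pattern test at n = 300,000.** The smallest configured effect
  (PROP→coffee, −0.021/SD) has $|z| \approx 1.3$ at n = 50,000 — sign
  recovery there is a coin flip plus noise, so asserting it would test
  luck, not code. At n = 300,000 every configured effect has expected
  $|z| \gtrsim 2.8$ and joint sign recovery per seed ≈99.5%, making
  ≥19/20 fixed seeds a fair bar.
- **Instrument SEs from F.** Where only $(\beta_1, F)$ are published,
  $\mathrm{se}(\beta_1) = \beta_1/\sqrt{F}$ (the definitional identity
  for a single-regressor Wald F).
- **Drinker cutoffs.** Fixed mode uses strict inequalities — coffee:
  light < 2, heavy > 4 cups/day; tea: < 2, > 5; alcohol: never vs daily
  or almost daily — with an intermediate class excluded from logistic
  contrasts. Percentile mode (20th/80th) is provided for sensitivity
  analyses and refuses degenerate distributions with an actionable
  error.
- **Estimation safeguards.** Association fits require ≥50 complete
  cases (≥25 per logistic class), reject constant or collinear
  regressors naming the offending column, and surface
  perfect-separation failures as `EstimationError` rather than
  statsmodels internals.

## Limitations

- The generator validates the estimators, not the biology: its causal
  effects are configured, so analyses on synthetic cohorts demonstrate
  recovery of known inputs, nothing more.
- A single-variant instrument per stimulus permits no pleiotropy
  diagnostics (no Egger/median estimators); the exclusion restriction
  is assumed and is checked only *within* the generator (a partial
  correlation test plus a direct-effect switch that breaks it).
- The first-order OR bridge and the delta-method SEs are asymptotic;
  both are checked at the sample sizes used, not in general.
- At the default n = 50,000, per-allele effects of realistic size do
  not reach Bonferroni significance; significance claims require
  biobank-scale n (~440,000), which the power calculator quantifies.
- Covariate effects, allele frequencies and demographics are stylized
  (independent genotypes, normal age, two-category sex, standard-normal
  PCs); population structure and assortative mating are out of scope.
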