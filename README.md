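# bittermr

Two-sample Mendelian randomization of bitter-taste perception and
beverage consumption, with a calibrated synthetic-cohort generator for
end-to-end validation.

## Scientific problem

Observationally, people who drink a lot of coffee drink less tea and
vice versa, but taste preference, culture and confounding make the
causal story hard to read. Perceived intensity of specific bitter
compounds — PROP (a thiourea), quinine and caffeine — is strongly
influenced by single genetic variants in bitter-taste receptor loci:

| SNP | Effect allele | Stimulus | β (SD/allele) | R² | F (n = 1,757) |
|---|---|---|---|---|---|
| rs1726866 | G | PROP | 0.965 | 0.46 | 901.1 |
| rs10772420 | A | quinine | 0.337 | 0.06 | 96.8 |
| rs2597979 | G | caffeine | 0.264 | 0.02 | 30.0 |

Because genotypes are fixed at conception, these variants can serve as
*instruments*: if genetically higher perceived bitterness of caffeine
shifts coffee intake, that shift is attributable to the perception
phenotype rather than to confounding. The two-sample design estimates
the instrument-exposure effect (β̂₁, SD of perceived intensity per
allele) in a small taste-test cohort and the instrument-outcome effect
(β̂₂, cups/day per allele) in a large consumption cohort, and combines
them as the Wald ratio β̂₂ / β̂₁ — the causal effect of a 1 SD increase
in perceived intensity on consumption.

This package implements:

- **`bittermr.synth_cohort`** — a generative model producing both
  samples with configurable per-SD causal effects, allele frequencies
  solved from variance explained, calibrated beverage marginals
  (censored-and-rounded latent normals) and a calibrated negative
  coffee-tea correlation.
- **`bittermr.phenotypes`** — harmonization: categorical
  alcohol-frequency recoding to occasions/month, repeat-assessment
  averaging, and light/intermediate/heavy drinker dichotomization at
  fixed or percentile cutoffs.
- **`bittermr.assoc`** — covariate-adjusted linear and logistic
  SNP-phenotype association fits (statsmodels), with a
  linear-to-log(OR) approximation for binary traits.
- **`bittermr.mr`** — Wald ratios with first-order and full
  delta-method standard errors, causal odds ratios, instrument F
  statistics, power, sex-difference z-tests, Bonferroni correction and
  a full analysis battery (main, binary, conditional, stratified,
  sex-stratified).
- **`bittermr.pipeline`** + CLI `bittermr` — a deterministic
  simulate → harmonize → associate → MR pipeline writing tab-separated
  tables and a manifest.

## Worked example

Recomputing the headline causal estimate from per-allele summary
statistics alone — each G allele of rs2597979 raises perceived caffeine
intensity by 0.264 SD and coffee intake by 0.039 cups/day
(95% CI 0.027–0.050):

```python
>>> from bittermr import wald_ratio
>>> from bittermr.reported import reported_coffee_assoc_caffeine, reported_instruments
>>> caffeine = next(i for i in reported_instruments() if i.stimulus == "caffeine")
>>> res = wald_ratio(reported_coffee_assoc_caffeine(), caffeine, se_mode="first_order")
>>> print(f"{res.estimate:.3f} [{res.ci_low:.3f}, {res.ci_high:.3f}] cups/day per SD")
0.148 [0.102, 0.189] cups/day per SD
```

Higher genetically proxied caffeine perception *increases* coffee
intake — the opposite sign from PROP and quinine, and mirrored for tea.

Running the whole pipeline on a synthetic cohort:

```bash
$ bittermr all --seed 2024 --outdir results/demo
```

or step by step through the narrative scripts:

```bash
$ python analysis/01_simulate_cohorts.py
sample 2: n = 50000
  mean coffee     = 2.125 cups/day
  mean tea        = 3.518 cups/day
  corr(coffee, tea) = -0.302
$ python analysis/02_harmonize_phenotypes.py
$ python analysis/03_fit_associations.py
$ python analysis/04_mr_estimates.py
$ python analysis/05_summary_mr_worked_examples.py
caffeine -> coffee Wald ratio (first_order): 0.148 [0.102, 0.189] cups/day per SD
caffeine -> tea, female -0.261 vs male -0.091: z = -2.71, p = 0.0068
```

Small result tables are committed under `results/`; the 50,000-row
cohort files they derive from are regenerated by
`analysis/01_simulate_cohorts.py` and deliberately not committed.

At n = 50,000 the main per-allele estimates reproduce the expected
*sign pattern* (caffeine positive on coffee, PROP/quinine negative,
mirrored for tea) but not genome-bank-scale significance — the fixed
cutoffs and effect sizes were designed for cohorts of ~440,000, and
`analysis/04_mr_estimates.py` says so in its output rather than
overstating the result.

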