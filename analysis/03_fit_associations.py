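#!/usr/bin/env python
"""Step 3: fit the genetic instruments and SNP-beverage associations.

From sample 1, regresses each standardized perceived-intensity rating on
its variant dosage to estimate the instrument strength (per-allele
effect in SD units, R-squared and F statistic).  From harmonized sample
2, fits linear SNP-beverage associations adjusted for age, sex and ten
principal components, and logistic heavy-vs-light drinker contrasts.

Writes results/associations/instruments.tsv and
results/associations/associations.tsv.
"""

from pathlib import Path

import pandas as pd

from bittermr import association_table, fit_taste_instruments
from bittermr.assoc import (
    DEFAULT_COVARIATES,
    fit_linear_snp_assoc,
    fit_logistic_snp_assoc,
)
from bittermr.pipeline import instruments_table, read_cohort
from bittermr.synth_cohort import STIMULI

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    sample1 = pd.read_csv(ROOT / "cohorts" / "sample1_taste.tsv", sep="\t")
    instruments = fit_taste_instruments(sample1)
    inst_df = instruments_table(instruments)
    outdir = ROOT / "associations"
    outdir.mkdir(parents=True, exist_ok=True)
    inst_df.to_csv(outdir / "instruments.tsv", sep="\t", index=False)
    print(inst_df.to_string(index=False))

    cohort = read_cohort(ROOT / "cohorts" / "sample2_harmonized.tsv")
    results = []
    for stim in STIMULI:
        dosage = f"{stim}_dosage"
        for bev in ("coffee", "tea", "alcohol_freq_month"):
            results.append(
                fit_linear_snp_assoc(
                    cohort, dosage, bev, covariates=DEFAULT_COVARIATES
                )
            )
        for bev in ("coffee", "tea", "alcohol"):
            results.append(
                fit_logistic_snp_assoc(
                    cohort,
                    dosage,
                    f"{bev}_drinker_status",
                    covariates=DEFAULT_COVARIATES,
                )
            )
    assoc_df = association_table(results)
    assoc_df.to_csv(outdir / "associations.tsv", sep="\t", index=False)
    print(f"\n{len(assoc_df)} associations written to {outdir}")


if __name__ == "__main__":
    main()
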