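#!/usr/bin/env python
"""Step 2: harmonize the consumption phenotypes.

Recodes the categorical alcohol frequency to occasions/month, and
dichotomizes each beverage into light/intermediate/heavy drinker status
at fixed cutoffs (coffee: <2 vs >4 cups/day; tea: <2 vs >5; alcohol:
never vs daily-or-almost-daily).

Reads results/cohorts/sample2_consumption.tsv; writes
results/cohorts/sample2_harmonized.tsv and a drinker-status count table.
"""

from pathlib import Path

from bittermr import harmonize_cohort
from bittermr.pipeline import read_cohort
from bittermr.synth_cohort import export_cohort

ROOT = Path(__file__).resolve().parent.parent / "results" / "cohorts"


def main() -> None:
    cohort = read_cohort(ROOT / "sample2_consumption.tsv")
    harmonized, statuses = harmonize_cohort(cohort)
    export_cohort(harmonized, ROOT / "sample2_harmonized.tsv")

    counts = {}
    for bev in ("coffee", "tea", "alcohol"):
        col = harmonized[f"{bev}_drinker_status"]
        counts[bev] = col.value_counts().to_dict()
        print(f"{bev}: {counts[bev]}")
    for status in statuses.values():
        print(
            f"  {status.beverage}: cutoffs ({status.cutoff_low}, "
            f"{status.cutoff_high}), mode = {status.mode}"
        )

    import pandas as pd

    pd.DataFrame(counts).to_csv(ROOT / "drinker_status_counts.tsv", sep="\t")
    print(f"wrote {ROOT / 'sample2_harmonized.tsv'}")


if __name__ == "__main__":
    main()
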