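"""Beverage-phenotype harmonization.

Recoding of the 6-level alcohol-frequency questionnaire to monthly
drinking occasions, averaging of repeat assessments, and drinker-status
dichotomization at either the questionnaire's fixed cutoffs or the
empirical 20th/80th percentiles.

Cutoff conventions (fixed mode): coffee light/non <2 and heavy >4
cups/day; tea light/non <2 and heavy >5 cups/day; alcohol non-drinker =
"Never" and heavy = drinking more often than 3-4 times a week (i.e.
daily or almost daily). Inequalities are strict: a participant exactly
at a cutoff is *intermediate* and excluded from binary contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .synth_cohort import (
    ALCOHOL_LEVELS,
    ALCOHOL_MONTHLY_FREQ,
    PREFER_NOT_TO_ANSWER,
)

__all__ = [
    "DrinkerStatus",
    "FIXED_CUTOFFS",
    "LIGHT",
    "INTERMEDIATE",
    "HEAVY",
    "recode_alcohol_frequency",
    "average_repeat_assessments",
    "collapse_repeat_columns",
    "dichotomize_drinkers",
    "harmonize_cohort",
]

LIGHT = "light_or_non"
INTERMEDIATE = "intermediate"
HEAVY = "heavy"

#: fixed (questionnaire-anchored) cutoffs; strict inequalities on both sides.
FIXED_CUTOFFS = {"coffee": (2.0, 4.0), "tea": (2.0, 5.0), "alcohol": (0.0, 15.0)}

_ALCOHOL_MAP = dict(zip(ALCOHOL_LEVELS, ALCOHOL_MONTHLY_FREQ))


@dataclass(frozen=True)
class DrinkerStatus:
    """Cutoffs defining a light/intermediate/heavy partition."""

    beverage: str
    cutoff_low: float
    cutoff_high: float
    mode: str  # "fixed" or "percentile"

    def __post_init__(self) -> None:
        if not self.cutoff_low < self.cutoff_high:
            raise ValueError(
                f"{self.beverage}: cutoff_low ({self.cutoff_low}) must be below "
                f"cutoff_high ({self.cutoff_high})"
            )


def recode_alcohol_frequency(category):
    """Map the 6-level alcohol-frequency answer to drinking occasions/month.

    Never -> 0, Special occasions only -> 1, 1-3 times a month -> 2,
    1-2 times a week -> 6, 3-4 times a week -> 15, Daily or almost
    daily -> 30. "Prefer not to answer" and missing propagate as missing
    (those participants are excluded downstream). Accepts a scalar, an
    array, or a pandas Series; unrecognized labels raise ``ValueError``.
    Values already on the monthly-frequency scale pass through unchanged,
    making the recoding idempotent.
    """
    if isinstance(category, (pd.Series, np.ndarray, list, tuple)):
        s = pd.Series(category)
        return s.map(lambda v: recode_alcohol_frequency(v))
    if category is None or (isinstance(category, float) and np.isnan(category)):
        return np.nan
    if isinstance(category, (int, float, np.integer, np.floating)):
        if float(category) in ALCOHOL_MONTHLY_FREQ:
            return float(category)
        raise ValueError(f"unrecognized alcohol frequency value: {category!r}")
    if category == PREFER_NOT_TO_ANSWER:
        return np.nan
    try:
        return _ALCOHOL_MAP[category]
    except KeyError:
        raise ValueError(f"unrecognized alcohol category label: {category!r}") from None


def average_repeat_assessments(values: Iterable) -> float:
    """Arithmetic mean of the non-missing repeat measurements.

    Participants assessed at multiple visits contribute the average of
    their non-missing answers; if every entry is missing the result is
    missing.
    """
    arr = np.asarray(list(values), dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        return np.nan
    return float(arr.mean())


def collapse_repeat_columns(table: pd.DataFrame, base: str) -> pd.Series:
    """Average columns named ``{base}_v0, {base}_v1, ...`` row-wise.

    Returns the single-visit column unchanged when no repeat columns
    exist.
    """
    repeats = [c for c in table.columns if c == base or c.startswith(f"{base}_v")]
    if not repeats:
        raise KeyError(f"no columns found for phenotype {base!r}")
    return table[repeats].mean(axis=1, skipna=True)


def _label_continuous(values: pd.Series, low: float, high: float) -> pd.Series:
    labels = pd.Series(
        np.where(
            values.isna(),
            None,
            np.where(values < low, LIGHT, np.where(values > high, HEAVY, INTERMEDIATE)),
        ),
        index=values.index,
        dtype=object,
    )
    labels[values.isna()] = np.nan
    return labels


def dichotomize_drinkers(
    table: pd.DataFrame,
    beverage: str,
    mode: str = "fixed",
    cutoffs: tuple[float, float] | None = None,
    percentiles: tuple[float, float] = (20.0, 80.0),
) -> tuple[pd.Series, DrinkerStatus]:
    """Assign light_or_non / intermediate / heavy drinker labels.

    Fixed mode applies the questionnaire-anchored cutoffs (see module
    docstring); for alcohol it works on ``alcohol_category`` directly
    ("Never" -> light_or_non, "Daily or almost daily" -> heavy — only
    drinking *more often than* 3-4 times a week counts as heavy).
    Percentile mode computes the 20th/80th percentiles of the supplied
    table's own distribution (for alcohol, of the recoded monthly
    frequency). ``cutoffs`` overrides either mode's thresholds, which is
    how alternative sensitivity cutoffs are expressed.

    Returns the per-participant label Series (missing phenotypes stay
    missing) and the :class:`DrinkerStatus` describing the partition.
    """
    if beverage not in FIXED_CUTOFFS:
        raise ValueError(f"unknown beverage {beverage!r}")
    if mode not in ("fixed", "percentile"):
        raise ValueError(f"mode must be 'fixed' or 'percentile', got {mode!r}")

    if beverage == "alcohol":
        values = _alcohol_monthly(table)
    else:
        values = pd.to_numeric(table[beverage], errors="coerce")

    if cutoffs is not None:
        low, high = cutoffs
    elif mode == "fixed":
        low, high = FIXED_CUTOFFS[beverage]
    else:
        non_missing = values.dropna()
        low = float(np.percentile(non_missing, percentiles[0]))
        high = float(np.percentile(non_missing, percentiles[1]))
        if low == high:
            raise ValueError(
                f"{beverage}: degenerate percentiles ({low} == {high}); "
                "use mode='fixed' or explicit cutoffs"
            )

    if beverage == "alcohol" and cutoffs is None and mode == "fixed":
        # categorical rule: Never is a non-drinker; heavy means drinking more
        # often than 3-4 times a week, i.e. daily or almost daily.
        cat = table["alcohol_category"]
        labels = pd.Series(np.nan, index=table.index, dtype=object)
        known = cat.isin(ALCOHOL_LEVELS)
        labels[known] = INTERMEDIATE
        labels[cat == ALCOHOL_LEVELS[0]] = LIGHT
        labels[cat == ALCOHOL_LEVELS[-1]] = HEAVY
        status = DrinkerStatus("alcohol", 0.0, 15.0, "fixed")
        return labels, status

    labels = _label_continuous(values, low, high)
    return labels, DrinkerStatus(beverage, float(low), float(high), mode)


def _alcohol_monthly(table: pd.DataFrame) -> pd.Series:
    if "alcohol_freq_month" in table.columns:
        return pd.to_numeric(table["alcohol_freq_month"], errors="coerce")
    return recode_alcohol_frequency(table["alcohol_category"]).astype(float)


def harmonize_cohort(
    table: pd.DataFrame, mode: str = "fixed"
) -> tuple[pd.DataFrame, dict[str, DrinkerStatus]]:
    """Full harmonization pass over a consumption cohort.

    Averages any repeat-assessment columns (``coffee_v0`` style), recodes
    alcohol frequency to occasions/month (``alcohol_freq_month``), and
    adds ``{beverage}_drinker_status`` label columns. Returns the new
    table plus the cutoff definitions used.
    """
    out = table.copy()
    for bev in ("coffee", "tea"):
        if bev not in out.columns or any(
            c.startswith(f"{bev}_v") for c in out.columns
        ):
            out[bev] = collapse_repeat_columns(out, bev)
    out["alcohol_freq_month"] = recode_alcohol_frequency(
        out["alcohol_category"]
    ).astype(float)
    statuses: dict[str, DrinkerStatus] = {}
    for bev in ("coffee", "tea", "alcohol"):
        labels, status = dichotomize_drinkers(out, bev, mode=mode)
        out[f"{bev}_drinker_status"] = labels
        statuses[bev] = status
    return out, statuses
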