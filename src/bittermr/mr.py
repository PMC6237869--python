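"""Single-instrument two-sample Mendelian randomization.

The causal effect of perceived bitterness on beverage intake is the
Wald-type ratio

    beta_wald = beta_bev / beta_bitter

with ``beta_bev`` the per-effect-allele SNP-beverage association
(sample 2) and ``beta_bitter`` the per-effect-allele shift in the
standardized taste-intensity rating (sample 1). For drinker-status
contrasts the causal odds ratio is ``exp(log OR_drinkstatus /
beta_bitter)``. Standard errors come from the delta method, either
first-order (numerator uncertainty only, equivalent to scaling the
outcome CI) or the full two-term expansion with zero cross-covariance,
as befits a two-sample design. Diagnostics: one-regressor instrument
F-statistics, closed-form power, Bonferroni thresholds and normal
z-tests for subgroup differences.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .assoc import (
    AssociationResult,
    EstimationError,
    fit_linear_snp_assoc,
    fit_logistic_snp_assoc,
)
from .synth_cohort import BEVERAGES, STIMULI

__all__ = [
    "GeneticInstrument",
    "MRResult",
    "StratumSpec",
    "AnalysisPlan",
    "wald_ratio",
    "causal_or",
    "instrument_F",
    "mr_power",
    "se_from_ci",
    "difference_test",
    "subgroup_difference_test",
    "bonferroni_threshold",
    "run_mr_battery",
    "mr_table",
    "sex_difference_tests",
]

Z95 = norm.ppf(0.975)


@dataclass(frozen=True)
class GeneticInstrument:
    """One SNP proxy for one bitter stimulus.

    ``beta`` is the per-effect-allele effect on the square-root
    transformed, standardized intensity rating (SD units); the effect
    allele is oriented so that ``beta > 0``. ``f_statistic`` may carry an
    externally reported instrument-strength value; :meth:`f` recomputes
    the one-regressor convention from R^2 and n when it is absent.
    """

    snp: str
    effect_allele: str
    stimulus: str
    beta: float
    se: float
    variance_explained: float
    n: int
    f_statistic: float | None = None

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError(
                "instrument effect must be positive (orient the effect allele "
                "to increase perceived bitterness)"
            )
        if self.se <= 0:
            raise ValueError("instrument SE must be positive")
        if not 0.0 < self.variance_explained < 1.0:
            raise ValueError("variance_explained must lie in (0, 1)")
        if self.n <= 2:
            raise ValueError("discovery n must exceed 2")

    def f(self) -> float:
        if self.f_statistic is not None:
            return self.f_statistic
        return instrument_F(self.variance_explained, self.n)


@dataclass(frozen=True)
class MRResult:
    """Causal estimate per SD of perceived bitterness.

    For ``scale='odds_ratio'``, ``estimate``/``ci_*`` are on the OR scale
    and ``se`` is on the log-OR scale.
    """

    stimulus: str
    outcome: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    scale: str  # linear | odds_ratio
    analysis: str = "main"
    stratum: str | None = None
    n: int | None = None
    significant: bool | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.p <= 1.0:
            raise ValueError("p must lie in (0, 1]")

    def estimation_scale(self) -> tuple[float, float]:
        """(estimate, se) on the scale the z-statistic lives on."""
        if self.scale == "odds_ratio":
            return math.log(self.estimate), self.se
        return self.estimate, self.se


def _p_from_z(z: float) -> float:
    return max(float(2.0 * norm.sf(abs(z))), np.nextafter(0, 1))


def wald_ratio(
    assoc: AssociationResult,
    instrument: GeneticInstrument,
    se_mode: str = "full_delta",
) -> MRResult:
    """Wald ratio estimate ``assoc.beta / instrument.beta`` with delta-method SE.

    ``se_mode='first_order'`` propagates only the numerator's uncertainty
    (``se_bev / |beta_bitter|``) and, when the association carries
    explicit CI bounds, obtains the MR CI by scaling those bounds — the
    operation that reproduces published intervals. ``'full_delta'`` adds
    the instrument-uncertainty term:

        sqrt(se_bev^2 / b^2 + beta_bev^2 se_b^2 / b^4)

    with zero cross-covariance (the two estimates come from different
    samples).
    """
    if assoc.model != "linear":
        raise ValueError("wald_ratio expects a linear association; use causal_or")
    return _ratio(assoc, instrument, se_mode, scale="linear")


def causal_or(
    assoc: AssociationResult,
    instrument: GeneticInstrument,
    se_mode: str = "full_delta",
) -> MRResult:
    """Causal odds ratio ``exp(log OR_drinkstatus / beta_bitter)``.

    The ratio and its CI are formed on the log-odds scale and then
    exponentiated, so the interval is symmetric on the log scale.
    """
    if assoc.model not in ("logistic", "linear_approx_logOR"):
        raise ValueError("causal_or expects a logistic (log-OR) association")
    log_res = _ratio(assoc, instrument, se_mode, scale="linear")
    return replace(
        log_res,
        estimate=math.exp(log_res.estimate),
        ci_low=math.exp(log_res.ci_low),
        ci_high=math.exp(log_res.ci_high),
        scale="odds_ratio",
    )


def _ratio(
    assoc: AssociationResult,
    instrument: GeneticInstrument,
    se_mode: str,
    scale: str,
) -> MRResult:
    b = instrument.beta
    if b == 0:
        raise ZeroDivisionError("instrument effect is zero; Wald ratio undefined")
    if se_mode not in ("first_order", "full_delta"):
        raise ValueError(f"se_mode must be 'first_order' or 'full_delta', got {se_mode!r}")
    estimate = assoc.beta / b
    if se_mode == "first_order":
        se = assoc.se / abs(b)
        lo, hi = assoc.ci()
        ci_low, ci_high = lo / b, hi / b
    else:
        se = math.sqrt(
            assoc.se**2 / b**2 + assoc.beta**2 * instrument.se**2 / b**4
        )
        ci_low, ci_high = estimate - Z95 * se, estimate + Z95 * se
    return MRResult(
        stimulus=instrument.stimulus,
        outcome=assoc.phenotype,
        estimate=estimate,
        se=se,
        ci_low=min(ci_low, ci_high),
        ci_high=max(ci_low, ci_high),
        p=_p_from_z(estimate / se),
        scale=scale,
        stratum=assoc.stratum,
        n=assoc.n,
    )


def instrument_F(variance_explained: float, n: int) -> float:
    """One-regressor instrument strength, ``(n - 2) R^2 / (1 - R^2)``.

    Values well above 10 indicate a strong instrument (negligible
    weak-instrument bias in the ratio estimate).
    """
    if not 0.0 <= variance_explained < 1.0:
        raise ValueError("variance_explained must lie in [0, 1)")
    if n <= 2:
        raise ValueError("n must exceed 2")
    return (n - 2) * variance_explained / (1.0 - variance_explained)


def mr_power(
    n: int, variance_explained: float, causal_effect: float, alpha: float = 0.05
) -> float:
    """Two-sided power of the single-instrument MR test.

    Normal approximation with non-centrality ``sqrt(n R^2) * theta`` for a
    standardized causal effect ``theta`` (SD of outcome per SD of
    exposure), outcome sample size ``n`` and instrument R^2 on the
    exposure.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0.0 < variance_explained < 1.0:
        raise ValueError("variance_explained must lie in (0, 1)")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    ncp = math.sqrt(n * variance_explained) * causal_effect
    z = norm.ppf(1.0 - alpha / 2.0)
    return float(norm.sf(z - ncp) + norm.cdf(-z - ncp))


def se_from_ci(low: float, high: float, level: float = 0.95) -> float:
    """Recover a standard error from a symmetric normal confidence interval."""
    if not low < high:
        raise ValueError("require low < high")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    z = norm.ppf(0.5 + level / 2.0)
    return (high - low) / (2.0 * z)


def difference_test(
    est1: float, se1: float, est2: float, se2: float
) -> tuple[float, float]:
    """z and two-sided p for the difference of two independent estimates."""
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    z = (est1 - est2) / math.sqrt(se1**2 + se2**2)
    return float(z), _p_from_z(z)


def subgroup_difference_test(res1: MRResult, res2: MRResult) -> tuple[float, float]:
    """Difference test between two MR results on a common scale.

    Used for sex differences; when applied to conditional-vs-original
    estimates note the two share an outcome sample, so the independent-z
    p-value is conservative only in direction, not calibrated.
    """
    if res1.scale != res2.scale:
        raise ValueError("subgroup estimates must share a scale")
    e1, s1 = res1.estimation_scale()
    e2, s2 = res2.estimation_scale()
    return difference_test(e1, s1, e2, s2)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise error control: per-test threshold ``alpha / m``."""
    if m < 1:
        raise ValueError("m must be at least 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / m


# --------------------------------------------------------------------------
# analysis battery
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class StratumSpec:
    """A named restriction of the analysis sample for one outcome."""

    name: str
    outcome: str
    query: str  # pandas query string, e.g. "tea == 0"


def _default_strata() -> tuple[StratumSpec, ...]:
    return (
        StratumSpec("non_tea_drinkers", "coffee", "tea == 0"),
        StratumSpec("non_coffee_drinkers", "tea", "coffee == 0"),
    )


@dataclass(frozen=True)
class AnalysisPlan:
    """Which MR cells to compute over a harmonized cohort.

    Continuous outcomes are ``coffee``/``tea`` (cups/day) and
    ``alcohol_freq_month`` (occasions/month); binary contrasts use the
    ``{beverage}_drinker_status`` columns. The test family for the
    Bonferroni flag is fixed at the main battery's 3 stimuli x 3
    beverages; subgroup cells are exploratory.
    """

    outcomes: tuple[str, ...] = ("coffee", "tea", "alcohol_freq_month")
    covariates: tuple[str, ...] = ("age", "sex") + tuple(f"pc{i}" for i in range(1, 11))
    binary_contrasts: bool = True
    conditional_pairs: tuple[tuple[str, str], ...] = (
        ("coffee", "tea"),
        ("tea", "coffee"),
    )
    strata: tuple[StratumSpec, ...] = field(default_factory=_default_strata)
    by_sex: bool = True
    alpha: float = 0.05
    n_tests: int = 9
    se_mode: str = "full_delta"


def run_mr_battery(
    cohort: pd.DataFrame,
    instruments: list[GeneticInstrument],
    plan: AnalysisPlan = AnalysisPlan(),
) -> tuple[list[MRResult], list[AssociationResult]]:
    """Run the full MR analysis grid on a harmonized cohort.

    Emits one :class:`MRResult` per (stimulus x outcome x analysis cell):
    main linear, binary drinker-status contrasts, conditional (other
    beverage as covariate), named strata, and by-sex analyses. Main
    linear results are flagged against the Bonferroni threshold
    ``alpha / n_tests``; cells that fail estimation (e.g. an empty
    stratum) are skipped with a warning. The underlying association fits
    are returned alongside.
    """
    threshold = bonferroni_threshold(plan.alpha, plan.n_tests)
    stim_of = {i.stimulus: i for i in instruments}
    mr_results: list[MRResult] = []
    assoc_results: list[AssociationResult] = []

    def add_linear(instrument, outcome, analysis, **kwargs):
        try:
            a = fit_linear_snp_assoc(
                cohort,
                f"{instrument.stimulus}_dosage",
                outcome,
                covariates=kwargs.pop("covariates", plan.covariates),
                snp_id=instrument.snp,
                **kwargs,
            )
        except EstimationError as exc:
            warnings.warn(f"skipping {analysis} {instrument.stimulus}->{outcome}: {exc}")
            return
        assoc_results.append(a)
        res = replace(
            wald_ratio(a, instrument, plan.se_mode),
            analysis=analysis,
        )
        if analysis == "main":
            res = replace(res, significant=res.p < threshold)
        mr_results.append(res)

    for stim in STIMULI:
        if stim not in stim_of:
            continue
        inst = stim_of[stim]
        for outcome in plan.outcomes:
            add_linear(inst, outcome, "main")
        if plan.binary_contrasts:
            for bev in BEVERAGES:
                col = f"{bev}_drinker_status"
                if col not in cohort.columns:
                    continue
                try:
                    a = fit_logistic_snp_assoc(
                        cohort,
                        f"{stim}_dosage",
                        col,
                        covariates=plan.covariates,
                        snp_id=inst.snp,
                    )
                except EstimationError as exc:
                    warnings.warn(f"skipping binary {stim}->{bev}: {exc}")
                    continue
                assoc_results.append(a)
                mr_results.append(
                    replace(causal_or(a, inst, plan.se_mode), analysis="binary")
                )
        for outcome, other in plan.conditional_pairs:
            add_linear(inst, outcome, "conditional", condition_on=other)
        for spec in plan.strata:
            add_linear(
                inst,
                spec.outcome,
                "stratified",
                stratum_query=spec.query,
                stratum=spec.name,
            )
        if plan.by_sex:
            covs = tuple(c for c in plan.covariates if c != "sex")
            for label, query in (("female", "sex == 0"), ("male", "sex == 1")):
                for outcome in plan.outcomes:
                    add_linear(
                        inst,
                        outcome,
                        "by_sex",
                        stratum_query=query,
                        stratum=label,
                        covariates=covs,
                    )
    return mr_results, assoc_results


def sex_difference_tests(results: list[MRResult]) -> pd.DataFrame:
    """z-tests comparing female vs male MR estimates per stimulus x outcome."""
    by_sex = [r for r in results if r.analysis == "by_sex"]
    rows = []
    keys = sorted({(r.stimulus, r.outcome) for r in by_sex})
    for stim, outcome in keys:
        female = [r for r in by_sex if (r.stimulus, r.outcome) == (stim, outcome) and r.stratum == "female"]
        male = [r for r in by_sex if (r.stimulus, r.outcome) == (stim, outcome) and r.stratum == "male"]
        if not (female and male):
            continue
        z, p = subgroup_difference_test(female[0], male[0])
        rows.append(
            {
                "stimulus": stim,
                "outcome": outcome,
                "estimate_female": female[0].estimate,
                "estimate_male": male[0].estimate,
                "z": z,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def mr_table(results: list[MRResult]) -> pd.DataFrame:
    """Tabulate MR results in a forest-plot-ready layout."""
    rows = []
    for r in results:
        rows.append(
            {
                "analysis": r.analysis,
                "stimulus": r.stimulus,
                "outcome": r.outcome,
                "scale": r.scale,
                "estimate": r.estimate,
                "se": r.se,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p": r.p,
                "stratum": r.stratum or "",
                "n": r.n if r.n is not None else "",
                "significant": "" if r.significant is None else bool(r.significant),
            }
        )
    return pd.DataFrame(rows)
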