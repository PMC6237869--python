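"""Per-allele SNP-phenotype association fits.

Ordinary least squares for continuous beverage outcomes and
maximum-likelihood logistic regression for drinker-status contrasts,
with covariate adjustment (age, sex, ancestry PCs by default),
complete-case missing-data handling, optional conditioning on a second
beverage and optional stratum restriction. Also the first-order
conversion from a linear slope on a binary indicator to a log odds
ratio, beta / (mu(1-mu)), used to harmonize linear mixed-model output
with logistic effect sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .phenotypes import HEAVY, LIGHT

__all__ = [
    "AssociationResult",
    "EstimationError",
    "fit_linear_snp_assoc",
    "fit_logistic_snp_assoc",
    "linear_to_logOR",
    "fit_taste_instruments",
    "association_table",
]

DEFAULT_COVARIATES = ("age", "sex") + tuple(f"pc{i}" for i in range(1, 11))


class EstimationError(RuntimeError):
    """Raised when an association model cannot be estimated."""


@dataclass(frozen=True)
class AssociationResult:
    """One per-effect-allele SNP-phenotype estimate.

    ``beta`` is the change in the phenotype per copy of the effect allele
    (log-odds for ``model='logistic'`` / ``'linear_approx_logOR'``).
    ``ci_low``/``ci_high`` may carry externally supplied (e.g. published)
    interval bounds; when absent, :meth:`ci` returns the +/-1.96 SE Wald
    interval.
    """

    snp: str
    phenotype: str
    beta: float
    se: float
    n: int
    model: str  # linear | logistic | linear_approx_logOR
    covariates: tuple[str, ...] = ()
    condition_on: str | None = None
    stratum: str | None = None
    ci_low: float | None = None
    ci_high: float | None = None

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("standard error must be positive")
        if self.model not in ("linear", "logistic", "linear_approx_logOR"):
            raise ValueError(f"unknown model {self.model!r}")

    def ci(self, z: float = 1.959963984540054) -> tuple[float, float]:
        if self.ci_low is not None and self.ci_high is not None:
            return self.ci_low, self.ci_high
        return self.beta - z * self.se, self.beta + z * self.se


def _design(
    table: pd.DataFrame,
    snp: str,
    outcome: str,
    covariates: tuple[str, ...],
    condition_on: str | None,
    stratum_query: str | None,
):
    cols = [snp, outcome, *covariates]
    if condition_on:
        cols.append(condition_on)
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise EstimationError(f"cohort table lacks column(s): {missing}")
    sub = table.query(stratum_query) if stratum_query else table
    sub = sub[cols].apply(pd.to_numeric, errors="coerce").dropna()
    if len(sub) < 50:
        raise EstimationError(
            f"only {len(sub)} usable rows for {snp} -> {outcome}; need >= 50"
        )
    if sub[snp].nunique() < 2:
        raise EstimationError(f"dosage column {snp!r} is constant in this stratum")
    regressors = [snp] + ([condition_on] if condition_on else []) + list(covariates)
    X = sm.add_constant(sub[regressors], has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify an offending column by greedy removal
        for col in regressors:
            reduced = X.drop(columns=[col])
            if np.linalg.matrix_rank(reduced.to_numpy()) == rank:
                raise EstimationError(f"design is collinear; column {col!r} is redundant")
        raise EstimationError("design matrix is rank deficient")
    return sub, X


def fit_linear_snp_assoc(
    table: pd.DataFrame,
    snp: str,
    phenotype: str,
    covariates: tuple[str, ...] = (),
    condition_on: str | None = None,
    stratum_query: str | None = None,
    stratum: str | None = None,
    snp_id: str | None = None,
) -> AssociationResult:
    """OLS slope of ``phenotype`` on effect-allele dosage.

    Covariates (and the conditioning phenotype, if any) enter as
    additional regressors; rows with any missing regressor or outcome are
    dropped (complete case). ``stratum_query`` is a pandas query string
    restricting the analysis sample, with ``stratum`` as its label in the
    result.
    """
    sub, X = _design(table, snp, phenotype, covariates, condition_on, stratum_query)
    fit = sm.OLS(sub[phenotype].to_numpy(), X).fit()
    return AssociationResult(
        snp=snp_id or snp,
        phenotype=phenotype,
        beta=float(fit.params[snp]),
        se=float(fit.bse[snp]),
        n=int(len(sub)),
        model="linear",
        covariates=tuple(covariates),
        condition_on=condition_on,
        stratum=stratum,
    )


def fit_logistic_snp_assoc(
    table: pd.DataFrame,
    snp: str,
    status_col: str,
    covariates: tuple[str, ...] = (),
    contrast: tuple[str, str] = (LIGHT, HEAVY),
    stratum_query: str | None = None,
    stratum: str | None = None,
    snp_id: str | None = None,
    min_cases: int = 25,
) -> AssociationResult:
    """Logistic per-allele log-OR for a drinker-status contrast.

    ``contrast`` names the (control, case) labels; intermediates and
    missing statuses are excluded. Newton-Raphson to a relative
    log-likelihood tolerance of 1e-8, at most 100 iterations; SEs from
    the observed information.
    """
    if status_col not in table.columns:
        raise EstimationError(f"cohort table lacks status column {status_col!r}")
    control, case = contrast
    sub = table[table[status_col].isin([control, case])].copy()
    outcome = "_case"
    sub[outcome] = (sub[status_col] == case).astype(float)
    sub, X = _design(sub, snp, outcome, covariates, None, stratum_query)
    n_case = int(sub[outcome].sum())
    n_ctrl = int(len(sub) - n_case)
    if min(n_case, n_ctrl) < min_cases:
        raise EstimationError(
            f"contrast {contrast} has {n_case} cases / {n_ctrl} controls; "
            f"need >= {min_cases} of each"
        )
    try:
        fit = sm.Logit(sub[outcome].to_numpy(), X).fit(
            method="newton", maxiter=100, tol=1e-8, disp=False
        )
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise EstimationError(
            f"logistic fit failed ({exc}); the classes may be separable - "
            "a larger sample usually resolves this"
        ) from exc
    se = float(fit.bse[snp])
    if not np.isfinite(se) or se <= 0:
        raise EstimationError(
            "logistic fit did not yield a finite standard error; the classes "
            "may be separable - a larger sample usually resolves this"
        )
    return AssociationResult(
        snp=snp_id or snp,
        phenotype=status_col,
        beta=float(fit.params[snp]),
        se=se,
        n=int(len(sub)),
        model="logistic",
        covariates=tuple(covariates),
        stratum=stratum,
    )


def linear_to_logOR(beta_linear: float, case_fraction: float) -> float:
    """First-order conversion of a linear slope on a 0/1 indicator to a
    log odds ratio: ``beta / (mu (1 - mu))`` with ``mu`` the case
    fraction.

    Accurate for small effects (relative error under ~10% for
    \\|log OR\\| < 0.3); used to put linear mixed-model output for binary
    traits on the logistic scale.
    """
    if not 0.0 < case_fraction < 1.0:
        raise ValueError(f"case_fraction must lie in (0, 1), got {case_fraction}")
    return beta_linear / (case_fraction * (1.0 - case_fraction))


def fit_taste_instruments(sample1: pd.DataFrame):
    """Estimate the three taste instruments from a discovery cohort.

    Regresses each standardized intensity rating on its SNP's dosage
    (simple regression, matching a covariate-free GWAS of standardized
    ratings) and packages the estimates as
    :class:`~bittermr.mr.GeneticInstrument` objects.
    """
    from .mr import GeneticInstrument  # local import to avoid a cycle
    from .synth_cohort import EFFECT_ALLELES, SNP_IDS, STIMULI

    instruments = []
    for stim in STIMULI:
        res = fit_linear_snp_assoc(
            sample1, f"{stim}_dosage", f"{stim}_intensity_sd", snp_id=SNP_IDS[stim]
        )
        fit_r2 = _simple_r2(
            sample1[f"{stim}_dosage"].to_numpy(dtype=float),
            sample1[f"{stim}_intensity_sd"].to_numpy(dtype=float),
        )
        instruments.append(
            GeneticInstrument(
                snp=SNP_IDS[stim],
                effect_allele=EFFECT_ALLELES[stim],
                stimulus=stim,
                beta=res.beta,
                se=res.se,
                variance_explained=fit_r2,
                n=res.n,
            )
        )
    return instruments


def _simple_r2(x: np.ndarray, y: np.ndarray) -> float:
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def association_table(results) -> pd.DataFrame:
    """Tabulate :class:`AssociationResult` objects (tab-separated friendly)."""
    rows = []
    for r in results:
        rows.append(
            {
                "snp": r.snp,
                "phenotype": r.phenotype,
                "model": r.model,
                "beta": r.beta,
                "se": r.se,
                "n": r.n,
                "covariates": ",".join(r.covariates),
                "condition_on": r.condition_on or "",
                "stratum": r.stratum or "",
            }
        )
    return pd.DataFrame(rows)
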