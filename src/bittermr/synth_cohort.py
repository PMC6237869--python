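"""Synthetic two-sample cohorts for bitter-taste Mendelian randomization.

Two linked datasets are generated with the statistical structure a
single-instrument MR analysis assumes:

* **sample 1** — a taste-GWAS discovery cohort in which square-root
  transformed, standardized intensity ratings for PROP, quinine and
  caffeine are each driven by one biallelic SNP under an additive model;
* **sample 2** — a biobank-style consumption cohort in which the only
  path from genotype to beverage intake runs through the latent
  perception score times a configurable causal effect, so the exclusion
  restriction holds by construction (a direct-effect switch can break it
  for robustness experiments).

Beverage phenotypes are rounded, zero-truncated draws from latent
Gaussians whose location/scale are solved numerically so the *observed*
(post-truncation) mean and SD hit the configured targets, and whose
latent correlation is solved (second-order Hermite expansion) so the
*observed* coffee–tea correlation hits its target.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import norm

__all__ = [
    "STIMULI",
    "BEVERAGES",
    "SNP_IDS",
    "EFFECT_ALLELES",
    "ALCOHOL_LEVELS",
    "ALCOHOL_MONTHLY_FREQ",
    "PREFER_NOT_TO_ANSWER",
    "LATENT_SCORE_COLUMNS",
    "InstrumentSpec",
    "CovariateEffects",
    "BeverageTargets",
    "SimulationConfig",
    "ConfigurationError",
    "solve_allele_frequency",
    "censored_round_moments",
    "solve_latent_moments",
    "solve_latent_correlation",
    "simulate_sample1",
    "simulate_sample2",
    "export_cohort",
    "read_cohort_table",
]

STIMULI = ("prop", "quinine", "caffeine")
BEVERAGES = ("coffee", "tea", "alcohol")

#: rsIDs of the bitter-taste instruments (TAS2R38 for PROP; the chromosome-12
#: bitter-receptor cluster for quinine and caffeine).
SNP_IDS = {"prop": "rs1726866", "quinine": "rs10772420", "caffeine": "rs2597979"}
#: Allele oriented to increase perceived bitterness.
EFFECT_ALLELES = {"prop": "G", "quinine": "A", "caffeine": "G"}

#: Ordered 6-level alcohol-frequency questionnaire vocabulary.
ALCOHOL_LEVELS = (
    "Never",
    "Special occasions only",
    "1-3 times a month",
    "1-2 times a week",
    "3-4 times a week",
    "Daily or almost daily",
)
#: Monthly drinking frequency assigned to each level by the harmonization step.
ALCOHOL_MONTHLY_FREQ = (0.0, 1.0, 2.0, 6.0, 15.0, 30.0)
PREFER_NOT_TO_ANSWER = "Prefer not to answer"

#: Oracle-only columns: latent perception scores retained for parameter
#: recovery tests, never available in real questionnaire data.
LATENT_SCORE_COLUMNS = tuple(f"{s}_score" for s in STIMULI)


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class InstrumentSpec:
    """Generating truth for one taste SNP.

    Parameters
    ----------
    effect_sd
        Per-effect-allele shift of the transformed intensity rating, in SD
        units of the rating.
    variance_explained
        Target R^2 of dosage on the transformed rating.
    allele_freq
        Effect-allele frequency. ``None`` (default) solves the frequency
        from the other two fields via ``2p(1-p) * effect_sd^2 =
        variance_explained``, taking the root in ``(0, 0.5]``.
    """

    effect_sd: float
    variance_explained: float
    allele_freq: float | None = None


@dataclass(frozen=True)
class CovariateEffects:
    """Additive covariate effects on one beverage's latent scale."""

    sex: float = 0.0  # added for males (sex == 1), phenotype units
    age: float = 0.0  # per SD of age
    pcs: tuple[float, ...] = ()  # per ancestry PC, phenotype units


@dataclass(frozen=True)
class BeverageTargets:
    """Observed-scale calibration targets for a cups/day beverage."""

    mean: float
    sd: float


def _default_instruments() -> dict[str, InstrumentSpec]:
    # Quinine's target is capped just below the biallelic-SNP bound
    # 0.5 * 0.337^2 = 0.0568; see docs/methods.md.
    return {
        "prop": InstrumentSpec(0.965, 0.46),
        "quinine": InstrumentSpec(0.337, 0.055),
        "caffeine": InstrumentSpec(0.264, 0.02),
    }


def _default_causal_effects() -> dict[str, dict[str, float]]:
    # Beverage change per SD of perceived bitterness (cups/day for coffee
    # and tea; drinking occasions/month for alcohol).
    return {
        "coffee": {"prop": -0.021, "quinine": -0.081, "caffeine": 0.146},
        "tea": {"prop": 0.0352, "quinine": 0.0831, "caffeine": -0.1705},
        "alcohol": {"prop": -0.136, "quinine": 0.03, "caffeine": -0.047},
    }


def _zero_effects() -> dict[str, dict[str, float]]:
    return {b: {s: 0.0 for s in STIMULI} for b in BEVERAGES}


def _default_covariate_effects() -> dict[str, CovariateEffects]:
    return {
        "coffee": CovariateEffects(sex=0.25, age=-0.05),
        "tea": CovariateEffects(sex=-0.15, age=0.10),
        "alcohol": CovariateEffects(sex=2.0, age=0.0),
    }


@dataclass(frozen=True)
class SimulationConfig:
    """All generator parameters for the linked two-sample simulation.

    One seed drives everything; per-cohort sub-streams are spawned
    deterministically from it, so identical configs give bit-identical
    cohorts.
    """

    seed: int = 0
    n_sample1: int = 1757
    n_sample2: int = 50_000
    instruments: dict[str, InstrumentSpec] = field(default_factory=_default_instruments)
    #: beverage -> stimulus -> effect per SD of perception.
    causal_effects: dict[str, dict[str, float]] = field(default_factory=_default_causal_effects)
    #: beverage -> stimulus -> direct per-allele effect bypassing perception
    #: (exclusion-restriction violation switch; zero by default).
    direct_snp_effects: dict[str, dict[str, float]] = field(default_factory=_zero_effects)
    beverage_targets: dict[str, BeverageTargets] = field(
        default_factory=lambda: {
            "coffee": BeverageTargets(2.13, 2.1),
            "tea": BeverageTargets(3.51, 2.9),
        }
    )
    #: target *observed* Pearson correlation between coffee and tea.
    coffee_tea_correlation: float = -0.3
    alcohol_probs: tuple[float, ...] = (0.081, 0.114, 0.116, 0.253, 0.237, 0.199)
    covariate_effects: dict[str, CovariateEffects] = field(
        default_factory=_default_covariate_effects
    )
    age_mean: float = 56.5
    age_sd: float = 8.1
    male_fraction: float = 0.458
    n_pcs: int = 10
    #: fraction of sample 2 answering "Prefer not to answer" on alcohol.
    prefer_not_rate: float = 0.0
    #: "rounded" gives questionnaire-style integer, zero-truncated cups/day;
    #: "latent" emits the underlying Gaussian value (useful when the
    #: estimand must equal the configured causal effect exactly).
    beverage_output_scale: str = "rounded"
    #: location/scale of sample 1's raw rating on the square-root scale.
    rating_sqrt_location: float = 6.0
    rating_sqrt_scale: float = 1.5

    def __post_init__(self) -> None:
        self.validate()

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        if self.n_sample1 < 10 or self.n_sample2 < 10:
            raise ConfigurationError("sample sizes must be at least 10")
        if self.beverage_output_scale not in ("rounded", "latent"):
            raise ConfigurationError(
                f"beverage_output_scale must be 'rounded' or 'latent', "
                f"got {self.beverage_output_scale!r}"
            )
        if not 0.0 < self.male_fraction < 1.0:
            raise ConfigurationError("male_fraction must lie in (0, 1)")
        if self.age_sd <= 0:
            raise ConfigurationError("age_sd must be positive")
        if not 0.0 <= self.prefer_not_rate < 1.0:
            raise ConfigurationError("prefer_not_rate must lie in [0, 1)")
        if len(self.alcohol_probs) != len(ALCOHOL_LEVELS):
            raise ConfigurationError(
                f"alcohol_probs needs {len(ALCOHOL_LEVELS)} entries"
            )
        if any(p < 0 for p in self.alcohol_probs):
            raise ConfigurationError("alcohol_probs must be non-negative")
        if abs(sum(self.alcohol_probs) - 1.0) > 1e-9:
            raise ConfigurationError("alcohol_probs must sum to 1 within 1e-9")
        if not -1.0 < self.coffee_tea_correlation < 1.0:
            raise ConfigurationError("coffee_tea_correlation must lie in (-1, 1)")
        for bev, tgt in self.beverage_targets.items():
            if tgt.sd <= 0:
                raise ConfigurationError(f"{bev}: target SD must be positive")
            if tgt.mean < 0:
                raise ConfigurationError(f"{bev}: target mean must be non-negative")
        for stim in STIMULI:
            if stim not in self.instruments:
                raise ConfigurationError(f"missing instrument spec for {stim!r}")
            spec = self.instruments[stim]
            if not 0.0 <= spec.variance_explained < 1.0:
                raise ConfigurationError(
                    f"{stim}: variance_explained must lie in [0, 1)"
                )
            if spec.allele_freq is not None and not 0.0 < spec.allele_freq < 1.0:
                raise ConfigurationError(f"{stim}: allele_freq must lie in (0, 1)")
            if spec.allele_freq is None and (
                spec.variance_explained == 0.0 or spec.effect_sd == 0.0
            ):
                raise ConfigurationError(
                    f"{stim}: a null instrument needs an explicit allele_freq"
                )
            # raises ConfigurationError if infeasible
            self.frequency(stim)

    # -- derived quantities ------------------------------------------------
    def frequency(self, stimulus: str) -> float:
        """Effect-allele frequency, solved from the spec when not given."""
        spec = self.instruments[stimulus]
        if spec.allele_freq is not None:
            return spec.allele_freq
        return solve_allele_frequency(
            spec.effect_sd, spec.variance_explained, stimulus=stimulus
        )

    def to_dict(self) -> dict:
        return _as_plain(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "instruments" in d:
            d["instruments"] = {
                k: InstrumentSpec(**v) if isinstance(v, dict) else v
                for k, v in d["instruments"].items()
            }
        if "beverage_targets" in d:
            d["beverage_targets"] = {
                k: BeverageTargets(**v) if isinstance(v, dict) else v
                for k, v in d["beverage_targets"].items()
            }
        if "covariate_effects" in d:
            d["covariate_effects"] = {
                k: CovariateEffects(**{**v, "pcs": tuple(v.get("pcs", ()))})
                if isinstance(v, dict)
                else v
                for k, v in d["covariate_effects"].items()
            }
        if "alcohol_probs" in d:
            d["alcohol_probs"] = tuple(d["alcohol_probs"])
        return cls(**d)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _as_plain(obj):
    if isinstance(obj, dict):
        return {k: _as_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


# --------------------------------------------------------------------------
# calibration helpers
# --------------------------------------------------------------------------


def solve_allele_frequency(
    effect_sd: float, variance_explained: float, stimulus: str = "?"
) -> float:
    """Solve ``2p(1-p) * effect_sd^2 = variance_explained`` for ``p``.

    The root in ``(0, 0.5]`` is returned (the mirror-image frequency
    ``1-p`` yields the same dosage variance). Raises
    :class:`ConfigurationError` when the target exceeds the maximum
    attainable ``0.5 * effect_sd^2``.
    """
    if effect_sd == 0:
        raise ConfigurationError(
            f"{stimulus}: cannot solve allele frequency for a zero effect"
        )
    two_pq = variance_explained / effect_sd**2
    if two_pq > 0.5:
        raise ConfigurationError(
            f"{stimulus}: no real allele frequency gives variance explained "
            f"{variance_explained} at effect {effect_sd} SD/allele "
            f"(requires 2p(1-p) = {two_pq:.4f} > 0.5)"
        )
    # p(1-p) = two_pq/2  ->  p = (1 - sqrt(1 - 2*two_pq)) / 2
    return (1.0 - math.sqrt(1.0 - 2.0 * two_pq)) / 2.0


def censored_round_moments(
    mu: float, sigma: float, kmax: int | None = None
) -> tuple[float, float]:
    """Mean and SD of ``max(round(X), 0)`` for ``X ~ N(mu, sigma^2)``."""
    if kmax is None:
        kmax = max(10, int(math.ceil(mu + 10 * sigma)))
    k = np.arange(1, kmax + 1)
    pk = norm.cdf((k + 0.5 - mu) / sigma) - norm.cdf((k - 0.5 - mu) / sigma)
    m1 = float(np.sum(k * pk))
    m2 = float(np.sum(k**2 * pk))
    return m1, math.sqrt(max(m2 - m1**2, 0.0))


def _hermite_coeffs(mu: float, sigma: float) -> tuple[float, float, float]:
    """First two Hermite coefficients (scaled by SD) of the round-clip map.

    For ``Y = max(round(mu + sigma Z), 0)`` returns ``(sd_Y, c1, c2)`` with
    ``c1 = E[Y Z] / sd_Y`` and ``c2 = E[Y (Z^2-1)] / (sqrt(2) sd_Y)``, the
    coefficients that govern how a latent Gaussian correlation propagates
    to the observed scale.
    """
    kmax = max(10, int(math.ceil(mu + 10 * sigma)))
    k = np.arange(1, kmax + 1)
    a = (k - 0.5 - mu) / sigma
    b = (k + 0.5 - mu) / sigma
    eyz = float(np.sum(k * (norm.pdf(a) - norm.pdf(b))))
    # E[1{a<Z<b}(Z^2-1)] = [-(z phi(z))]_a^b
    eyz2 = float(np.sum(k * (a * norm.pdf(a) - b * norm.pdf(b))))
    _, sd = censored_round_moments(mu, sigma, kmax)
    return sd, eyz / sd, eyz2 / (math.sqrt(2.0) * sd)


def solve_latent_moments(target_mean: float, target_sd: float) -> tuple[float, float]:
    """Latent ``(mu, sigma)`` whose round-clip moments match the targets."""
    def resid(x):
        m, s = censored_round_moments(x[0], x[1])
        return [m - target_mean, s - target_sd]

    sol = optimize.root(resid, [target_mean, target_sd])
    if not sol.success:  # pragma: no cover - targets are validated upstream
        raise ConfigurationError(
            f"cannot calibrate latent moments for mean={target_mean}, sd={target_sd}"
        )
    mu, sigma = float(sol.x[0]), float(sol.x[1])
    if sigma <= 0:
        raise ConfigurationError(
            f"infeasible marginal targets mean={target_mean}, sd={target_sd}"
        )
    return mu, sigma


def solve_latent_correlation(
    target_r: float,
    mu1: float,
    sigma1: float,
    mu2: float,
    sigma2: float,
) -> float:
    """Latent Gaussian correlation whose observed round-clip correlation is
    ``target_r``.

    Uses the two-term Hermite expansion
    ``r_obs = rho c1 c1' + rho^2 c2 c2'`` and solves the quadratic for
    ``rho``; residual third-order error is below ~0.005 for the beverage
    calibrations used here.
    """
    _, c11, c12 = _hermite_coeffs(mu1, sigma1)
    _, c21, c22 = _hermite_coeffs(mu2, sigma2)
    a, b = c12 * c22, c11 * c21
    if abs(a) < 1e-12:
        rho = target_r / b
    else:
        disc = b * b + 4.0 * a * target_r
        if disc < 0:
            raise ConfigurationError(
                f"observed correlation {target_r} is unattainable after rounding"
            )
        roots = ((-b + math.sqrt(disc)) / (2 * a), (-b - math.sqrt(disc)) / (2 * a))
        # take the root continuous with the linear solution
        rho = min(roots, key=lambda r: abs(r - target_r / b))
    if not -1.0 < rho < 1.0:
        raise ConfigurationError(
            f"observed correlation {target_r} maps to latent correlation "
            f"{rho:.3f} outside (-1, 1)"
        )
    return rho


# --------------------------------------------------------------------------
# sample 1: taste-GWAS discovery cohort
# --------------------------------------------------------------------------


def _spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _draw_genotypes(rng: np.random.Generator, n: int, p: float) -> np.ndarray:
    return rng.binomial(2, p, size=n)


def _perception_scores(
    rng: np.random.Generator, dosage: np.ndarray, spec: InstrumentSpec, p: float
) -> np.ndarray:
    """Population-standardized latent perception: mean 0, variance 1."""
    beta = spec.effect_sd
    resid_var = 1.0 - 2.0 * p * (1.0 - p) * beta**2
    if resid_var < 0:  # caught earlier by validate(); belt and braces
        raise ConfigurationError("instrument effect explains more than total variance")
    return beta * (dosage - 2.0 * p) + rng.normal(0.0, math.sqrt(resid_var), dosage.size)


def simulate_sample1(config: SimulationConfig) -> pd.DataFrame:
    """Generate the taste-GWAS discovery cohort (sample 1).

    Each stimulus gets one SNP and one intensity rating. Ratings live on a
    raw non-negative scale constructed so the square-root transform is
    exact: a latent normal on the sqrt scale (floored at 0, which is a
    ~3e-5 tail event at the default location) is squared to give the raw
    rating. Columns:

    ``iid``, ``{stim}_dosage`` (effect-allele dosage), ``{stim}_rating``
    (raw), ``{stim}_intensity_sd`` (square-root transformed then
    empirically standardized, as the discovery GWAS did).
    """
    rng = _spawn_rngs(config.seed, 2)[0]
    n = config.n_sample1
    cols: dict[str, np.ndarray] = {"iid": np.array([f"S1_{i:06d}" for i in range(n)])}
    for stim in STIMULI:
        spec = config.instruments[stim]
        p = config.frequency(stim)
        g = _draw_genotypes(rng, n, p)
        score = _perception_scores(rng, g, spec, p)
        sqrt_scale = config.rating_sqrt_location + config.rating_sqrt_scale * score
        sqrt_scale = np.maximum(sqrt_scale, 0.0)
        raw = sqrt_scale**2
        transformed = np.sqrt(raw)
        transformed = (transformed - transformed.mean()) / transformed.std(ddof=0)
        cols[f"{stim}_dosage"] = g
        cols[f"{stim}_rating"] = raw
        cols[f"{stim}_intensity_sd"] = transformed
    return pd.DataFrame(cols)


# --------------------------------------------------------------------------
# sample 2: biobank-style consumption cohort
# --------------------------------------------------------------------------


def _alcohol_latent_sd(probs: tuple[float, ...]) -> float:
    v = np.asarray(ALCOHOL_MONTHLY_FREQ)
    p = np.asarray(probs)
    m = float(np.sum(p * v))
    return math.sqrt(float(np.sum(p * v**2)) - m * m)


def _structural_cov(
    config: SimulationConfig, bev1: str, bev2: str
) -> float:
    """Covariance between the structural (genotype + covariate) parts of two
    beverages' latent scales; ``bev1 == bev2`` gives the variance."""
    total = 0.0
    for stim in STIMULI:
        spec = config.instruments[stim]
        p = config.frequency(stim)
        two_pq = 2.0 * p * (1.0 - p)
        t1 = config.causal_effects[bev1][stim]
        t2 = config.causal_effects[bev2][stim]
        d1 = config.direct_snp_effects[bev1][stim]
        d2 = config.direct_snp_effects[bev2][stim]
        # var(score)=1; cov(score, dosage) = beta * 2pq; var(dosage) = 2pq
        total += (
            t1 * t2
            + (t1 * d2 + t2 * d1) * spec.effect_sd * two_pq
            + d1 * d2 * two_pq
        )
    c1 = config.covariate_effects.get(bev1, CovariateEffects())
    c2 = config.covariate_effects.get(bev2, CovariateEffects())
    total += c1.sex * c2.sex * config.male_fraction * (1.0 - config.male_fraction)
    total += c1.age * c2.age  # age effects are per SD of age
    for e1, e2 in zip(c1.pcs, c2.pcs):
        total += e1 * e2
    return total


def _structural_part(
    config: SimulationConfig,
    bev: str,
    scores: dict[str, np.ndarray],
    dosages: dict[str, np.ndarray],
    age_z: np.ndarray,
    sex: np.ndarray,
    pcs: np.ndarray,
) -> np.ndarray:
    s = np.zeros_like(age_z)
    for stim in STIMULI:
        p = config.frequency(stim)
        s += config.causal_effects[bev][stim] * scores[stim]
        s += config.direct_snp_effects[bev][stim] * (dosages[stim] - 2.0 * p)
    eff = config.covariate_effects.get(bev, CovariateEffects())
    s += eff.sex * (sex - config.male_fraction)
    s += eff.age * age_z
    for j, e in enumerate(eff.pcs):
        s += e * pcs[:, j]
    return s


def simulate_sample2(config: SimulationConfig) -> pd.DataFrame:
    """Generate the biobank-style consumption cohort (sample 2).

    Genotype reaches the beverages only through the latent perception
    scores (unless ``direct_snp_effects`` is switched on), so the
    instrumental-variable exclusion restriction holds by construction.
    Coffee and tea are rounded, zero-truncated Gaussians calibrated so
    their observed mean/SD and mutual correlation match the configured
    targets; alcohol is an ordered 6-category draw whose latent scale
    carries the configured causal effects in occasions/month units.

    Oracle-only columns ``{stim}_score`` hold the latent perception
    scores; :func:`export_cohort` drops them unless asked not to.
    """
    rng = _spawn_rngs(config.seed, 2)[1]
    n = config.n_sample2

    dosages, scores = {}, {}
    for stim in STIMULI:
        spec = config.instruments[stim]
        p = config.frequency(stim)
        g = _draw_genotypes(rng, n, p)
        dosages[stim] = g
        scores[stim] = _perception_scores(rng, g, spec, p)

    age = rng.normal(config.age_mean, config.age_sd, n)
    age_z = (age - config.age_mean) / config.age_sd
    sex = rng.binomial(1, config.male_fraction, n)
    pcs = rng.normal(0.0, 1.0, (n, config.n_pcs))

    # latent calibration for coffee and tea
    latent: dict[str, tuple[float, float]] = {}
    for bev in ("coffee", "tea"):
        tgt = config.beverage_targets[bev]
        if config.beverage_output_scale == "rounded":
            latent[bev] = solve_latent_moments(tgt.mean, tgt.sd)
        else:
            latent[bev] = (tgt.mean, tgt.sd)

    if config.beverage_output_scale == "rounded":
        rho_lat = solve_latent_correlation(
            config.coffee_tea_correlation, *latent["coffee"], *latent["tea"]
        )
    else:
        rho_lat = config.coffee_tea_correlation

    s_coffee = _structural_part(config, "coffee", scores, dosages, age_z, sex, pcs)
    s_tea = _structural_part(config, "tea", scores, dosages, age_z, sex, pcs)
    v_c = _structural_cov(config, "coffee", "coffee")
    v_t = _structural_cov(config, "tea", "tea")
    cov_ct = _structural_cov(config, "coffee", "tea")

    sig_c, sig_t = latent["coffee"][1], latent["tea"][1]
    res_var_c = sig_c**2 - v_c
    res_var_t = sig_t**2 - v_t
    if res_var_c <= 0 or res_var_t <= 0:
        raise ConfigurationError(
            "structural effects exceed the latent beverage variance; "
            "reduce causal/covariate effects or raise the target SD"
        )
    res_cov = rho_lat * sig_c * sig_t - cov_ct
    res_rho = res_cov / math.sqrt(res_var_c * res_var_t)
    if not -1.0 < res_rho < 1.0:
        raise ConfigurationError(
            "coffee-tea correlation target is infeasible given the structural effects"
        )
    e = rng.multivariate_normal(
        [0.0, 0.0],
        [[res_var_c, res_cov], [res_cov, res_var_t]],
        size=n,
        method="cholesky",
    )
    x_coffee = latent["coffee"][0] + s_coffee + e[:, 0]
    x_tea = latent["tea"][0] + s_tea + e[:, 1]
    if config.beverage_output_scale == "rounded":
        coffee = np.clip(np.round(x_coffee), 0.0, None)
        tea = np.clip(np.round(x_tea), 0.0, None)
    else:
        coffee, tea = x_coffee, x_tea

    # alcohol: ordered categories from a latent occasions/month scale
    sig_a = _alcohol_latent_sd(config.alcohol_probs)
    s_alc = _structural_part(config, "alcohol", scores, dosages, age_z, sex, pcs)
    v_a = _structural_cov(config, "alcohol", "alcohol")
    if sig_a**2 <= v_a:
        raise ConfigurationError(
            "alcohol structural effects exceed the latent alcohol variance"
        )
    x_alc = s_alc + rng.normal(0.0, math.sqrt(sig_a**2 - v_a), n)
    cum = np.cumsum(config.alcohol_probs)[:-1]
    thresholds = sig_a * norm.ppf(cum)
    idx = np.searchsorted(thresholds, x_alc, side="right")
    alcohol = pd.Categorical.from_codes(
        idx, categories=list(ALCOHOL_LEVELS), ordered=True
    ).astype(object)
    if config.prefer_not_rate > 0:
        mask = rng.random(n) < config.prefer_not_rate
        alcohol = np.where(mask, PREFER_NOT_TO_ANSWER, alcohol)

    table = pd.DataFrame(
        {
            "iid": [f"S2_{i:07d}" for i in range(n)],
            **{f"{stim}_dosage": dosages[stim] for stim in STIMULI},
            "age": age,
            "sex": sex,
            **{f"pc{j + 1}": pcs[:, j] for j in range(config.n_pcs)},
            "coffee": coffee,
            "tea": tea,
            "alcohol_category": alcohol,
            **{f"{stim}_score": scores[stim] for stim in STIMULI},
        }
    )
    return table


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------


def export_cohort(
    table: pd.DataFrame, path, include_latent: bool = False
) -> None:
    """Write a cohort as a tab-delimited file with a header row.

    Oracle-only latent score columns are dropped unless
    ``include_latent=True``. Missing values are written as empty fields
    and round-trip through :func:`read_cohort_table`.
    """
    out = table
    if not include_latent:
        drop = [c for c in LATENT_SCORE_COLUMNS if c in out.columns]
        out = out.drop(columns=drop)
    out.to_csv(path, sep="\t", index=False, na_rep="")


def read_cohort_table(path) -> pd.DataFrame:
    """Read a tab-delimited cohort written by :func:`export_cohort`."""
    df = pd.read_csv(path, sep="\t", dtype={"iid": str})
    return df
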