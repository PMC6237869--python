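"""Published summary statistics used as worked-example inputs.

Two-sample MR runs entirely on summary data, so the published
per-allele instrument effects (taste-intensity GWAS, n = 1757) and
SNP-beverage associations (UK-scale biobank analysis, n = 438,870) are
themselves analysis inputs. They are collected here for the worked
examples and consistency checks; instrument SEs, which the source
tables omit, are recovered from the reported F statistics via the 1-df
Wald identity ``se = beta / sqrt(F)``.
"""

from __future__ import annotations

from .assoc import AssociationResult
from .mr import GeneticInstrument, se_from_ci
from .synth_cohort import EFFECT_ALLELES, SNP_IDS

__all__ = [
    "N_DISCOVERY",
    "N_BIOBANK",
    "reported_instruments",
    "reported_coffee_assoc_caffeine",
    "reported_heavy_coffee_logor_caffeine",
    "reported_caffeine_tea_by_sex",
]

N_DISCOVERY = 1757
N_BIOBANK = 438_870

#: (effect SD/allele, variance explained, reported F) per stimulus.
_INSTRUMENT_ROWS = {
    "prop": (0.965, 0.46, 901.1),
    "quinine": (0.337, 0.06, 96.8),
    "caffeine": (0.264, 0.02, 30.0),
}


def reported_instruments() -> list[GeneticInstrument]:
    """The three bitter-taste instruments with their published effects."""
    out = []
    for stim, (beta, r2, f) in _INSTRUMENT_ROWS.items():
        out.append(
            GeneticInstrument(
                snp=SNP_IDS[stim],
                effect_allele=EFFECT_ALLELES[stim],
                stimulus=stim,
                beta=beta,
                se=beta / f**0.5,
                variance_explained=r2,
                n=N_DISCOVERY,
                f_statistic=f,
            )
        )
    return out


def reported_coffee_assoc_caffeine() -> AssociationResult:
    """Published per-allele caffeine-SNP association with coffee intake:
    0.039 cups/day (95% CI 0.027, 0.050)."""
    low, high = 0.027, 0.050
    return AssociationResult(
        snp=SNP_IDS["caffeine"],
        phenotype="coffee",
        beta=0.039,
        se=se_from_ci(low, high),
        n=N_BIOBANK,
        model="linear",
        ci_low=low,
        ci_high=high,
    )


def reported_heavy_coffee_logor_caffeine() -> tuple[float, float, float]:
    """Published causal OR for heavy coffee drinking per SD of caffeine
    perception: 1.207 (95% CI 1.126, 1.294), returned as
    (or, ci_low, ci_high)."""
    return 1.207, 1.126, 1.294


def reported_caffeine_tea_by_sex() -> dict[str, tuple[float, float, float]]:
    """Published per-SD caffeine-perception effects on tea (cups/day) by
    sex: estimate and 95% CI bounds."""
    return {
        "female": (-0.261, -0.341, -0.182),
        "male": (-0.091, -0.184, 0.004),
    }
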