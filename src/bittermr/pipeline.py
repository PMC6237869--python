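"""End-to-end orchestration: simulate -> harmonize -> associate -> MR.

A :class:`RunConfig` names either an input cohort file or a simulation
block (exactly one), the analysis plan, and an output directory. A run
writes the simulated cohorts (when simulating), the harmonized cohort,
the instrument table, the association and MR tables, a Fig-style
summary, and a manifest with the config hash and seed — all
tab-separated text, deterministic under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .assoc import association_table, fit_taste_instruments
from .mr import AnalysisPlan, StratumSpec, mr_table, run_mr_battery, sex_difference_tests
from .phenotypes import harmonize_cohort
from .synth_cohort import (
    STIMULI,
    ConfigurationError,
    SimulationConfig,
    export_cohort,
    read_cohort_table,
    simulate_sample1,
    simulate_sample2,
)

__all__ = ["RunConfig", "run_pipeline", "read_cohort", "instruments_table"]

log = logging.getLogger("bittermr")

REQUIRED_COLUMNS = tuple(f"{s}_dosage" for s in STIMULI) + (
    "age",
    "sex",
    "coffee",
    "tea",
    "alcohol_category",
)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``cohort_path`` (a pre-existing tab-separated cohort)
    or ``simulation`` (a :class:`SimulationConfig` block) must be active.
    """

    outdir: str = "results/run"
    seed: int = 0
    cohort_path: str | None = None
    simulation: SimulationConfig | None = field(default_factory=SimulationConfig)
    plan: AnalysisPlan = field(default_factory=AnalysisPlan)
    drinker_mode: str = "fixed"
    write_latent: bool = False

    def __post_init__(self) -> None:
        if (self.cohort_path is None) == (self.simulation is None):
            raise ConfigurationError(
                "exactly one of cohort_path or simulation must be set"
            )
        if self.simulation is not None and self.simulation.seed != self.seed:
            # one seed rules the run; keep the blocks consistent
            object.__setattr__(
                self, "simulation", dataclasses.replace(self.simulation, seed=self.seed)
            )

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "outdir": self.outdir,
            "seed": self.seed,
            "cohort_path": self.cohort_path,
            "drinker_mode": self.drinker_mode,
            "write_latent": self.write_latent,
            "simulation": self.simulation.to_dict() if self.simulation else None,
            "plan": {
                **dataclasses.asdict(self.plan),
                "strata": [dataclasses.asdict(s) for s in self.plan.strata],
            },
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.get("simulation")
        if isinstance(sim, dict):
            d["simulation"] = SimulationConfig.from_dict(sim)
        plan = d.get("plan")
        if isinstance(plan, dict):
            plan = dict(plan)
            for key in ("outcomes", "covariates"):
                if key in plan:
                    plan[key] = tuple(plan[key])
            if "conditional_pairs" in plan:
                plan["conditional_pairs"] = tuple(
                    tuple(p) for p in plan["conditional_pairs"]
                )
            if "strata" in plan:
                plan["strata"] = tuple(
                    StratumSpec(**s) if isinstance(s, dict) else s
                    for s in plan["strata"]
                )
            d["plan"] = AnalysisPlan(**plan)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def read_cohort(path, required: tuple[str, ...] = REQUIRED_COLUMNS) -> pd.DataFrame:
    """Read and validate a tab-separated cohort table.

    Missing required phenotype columns raise a schema error naming them;
    unknown columns are kept with a warning (they are ignored by the
    analyses). Malformed rows surface pandas' parse error, which carries
    the offending line number.
    """
    try:
        df = read_cohort_table(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed cohort file {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file {path} lacks required column(s): {missing}")
    known = set(required) | {"iid", "alcohol_freq_month"}
    known |= {f"pc{i}" for i in range(1, 41)}
    known |= {f"{s}_score" for s in STIMULI}
    known |= {f"{b}_drinker_status" for b in ("coffee", "tea", "alcohol")}
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        warnings.warn(f"ignoring unknown cohort column(s): {unknown}")
    log.info("read cohort %s: %d rows", path, len(df))
    return df


def instruments_table(instruments) -> pd.DataFrame:
    rows = [
        {
            "snp": i.snp,
            "effect_allele": i.effect_allele,
            "stimulus": i.stimulus,
            "beta": i.beta,
            "se": i.se,
            "variance_explained": i.variance_explained,
            "n": i.n,
            "F": i.f(),
        }
        for i in instruments
    ]
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute a full run; returns a bundle of output paths and tables.

    On failure, files already written to the output directory during
    this run are removed so partial results never masquerade as
    complete.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def write(df: pd.DataFrame, name: str) -> Path:
        path = outdir / name
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
        written.append(path)
        return path

    try:
        if config.simulation is not None:
            sim = config.simulation
            log.info("simulating sample 1 (n=%d) and sample 2 (n=%d)",
                     sim.n_sample1, sim.n_sample2)
            sample1 = simulate_sample1(sim)
            cohort = simulate_sample2(sim)
            p1 = outdir / "sample1_taste_gwas.tsv"
            export_cohort(sample1, p1, include_latent=True)
            written.append(p1)
            p2 = outdir / "sample2_cohort.tsv"
            export_cohort(cohort, p2, include_latent=config.write_latent)
            written.append(p2)
            instruments = fit_taste_instruments(sample1)
            sim_hash = sim.config_hash()
        else:
            cohort = read_cohort(config.cohort_path)
            sample1 = None
            from .reported import reported_instruments

            instruments = reported_instruments()
            sim_hash = None

        harmonized, statuses = harmonize_cohort(cohort, mode=config.drinker_mode)
        n_excluded = int(harmonized["alcohol_freq_month"].isna().sum())
        log.info(
            "harmonized %d participants (%d excluded from alcohol analyses)",
            len(harmonized),
            n_excluded,
        )
        write(instruments_table(instruments), "instruments.tsv")

        mr_results, assoc_results = run_mr_battery(harmonized, instruments, config.plan)
        assoc_path = write(association_table(assoc_results), "associations.tsv")
        mr_df = mr_table(mr_results)
        mr_path = write(mr_df, "mr_estimates.tsv")

        # Fig-style summary: main linear and binary panels
        summary = mr_df[mr_df["analysis"].isin(["main", "binary"])][
            ["analysis", "stimulus", "outcome", "scale", "estimate", "ci_low", "ci_high", "p", "significant"]
        ]
        summary_path = write(summary, "summary_panels.tsv")

        sexdiff = sex_difference_tests(mr_results)
        if len(sexdiff):
            write(sexdiff, "sex_difference_tests.tsv")

        manifest = {
            "package_version": __version__,
            "seed": config.seed,
            "config_hash": sim_hash,
            "n_cohort": int(len(cohort)),
            "n_sample1": int(len(sample1)) if sample1 is not None else None,
            "n_mr_results": len(mr_results),
            "n_assoc_results": len(assoc_results),
            "drinker_cutoffs": {
                b: dataclasses.asdict(s) for b, s in statuses.items()
            },
        }
        manifest_path = outdir / "manifest.json"
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        written.append(manifest_path)
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise

    return {
        "cohort": harmonized,
        "sample1": sample1,
        "instruments": instruments,
        "mr_results": mr_results,
        "assoc_results": assoc_results,
        "mr_table": mr_df,
        "paths": {
            "mr": mr_path,
            "assoc": assoc_path,
            "summary": summary_path,
            "manifest": manifest_path,
        },
    }
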