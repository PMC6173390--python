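"""End-to-end pipeline runs with full seed and provenance capture.

``run_pipeline`` executes generate/load -> exclusions -> target -> schedule
-> energy change -> weight simulation -> outcomes from a single RunConfig
and writes every stage artifact plus a manifest (config hash, seed, library
versions, per-file checksums).  Identical config and seed reproduce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bodyweight import ModelParams
from .energy import PolicyScenario
from .errors import ConfigurationError
from .model import SugarReformulationModel
from .population import POPULATION_COLUMNS, PopulationConfig, generate_population

__all__ = ["RunConfig", "run_pipeline", "validate_population_csv"]

logger = logging.getLogger("ssbreform")

_FLOAT_FMT = "%.10g"


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one end-to-end run.

    Exactly one population source: a synthetic-population config, or the
    path of a population CSV.
    """

    population: PopulationConfig | None = None
    population_csv: str | None = None
    scenario: PolicyScenario = field(default_factory=PolicyScenario)
    params: ModelParams = field(default_factory=ModelParams)
    projected_adults: float = 90_000_000.0
    ter_model: str = "hall"
    ci_method: str = "bootstrap"
    n_boot: int = 500
    outdir: str = "ssbreform_run"
    seed: int = 0
    verbosity: int = 1

    def __post_init__(self) -> None:
        if (self.population is None) == (self.population_csv is None):
            raise ConfigurationError(
                "exactly one of population / population_csv must be set"
            )
        if self.scenario.horizon_years < self.scenario.years:
            raise ConfigurationError("horizon must cover the rollout years")


def _config_dict(config: RunConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {
                k: enc(v)
                for k, v in dataclasses.asdict(obj).items()
                if k != "cell_overrides"
            }
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    return {f.name: enc(getattr(config, f.name)) for f in dataclasses.fields(config)}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages and write the artifact bundle; returns output paths."""
    level = {0: logging.WARNING, 1: logging.INFO}.get(config.verbosity, logging.DEBUG)
    logging.basicConfig(stream=sys.stderr, level=level, format="%(message)s")

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # a single seeded stream with per-stage substreams, so e.g. changing the
    # bootstrap replicate count cannot perturb population generation
    root = np.random.SeedSequence(config.seed)
    pop_seed, boot_seed = (int(s.generate_state(1)[0]) % (2**31) for s in root.spawn(2))

    if config.population is not None:
        logger.info("generating synthetic population (seed %d)", pop_seed)
        population = generate_population(config.population, seed=pop_seed)
    else:
        logger.info("loading population from %s", config.population_csv)
        report = validate_population_csv(config.population_csv)
        if not report["ok"]:
            raise ConfigurationError(
                f"population CSV failed validation: {report['errors']}"
            )
        population = pd.read_csv(config.population_csv)

    model = SugarReformulationModel(
        population,
        scenario=config.scenario,
        params=config.params,
        projected_adults=config.projected_adults,
        ter_model=config.ter_model,
    )
    logger.info("fitting pipeline (scenario %s)", config.scenario.scenario)
    res = model.fit(seed=boot_seed, ci_method=config.ci_method, n_boot=config.n_boot)

    paths = {}

    def save(name: str, df: pd.DataFrame) -> None:
        path = outdir / name
        _write(df, path)
        paths[name] = path

    save("population.csv", population[POPULATION_COLUMNS])
    save("exclusions.csv", res.exclusion_log)
    save("target_report.csv", res.target_table)
    save("schedule.csv", res.schedule.to_frame() if res.schedule is not None
         else pd.DataFrame(columns=["year", "cumulative_fraction", "increment"]))
    save("individual_results.csv", res.individual_results)
    save("outcomes_means.csv", res.summary_means)
    save("outcomes_prevalence.csv", res.summary_prevalence)

    manifest = {
        "config": _config_dict(config),
        "config_sha256": hashlib.sha256(
            json.dumps(_config_dict(config), sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "required_proportion_raw": res.required_proportion_raw,
        "target_rounded": res.target_rounded,
        "target_used": res.scenario.target,
        "mean_delta_weight": res.mean_delta_weight,
        "versions": {
            "ssbreform": _package_version(),
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "outputs": {name: _sha256(p) for name, p in paths.items()},
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    paths["manifest.json"] = manifest_path
    logger.info("wrote %d artifacts to %s", len(paths), outdir)
    return {"paths": paths, "results": res, "manifest": manifest}


def _package_version() -> str:
    from importlib.metadata import version

    try:
        return version("ssbreform")
    except Exception:  # pragma: no cover
        return "unknown"


# ---------------------------------------------------------------------------
# population CSV validation
# ---------------------------------------------------------------------------

_UNIT_CHECKS = [
    # column, plausible range of the column mean, hint
    ("height", 1.2, 2.2, "height should be in meters (values ~1.6, not ~160)"),
    ("weight", 35.0, 200.0, "weight should be in kilograms"),
    ("tei_init", 500.0, 6000.0, "tei_init should be kcal/day"),
]


def validate_population_csv(path) -> dict:
    """Schema, invariant and unit checks on a population CSV.

    Returns a report dict: ``ok`` (bool), ``errors`` (table-level messages),
    and ``row_errors`` (DataFrame of row index, column, message).
    """
    errors: list[str] = []
    row_errors: list[tuple] = []
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        return {"ok": False, "errors": [f"unreadable file: {exc}"],
                "row_errors": pd.DataFrame(columns=["row", "column", "message"])}

    missing = [c for c in POPULATION_COLUMNS if c not in df.columns]
    if missing:
        errors.append(f"missing columns: {missing}")
    else:
        for col, lo, hi, hint in _UNIT_CHECKS:
            m = df[col].mean()
            if not lo <= m <= hi:
                errors.append(f"{col} mean {m:.3g} outside [{lo}, {hi}]: {hint}")
        checks = [
            (df["sugar_ssb"] > df["sugar_total"] + 1e-6, "sugar_ssb",
             "sugar_ssb exceeds sugar_total"),
            (df["sugar_total"] > df["tei_init"] + 1e-6, "sugar_total",
             "sugar_total exceeds tei_init"),
            ((df["sugar_other"] - (df["sugar_total"] - df["sugar_ssb"])).abs()
             > 1e-6, "sugar_other", "sugar_other != sugar_total - sugar_ssb"),
            (df["survey_weight"] <= 0, "survey_weight", "non-positive weight"),
            (df["height"] <= 0, "height", "non-positive height"),
            (df["weight"] <= 0, "weight", "non-positive weight (kg)"),
            (df["sugar_ssb"] < 0, "sugar_ssb", "negative sugar_ssb"),
        ]
        for mask, col, msg in checks:
            for idx in df.index[mask.fillna(False)]:
                row_errors.append((int(idx), col, msg))
        if df["id"].duplicated().any():
            errors.append("duplicate ids")

    row_df = pd.DataFrame(row_errors, columns=["row", "column", "message"])
    return {"ok": not errors and row_df.empty, "errors": errors, "row_errors": row_df}
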