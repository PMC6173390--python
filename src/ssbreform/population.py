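"""Seeded synthetic populations with the structure of a national diet survey.

The generator emulates an adult 24-hour-recall analytic sample: ~3,000
records expanding to ~65 M adults, right-skewed intake distributions with
sex / age-group / socioeconomic gradients, zero-inflated SSB sugar (about
half the sample consumed an SSB in the past 24 h), BMI spanning the three
categories with the observed prevalences, and a stratified two-stage
sampling design (strata x primary sampling units with mild between-PSU
correlation) so that design-based variance estimation is exercised.

Cell means follow a multiplicative main-effects decomposition: the mean of
a variable in a sex x age x SES cell is the overall mean times one relative
factor per margin.  Because the three demographic margins are drawn
independently, the generated marginal means reproduce the configured
marginal means by construction.

Intakes are log-normal within cells; SSB sugar is a Beta-distributed
fraction of total added sugar for consumers and exactly zero otherwise,
with the per-cell consumer share solved from the cell's target SSB mean.
BMI is log-normal, tied to the intake deviate through a configurable rank
correlation (weak by default, as observed in recall data).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .bodyweight import ModelParams, total_energy_requirement
from .errors import ConfigurationError

__all__ = [
    "PopulationConfig",
    "generate_population",
    "apply_exclusions",
    "write_population_csv",
    "read_population_csv",
]

SEXES = ("male", "female")
AGE_GROUPS = ("20-39", "40-59", "60+")
SES_LEVELS = ("low", "middle", "high")

POPULATION_COLUMNS = [
    "id", "sex", "age", "height", "weight", "ses",
    "tei_init", "sugar_total", "sugar_ssb", "sugar_other",
    "survey_weight", "stratum", "psu",
]

# Overall means (kcal/day) and relative marginal factors of the emulated
# adult sample: total added sugar 244.9 (12.6% TEI), SSB added sugar 101.1
# (5.1% TEI), with the published sex / age / SES gradients.
_OVERALL = {"sugar_total": 244.9, "sugar_ssb": 101.1, "tei": 244.9 / 0.126}

_FACTORS = {
    "sex": {
        "p": {"male": 0.477, "female": 0.523},
        "sugar_total": {"male": 278.9, "female": 213.9},
        "sugar_ssb": {"male": 128.0, "female": 76.7},
        "tei": {"male": 278.9 / 0.129, "female": 213.9 / 0.122},
    },
    "age_group": {
        "p": {"20-39": 0.446, "40-59": 0.368, "60+": 0.186},
        "sugar_total": {"20-39": 285.7, "40-59": 235.7, "60+": 165.2},
        "sugar_ssb": {"20-39": 130.8, "40-59": 90.3, "60+": 51.4},
        "tei": {"20-39": 285.7 / 0.138, "40-59": 235.7 / 0.122, "60+": 165.2 / 0.103},
    },
    "ses": {
        "p": {"low": 0.297, "middle": 0.301, "high": 0.402},
        "sugar_total": {"low": 213.1, "middle": 255.0, "high": 260.7},
        "sugar_ssb": {"low": 84.5, "middle": 118.0, "high": 100.8},
        "tei": {"low": 213.1 / 0.113, "middle": 255.0 / 0.127, "high": 260.7 / 0.134},
    },
}


def _normalized_factors(var: str) -> dict:
    """Marginal means -> relative factors with weighted mean exactly 1."""
    out = {}
    for dim, spec in _FACTORS.items():
        probs = spec["p"]
        means = spec[var]
        overall = sum(probs[k] * means[k] for k in probs)
        out[dim] = {k: means[k] / overall for k in probs}
    return out


@dataclass(frozen=True)
class PopulationConfig:
    """Generator settings; defaults emulate the adult analytic sample.

    The BMI log-normal defaults place 30.4 / 38.7 / 30.9 percent of mass
    in the normal / overweight / obese categories.
    """

    n_records: int = 3005
    target_expansion: float = 64_885_715.0
    mean_sugar_total: float = _OVERALL["sugar_total"]
    mean_sugar_ssb: float = _OVERALL["sugar_ssb"]
    mean_tei: float = _OVERALL["tei"]
    consumer_share: float = 0.518
    sigma_tei: float = 0.35        # log-scale sd of TEI within a cell
    sigma_other: float = 0.70      # log-scale sd of non-SSB added sugar
    sigma_ssb: float = 0.75        # log-scale sd of SSB added sugar (consumers)
    max_sugar_tei_ratio: float = 0.85  # cap on added sugar as a share of TEI
    bmi_log_mu: float = 3.3113     # ln-BMI location
    bmi_log_sigma: float = 0.1802  # ln-BMI scale
    bmi_intake_corr: float = 0.1   # rank correlation of BMI with intake
    icc: float = 0.02              # between-PSU intraclass correlation
    n_strata: int = 30
    psus_per_stratum: int = 3
    seed: int = 0
    cell_overrides: dict = field(default_factory=dict, hash=False, compare=False)

    def __post_init__(self) -> None:
        if self.n_records < 1:
            raise ConfigurationError("n_records must be positive")
        for name in ("mean_sugar_total", "mean_sugar_ssb", "mean_tei",
                     "target_expansion"):
            if getattr(self, name) <= 0.0:
                raise ConfigurationError(f"{name} must be positive")
        if not 0.0 <= self.consumer_share <= 1.0:
            raise ConfigurationError("consumer_share must be in [0, 1]")
        if not 0.0 <= self.icc < 1.0:
            raise ConfigurationError("icc must be in [0, 1)")

    def with_(self, **kwargs) -> "PopulationConfig":
        return replace(self, **kwargs)

    def cell_means(self) -> pd.DataFrame:
        """Per sex x age-group x SES cell means of tei, sugar_total, sugar_ssb."""
        rows = []
        facs = {v: _normalized_factors(v) for v in ("sugar_total", "sugar_ssb", "tei")}
        for sex in SEXES:
            for ag in AGE_GROUPS:
                for ses in SES_LEVELS:
                    row = {"sex": sex, "age_group": ag, "ses": ses}
                    for var, base in (
                        ("sugar_total", self.mean_sugar_total),
                        ("sugar_ssb", self.mean_sugar_ssb),
                        ("tei", self.mean_tei),
                    ):
                        f = facs[var]
                        row[var] = (
                            base
                            * f["sex"][sex] * f["age_group"][ag] * f["ses"][ses]
                        )
                    row.update(self.cell_overrides.get((sex, ag, ses), {}))
                    rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_yaml(cls, path) -> "PopulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = {
            k: v for k, v in self.__dict__.items() if k != "cell_overrides"
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def _age_within(group: str, u: np.ndarray) -> np.ndarray:
    lo, hi = {"20-39": (20.0, 40.0), "40-59": (40.0, 60.0), "60+": (60.0, 85.0)}[group]
    return lo + u * (hi - lo)


def generate_population(
    config: PopulationConfig | None = None, seed: int | None = None
) -> pd.DataFrame:
    """Generate a seeded population table with the configured structure.

    Deterministic given the seed (``seed`` overrides ``config.seed``).
    Returns a DataFrame with exactly the canonical population columns.
    """
    config = config or PopulationConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_records

    sex = rng.choice(SEXES, size=n, p=[_FACTORS["sex"]["p"][s] for s in SEXES])
    age_group = rng.choice(
        AGE_GROUPS, size=n, p=[_FACTORS["age_group"]["p"][a] for a in AGE_GROUPS]
    )
    ses = rng.choice(
        SES_LEVELS, size=n, p=[_FACTORS["ses"]["p"][s] for s in SES_LEVELS]
    )
    age = _age_within_vec(age_group, rng.uniform(size=n))

    male = sex == "male"
    height = np.where(
        male, rng.normal(1.67, 0.07, size=n), rng.normal(1.55, 0.06, size=n)
    )
    height = np.clip(height, 1.35, 2.05)

    # survey design: records spread over strata and PSUs; a shared PSU-level
    # deviate induces the configured intraclass correlation on the intake scale
    stratum = rng.integers(1, config.n_strata + 1, size=n)
    psu_within = rng.integers(1, config.psus_per_stratum + 1, size=n)
    psu = (stratum - 1) * config.psus_per_stratum + psu_within
    psu_effect = rng.normal(size=config.n_strata * config.psus_per_stratum + 1)
    z_cluster = psu_effect[psu]
    z_ind = rng.normal(size=n)
    z_intake = np.sqrt(config.icc) * z_cluster + np.sqrt(1 - config.icc) * z_ind

    rho = config.bmi_intake_corr
    z_bmi = rho * z_intake + np.sqrt(1.0 - rho**2) * rng.normal(size=n)
    bmi = np.exp(config.bmi_log_mu + config.bmi_log_sigma * z_bmi)
    weight = bmi * height**2

    cells = config.cell_means().set_index(["sex", "age_group", "ses"])
    cell_tei = cells["tei"].to_numpy()
    cell_sugar = cells["sugar_total"].to_numpy()
    cell_ssb = cells["sugar_ssb"].to_numpy()
    idx = cells.index.get_indexer(list(zip(sex, age_group, ses)))

    tei = cell_tei[idx] * np.exp(
        config.sigma_tei * z_intake - config.sigma_tei**2 / 2.0
    )

    # Added sugar from non-SSB sources and from SSBs are drawn as separate
    # log-normal components (the latter zero-inflated), so heavy total-sugar
    # intakes come predominantly from SSBs, as in recall data.  Per-cell
    # consumer shares are proportional to the cell's SSB-to-total-sugar
    # ratio, normalized so the expected overall share matches the config;
    # the consumer-conditional SSB mean is then back-solved per cell so the
    # cell SSB means are exact in expectation.
    cell_other = cell_sugar - cell_ssb
    z_other = rng.normal(size=n)
    sugar_other = cell_other[idx] * np.exp(
        config.sigma_other * z_other - config.sigma_other**2 / 2.0
    )
    if config.consumer_share == 0.0:
        sugar_ssb = np.zeros(n)
    else:
        p_raw = cell_ssb / cell_sugar
        cell_prob = np.array(
            [
                _FACTORS["sex"]["p"][s]
                * _FACTORS["age_group"]["p"][a]
                * _FACTORS["ses"]["p"][e]
                for s, a, e in cells.index
            ]
        )
        p_cell = np.clip(
            p_raw * config.consumer_share / np.sum(cell_prob * p_raw), 0.02, 0.98
        )
        is_consumer = rng.uniform(size=n) < p_cell[idx]
        z_ssb = rng.normal(size=n)
        ssb_consumer_mean = cell_ssb[idx] / p_cell[idx]
        sugar_ssb = np.where(
            is_consumer,
            ssb_consumer_mean
            * np.exp(config.sigma_ssb * z_ssb - config.sigma_ssb**2 / 2.0),
            0.0,
        )
    # cap implausible totals (a 24-h recall cannot exceed TEI) by scaling
    # both sources down proportionally
    total = sugar_other + sugar_ssb
    cap = config.max_sugar_tei_ratio * tei
    scale = np.where(total > cap, cap / np.where(total > 0, total, 1.0), 1.0)
    sugar_other = sugar_other * scale
    sugar_ssb = sugar_ssb * scale
    sugar_total = sugar_other + sugar_ssb

    raw_w = rng.lognormal(mean=0.0, sigma=0.5, size=n)
    survey_weight = raw_w * (config.target_expansion / raw_w.sum())

    pop = pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "sex": sex,
            "age": age,
            "height": height,
            "weight": weight,
            "ses": ses,
            "tei_init": tei,
            "sugar_total": sugar_total,
            "sugar_ssb": sugar_ssb,
            "sugar_other": sugar_other,
            "survey_weight": survey_weight,
            "stratum": stratum,
            "psu": psu,
        }
    )
    return pop


def _age_within_vec(groups: np.ndarray, u: np.ndarray) -> np.ndarray:
    out = np.empty_like(u)
    for g in AGE_GROUPS:
        mask = groups == g
        out[mask] = _age_within(g, u[mask])
    return out


def apply_exclusions(
    population: pd.DataFrame,
    ter_model: str = "hall",
    params: ModelParams | None = None,
    sd_limit: float = 3.0,
    ssb_kcal_limit: float = 3000.0,
):
    """Apply the analytic-sample exclusion filters.

    Rules, in order: missing weight/height; age under 20; SSB caloric
    intake above ``ssb_kcal_limit``; energy misreporting, i.e.
    |ln(TEI / TER)| more than ``sd_limit`` sample standard deviations from
    the sample mean of that log-ratio (TER from ``ter_model``).  When the
    log-ratio has zero dispersion no record is excluded under that rule.

    Returns ``(kept, log)`` where ``log`` lists rule, count and excluded ids.
    """
    df = population
    entries = []

    missing = df["weight"].isna() | df["height"].isna()
    entries.append(("missing_anthropometry", df.loc[missing, "id"]))
    df = df.loc[~missing]

    underage = df["age"] < 20.0
    entries.append(("age_under_20", df.loc[underage, "id"]))
    df = df.loc[~underage]

    extreme_ssb = df["sugar_ssb"] > ssb_kcal_limit
    entries.append(("ssb_above_3000_kcal", df.loc[extreme_ssb, "id"]))
    df = df.loc[~extreme_ssb]

    ter = total_energy_requirement(df, params, model=ter_model)
    log_ratio = np.log(df["tei_init"].to_numpy(dtype=float) / ter)
    sd = float(np.std(log_ratio, ddof=1)) if len(log_ratio) > 1 else 0.0
    if sd > 0.0:
        z = np.abs(log_ratio - log_ratio.mean()) / sd
        misreport = pd.Series(z > sd_limit, index=df.index)
    else:
        misreport = pd.Series(False, index=df.index)
    entries.append(("energy_misreporting_3sd", df.loc[misreport, "id"]))
    df = df.loc[~misreport]

    log = pd.DataFrame(
        {
            "rule": [rule for rule, ids in entries],
            "count": [len(ids) for _, ids in entries],
            "ids": [";".join(map(str, ids.tolist())) for _, ids in entries],
        }
    )
    return df.reset_index(drop=True), log


def write_population_csv(population: pd.DataFrame, path) -> None:
    population.to_csv(path, index=False, float_format="%.10g")


def read_population_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
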