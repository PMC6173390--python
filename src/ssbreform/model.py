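"""Model / Results interface tying the pipeline stages together.

``SugarReformulationModel`` holds a person-level population table and a
policy scenario; ``fit`` runs exclusions, the per-individual sugar target,
the rollout schedule, the net-intake trajectories, the dynamic weight
simulation, and the survey-weighted aggregation, returning a
``SugarReformulationResults`` object that carries every intermediate table
plus a printable summary.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import outcomes as _outcomes
from .bodyweight import ModelParams, simulate_population
from .energy import PolicyScenario, yearly_net_change
from .errors import ConfigurationError
from .population import (
    PopulationConfig,
    apply_exclusions,
    generate_population,
    read_population_csv,
)
from .targets import compute_targets, required_proportion, round_target

__all__ = ["SugarReformulationModel", "SugarReformulationResults"]

_REQUIRED = [
    "id", "sex", "age", "height", "weight", "ses",
    "tei_init", "sugar_total", "sugar_ssb", "sugar_other",
    "survey_weight", "stratum", "psu",
]


class SugarReformulationModel:
    """Reformulation policy model over a person-level population table.

    Parameters
    ----------
    data : DataFrame
        Population table with the canonical columns (see
        ``population.POPULATION_COLUMNS``).
    scenario : PolicyScenario
        Policy levers; a ``target`` of None is resolved at fit time from
        the data (survey-weighted required proportion, rounded down to the
        policy grid).
    params : ModelParams
        Body-weight model constants.
    apply_filters : bool
        Apply the analytic-sample exclusion rules before fitting.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        scenario: PolicyScenario | None = None,
        params: ModelParams | None = None,
        projected_adults: float = 90_000_000.0,
        apply_filters: bool = True,
        ter_model: str = "hall",
    ):
        missing = [c for c in _REQUIRED if c not in data.columns]
        if missing:
            raise ConfigurationError(f"population table missing columns {missing}")
        self.data = data.reset_index(drop=True)
        self.scenario = scenario or PolicyScenario()
        self.params = params or ModelParams()
        self.projected_adults = projected_adults
        self.apply_filters = apply_filters
        self.ter_model = ter_model

    @classmethod
    def from_csv(cls, path, **kwargs) -> "SugarReformulationModel":
        return cls(read_population_csv(path), **kwargs)

    @classmethod
    def from_synthetic(
        cls,
        config: PopulationConfig | None = None,
        seed: int | None = None,
        **kwargs,
    ) -> "SugarReformulationModel":
        return cls(generate_population(config, seed=seed), **kwargs)

    def fit(
        self,
        seed: int = 0,
        ci_method: str = "bootstrap",
        n_boot: int = 500,
        dt: float = 1.0,
    ) -> "SugarReformulationResults":
        """Run the full pipeline and return a results object."""
        if self.apply_filters:
            kept, exclusion_log = apply_exclusions(
                self.data, ter_model=self.ter_model, params=self.params
            )
        else:
            kept, exclusion_log = self.data, None

        target_table = compute_targets(kept, self.scenario.goal)
        raw_prop = required_proportion(kept, self.scenario.goal)
        rounded = round_target(raw_prop)
        scenario = self.scenario
        if scenario.target is None:
            scenario = scenario.with_(target=rounded)

        schedule = scenario.build_schedule()
        ssb = kept["sugar_ssb"].to_numpy(dtype=float)
        net = yearly_net_change(
            ssb, schedule, scenario.compensation, scenario.horizon_years
        )
        sim = simulate_population(kept, net, params=self.params, dt=dt)

        final_reduction = schedule.at_year(scenario.horizon_years) if schedule else 0.0
        results = sim.copy()
        results["delta_sugar"] = -ssb * final_reduction  # gross cut at full rollout
        results["delta_intake"] = net[:, -1]             # net, with compensation

        summary = _outcomes.weighted_summary(
            kept, results,
            ci_method=ci_method, n_boot=n_boot, seed=seed,
            projected_adults=self.projected_adults,
        )
        return SugarReformulationResults(
            model=self,
            scenario=scenario,
            population=kept,
            exclusion_log=exclusion_log,
            target_table=target_table,
            required_proportion_raw=raw_prop,
            target_rounded=rounded,
            schedule=schedule,
            individual_results=results,
            summary_frame=summary,
        )


class SugarReformulationResults:
    """Fitted results: per-individual tables, weighted summaries, projections."""

    def __init__(
        self, model, scenario, population, exclusion_log, target_table,
        required_proportion_raw, target_rounded, schedule,
        individual_results, summary_frame,
    ):
        self.model = model
        self.scenario = scenario
        self.population = population
        self.exclusion_log = exclusion_log
        self.target_table = target_table
        self.required_proportion_raw = required_proportion_raw
        self.target_rounded = target_rounded
        self.schedule = schedule
        self.individual_results = individual_results
        self.summary_frame = summary_frame

    # -- headline scalars ---------------------------------------------------

    def _overall(self, col: str) -> float:
        row = self.summary_frame.loc[self.summary_frame["stratum_var"] == "overall"]
        return float(row[col].iloc[0])

    @property
    def mean_delta_sugar(self) -> float:
        """Weighted mean gross added-sugar change at full rollout (kcal/day)."""
        return self._overall("mean_delta_sugar")

    @property
    def mean_delta_intake(self) -> float:
        """Weighted mean net energy-intake change (kcal/day)."""
        return self._overall("mean_delta_intake")

    @property
    def mean_delta_weight(self) -> float:
        """Weighted mean body-weight change at the horizon (kg)."""
        return self._overall("mean_delta_weight")

    @property
    def mean_delta_bmi(self) -> float:
        return self._overall("mean_delta_bmi")

    @property
    def obesity_delta_pp(self) -> float:
        """Change in obesity prevalence, percentage points."""
        return self._overall("delta_pp_obese")

    # -- derived tables -----------------------------------------------------

    @property
    def summary_means(self) -> pd.DataFrame:
        """Mean changes by stratum (sugar, intake, weight, BMI)."""
        cols = ["stratum_var", "stratum", "n"]
        for c in ("delta_sugar", "delta_intake", "delta_weight", "delta_bmi"):
            cols.append(f"mean_{c}")
            for suf in ("_ci_low", "_ci_high"):
                if f"mean_{c}{suf}" in self.summary_frame:
                    cols.append(f"mean_{c}{suf}")
        return self.summary_frame[cols]

    @property
    def summary_prevalence(self) -> pd.DataFrame:
        """Prevalence changes and projected case counts by stratum."""
        cols = ["stratum_var", "stratum", "n"]
        for cat in _outcomes.BMI_CATEGORIES:
            cols += [
                f"prev_baseline_{cat}", f"prev_final_{cat}",
                f"delta_pp_{cat}", f"delta_rel_{cat}", f"cases_millions_{cat}",
            ]
            for suf in ("_ci_low", "_ci_high"):
                if f"delta_pp_{cat}{suf}" in self.summary_frame:
                    cols.append(f"delta_pp_{cat}{suf}")
        return self.summary_frame[cols]

    def sensitivity(
        self, targets=None, compensations=None, dt: float = 1.0
    ) -> pd.DataFrame:
        """Mean weight change over a target x compensation grid."""
        if targets is None:
            targets = [0.0, 0.25, 0.5, 0.75, 1.0]
        if compensations is None:
            compensations = [0.0, 25.0, 50.0, 75.0, 100.0]
        return _outcomes.sensitivity_matrix(
            self.population, targets, compensations,
            scenario=self.scenario.scenario, years=self.scenario.years,
            horizon_years=self.scenario.horizon_years,
            params=self.model.params, dt=dt,
        )

    def plot_sensitivity(self, matrix: pd.DataFrame | None = None, ax=None):
        """Heat map of the sensitivity matrix (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if matrix is None:
            matrix = self.sensitivity()
        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(matrix.to_numpy(), aspect="auto", cmap="viridis")
        ax.set_xticks(range(matrix.shape[1]), [f"{t:.0%}" for t in matrix.columns])
        ax.set_yticks(range(matrix.shape[0]), [f"{c:.0f}%" for c in matrix.index])
        ax.set_xlabel("sugar reduction target")
        ax.set_ylabel("caloric compensation")
        ax.figure.colorbar(im, ax=ax, label="mean weight change (kg)")
        return ax

    def summary(self) -> str:
        """Printable run summary."""
        s = self.scenario
        w = self.population["survey_weight"].sum()
        lines = [
            "Added-sugar reformulation in SSBs: simulation results",
            "=" * 56,
            f"records: {len(self.population)}   expanded adults: {w:,.0f}",
            f"scenario: {s.scenario} rollout, target {s.target:.0%} over "
            f"{s.years} y, compensation {s.compensation:.0f}%, "
            f"horizon {s.horizon_years} y",
            f"required reduction proportion: {self.required_proportion_raw:.1%}"
            f" (rounded down to {self.target_rounded:.0%})",
            "",
            "Survey-weighted mean changes at the horizon",
            f"  added sugar (gross): {self.mean_delta_sugar:8.1f} kcal/day",
            f"  energy intake (net): {self.mean_delta_intake:8.1f} kcal/day",
            f"  body weight:         {self.mean_delta_weight:8.2f} kg",
            f"  BMI:                 {self.mean_delta_bmi:8.2f} kg/m2",
            "",
            "BMI-category prevalence (baseline -> final, pp change)",
        ]
        for cat in _outcomes.BMI_CATEGORIES:
            b = self._overall(f"prev_baseline_{cat}")
            f = self._overall(f"prev_final_{cat}")
            d = self._overall(f"delta_pp_{cat}")
            c = self._overall(f"cases_millions_{cat}")
            lines.append(
                f"  {cat:<10} {b:5.1f}% -> {f:5.1f}%   {d:+5.1f} pp"
                f"   {c:+5.2f} M persons"
            )
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<SugarReformulationResults: n={len(self.population)}, "
            f"mean_delta_weight={self.mean_delta_weight:.3f} kg>"
        )
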