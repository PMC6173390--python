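"""Net caloric-change trajectories under a rollout schedule and compensation.

The gross caloric cut for an individual in policy year *y* is their baseline
SSB added sugar times the cumulative reduction fraction in force that year.
A fraction ``compensation/100`` of that cut is regained from other dietary
sources, so the net change is

    delta_intake(y) = -sugar_ssb * Reduction(y) * (1 - compensation/100).

Diet composition is assumed constant, so the carbohydrate share of the net
change defaults to 1 (the intervention removes sugar and the compensated
calories restore mixed food at the baseline macronutrient split); with full
compensation both the net energy and net carbohydrate changes vanish.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError, DomainError
from .schedule import SCENARIOS, ReductionSchedule, build_schedule

__all__ = [
    "PolicyScenario",
    "IntakeTrajectory",
    "caloric_change",
    "overall_reduction",
    "yearly_net_change",
    "build_trajectory",
]

DAYS_PER_YEAR = 365


@dataclass(frozen=True)
class PolicyScenario:
    """Policy levers of one simulation run.

    target
        Fraction of SSB added sugar removed at full rollout (0.5 = 50%).
    compensation
        Percent of the gross caloric cut regained from other sources.
    years
        Rollout length in years.
    scenario
        Rollout shape: decreasing, constant, or increasing.
    horizon_years
        Total simulated years; the final reduction holds after the rollout
        so the weight response can play out (default 12 for a 10-year
        rollout, leaving the slow body-weight transient two extra years).
    """

    target: float | None = 0.5
    compensation: float = 43.0
    years: int = 10
    scenario: str = "decreasing"
    horizon_years: int = 12
    goal: float = 0.10

    def __post_init__(self) -> None:
        if not 0.0 <= self.compensation <= 100.0:
            raise ConfigurationError(
                f"compensation must be in [0, 100], got {self.compensation}"
            )
        if self.target is not None and not 0.0 <= self.target <= 1.0:
            raise ConfigurationError(f"target must be in [0, 1], got {self.target}")
        if self.horizon_years < self.years:
            raise ConfigurationError("horizon_years must be >= years")
        if self.scenario not in SCENARIOS:
            raise ConfigurationError(f"unknown scenario {self.scenario!r}")

    def build_schedule(self) -> ReductionSchedule | None:
        """Schedule for this scenario; None for a zero target (no policy)."""
        if self.target is None:
            raise ConfigurationError(
                "target is unresolved; fit the model to derive it from data"
            )
        if self.target == 0.0:
            return None
        return build_schedule(self.scenario, self.target, self.years)

    def with_(self, **kwargs) -> "PolicyScenario":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class IntakeTrajectory:
    """Daily net energy-intake change for one individual.

    ``delta_intake[d]`` is the net change (kcal/day, <= 0) in force on day
    ``d``; day 0 is the pre-policy baseline (0).  The series is piecewise
    constant within policy years and holds the final-year value through the
    horizon.  ``carb_fraction_of_change`` is the fraction of the net change
    that is carbohydrate.
    """

    days: np.ndarray = field(repr=False)
    delta_intake: np.ndarray = field(repr=False)
    carb_fraction_of_change: float = 1.0

    def __post_init__(self) -> None:
        if self.delta_intake[0] != 0.0:
            raise DomainError("delta_intake must be 0 at day 0")
        if np.any(self.delta_intake > 1e-12):
            raise DomainError("delta_intake must be <= 0 (a reduction)")

    @property
    def delta_carb(self) -> np.ndarray:
        """Daily net carbohydrate-energy change (kcal/day)."""
        return self.carb_fraction_of_change * self.delta_intake

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "day": self.days,
                "delta_intake": self.delta_intake,
                "carb_fraction": self.carb_fraction_of_change,
            }
        )


def caloric_change(
    sugar_ssb: float, cumulative_reduction: float, compensation: float
) -> float:
    """Net daily caloric change (kcal/day, <= 0) for one policy year."""
    if sugar_ssb < 0.0:
        raise DomainError(f"sugar_ssb must be >= 0, got {sugar_ssb}")
    if not 0.0 <= cumulative_reduction <= 1.0:
        raise DomainError(
            f"cumulative_reduction must be in [0, 1], got {cumulative_reduction}"
        )
    if not 0.0 <= compensation <= 100.0:
        raise DomainError(f"compensation must be in [0, 100], got {compensation}")
    return -sugar_ssb * cumulative_reduction * (1.0 - compensation / 100.0)


def overall_reduction(target: float, compensation: float) -> float:
    """Effective net reduction fraction Target * (1 - Compensation/100)."""
    if not 0.0 <= target <= 1.0:
        raise DomainError(f"target must be in [0, 1], got {target}")
    if not 0.0 <= compensation <= 100.0:
        raise DomainError(f"compensation must be in [0, 100], got {compensation}")
    return target * (1.0 - compensation / 100.0)


def yearly_net_change(
    sugar_ssb,
    schedule: ReductionSchedule | None,
    compensation: float,
    horizon_years: int,
) -> np.ndarray:
    """Net intake change per simulation year, shape (n, horizon_years).

    Vectorized over individuals; years past the rollout hold the target
    level.  A None schedule (zero target) yields all zeros.
    """
    ssb = np.atleast_1d(np.asarray(sugar_ssb, dtype=float))
    if schedule is None:
        return np.zeros((len(ssb), horizon_years))
    if horizon_years < schedule.years:
        raise ConfigurationError("horizon shorter than the rollout schedule")
    cum = np.array(
        [schedule.at_year(y) for y in range(1, horizon_years + 1)]
    )
    return -np.outer(ssb, cum) * (1.0 - compensation / 100.0)


def build_trajectory(
    individual, schedule: ReductionSchedule | None, scenario: PolicyScenario
) -> IntakeTrajectory:
    """Expand the yearly levels of one individual into a daily trajectory.

    ``individual`` is anything with a ``sugar_ssb`` attribute or key
    (a dataclass, a pandas Series / row, or a mapping).
    """
    try:
        ssb = float(individual["sugar_ssb"])
    except (TypeError, IndexError, KeyError):
        ssb = float(individual.sugar_ssb)
    levels = yearly_net_change(
        ssb, schedule, scenario.compensation, scenario.horizon_years
    )[0]
    n_days = scenario.horizon_years * DAYS_PER_YEAR
    days = np.arange(n_days + 1)
    # day d (1-based) falls in policy year floor((d-1)/365) + 1
    delta = np.concatenate([[0.0], np.repeat(levels, DAYS_PER_YEAR)])
    return IntakeTrajectory(days=days, delta_intake=delta)
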