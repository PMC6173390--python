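"""Yearly sugar-reduction rollout schedules.

A regulation phases the reformulation target in over ``years`` annual steps.
Three rollout shapes are supported:

``decreasing``
    A constant *multiplicative* yearly cut: the sugar content retained after
    year *j* is ``(1 - r1)**j``, with the first-year reduction ``r1`` chosen
    so that the cumulative reduction reaches the target at the final year.
    Because each year's cut applies to an already-reduced content, the
    absolute yearly decrements shrink over time.

``constant``
    The same absolute decrement of the *baseline* content every year
    (target/years per year).

``increasing``
    The yearly decrements of the decreasing schedule applied in reverse
    order: small cuts first, the largest cut last.

All three agree at year 0 (no reduction) and at the final year (the target).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError

__all__ = [
    "ReductionSchedule",
    "first_year_reduction",
    "schedule_decreasing",
    "schedule_constant",
    "schedule_increasing",
    "build_schedule",
]

SCENARIOS = ("decreasing", "constant", "increasing")


@dataclass(frozen=True)
class ReductionSchedule:
    """Cumulative sugar-reduction fraction per policy year.

    ``cumulative[j - 1]`` is the fraction of the baseline sugar content
    removed from the start of policy year ``j``; it is nondecreasing and
    reaches ``target`` at year ``years``.
    """

    scenario: str
    target: float
    years: int
    cumulative: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        cum = np.asarray(self.cumulative, dtype=float)
        object.__setattr__(self, "cumulative", cum)
        if len(cum) != self.years:
            raise DomainError("cumulative must have one entry per year")
        if np.any(np.diff(cum) < -1e-12):
            raise DomainError("cumulative reductions must be nondecreasing")
        if abs(cum[-1] - self.target) > 1e-12:
            raise DomainError("final cumulative reduction must equal target")

    @property
    def increments(self) -> np.ndarray:
        """Absolute yearly decrements of the baseline content."""
        return np.diff(np.concatenate([[0.0], self.cumulative]))

    def at_year(self, year: int) -> float:
        """Cumulative reduction in force during policy year ``year`` (1-based).

        Years past the rollout hold at the target; year 0 is 0.
        """
        if year <= 0:
            return 0.0
        return float(self.cumulative[min(year, self.years) - 1])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "year": np.arange(1, self.years + 1),
                "cumulative_fraction": self.cumulative,
                "increment": self.increments,
            }
        )


def _check(target: float, years: int) -> None:
    # 1.0 (full removal) is admitted for sensitivity grids; the decreasing
    # schedule then degenerates to a single first-year step
    if not 0.0 < target <= 1.0:
        raise DomainError(f"target must be in (0, 1], got {target}")
    if years < 1:
        raise DomainError(f"years must be >= 1, got {years}")


def first_year_reduction(target: float, years: int) -> float:
    """First-year reduction 1 - (1 - target)**(1/years).

    This is the constant multiplicative yearly cut that compounds to the
    target after ``years`` years (e.g. 6.7% per year reaches 50% in 10).
    """
    _check(target, years)
    return 1.0 - (1.0 - target) ** (1.0 / years)


def schedule_decreasing(target: float, years: int) -> ReductionSchedule:
    """Geometric rollout: cumulative[j] = 1 - (1 - r1)**j."""
    _check(target, years)
    r1 = first_year_reduction(target, years)
    j = np.arange(1, years + 1)
    cum = 1.0 - (1.0 - r1) ** j
    cum[-1] = target  # compounding reaches the target exactly
    return ReductionSchedule("decreasing", target, years, cum)


def schedule_constant(target: float, years: int) -> ReductionSchedule:
    """Linear rollout: the same fraction of baseline content each year."""
    _check(target, years)
    j = np.arange(1, years + 1)
    cum = target * j / years
    cum[-1] = target
    return ReductionSchedule("constant", target, years, cum)


def schedule_increasing(target: float, years: int) -> ReductionSchedule:
    """Reversed-decrement rollout: smallest cut first, largest last."""
    _check(target, years)
    inc = schedule_decreasing(target, years).increments[::-1]
    cum = np.cumsum(inc)
    cum[-1] = target
    return ReductionSchedule("increasing", target, years, cum)


_BUILDERS = {
    "decreasing": schedule_decreasing,
    "constant": schedule_constant,
    "increasing": schedule_increasing,
}


def build_schedule(scenario: str, target: float, years: int) -> ReductionSchedule:
    """Dispatch on scenario name; unknown names raise DomainError."""
    try:
        builder = _BUILDERS[scenario]
    except KeyError:
        raise DomainError(
            f"unknown scenario {scenario!r}; expected one of {SCENARIOS}"
        ) from None
    return builder(target, years)
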