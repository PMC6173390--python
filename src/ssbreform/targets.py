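"""Per-individual reformulation targets for an added-sugar intake goal.

The policy goal is that mean added-sugar intake not exceed a fraction
``goal`` (default 10%) of total energy intake (TEI).  For each individual
we solve for the maximum added sugar from sugar-sweetened beverages (SSBs)
compatible with the goal, accounting for the fact that removing SSB sugar
also lowers TEI:

    goal = (ssb_max + others) / (tei_init + (ssb_max - ssb_init))

which has the closed form

    ssb_max = [goal * (tei_init - ssb_init) - others] / (1 - goal).

Three regimes follow:

* ``ssb_init <= ssb_max``: the individual is already at or below the goal;
  no change (delta = 0).
* ``ssb_init > ssb_max >= 0``: cut SSB sugar down to ``ssb_max``
  (delta = ssb_max - ssb_init < 0); back-substitution then recovers the
  goal share exactly.
* ``ssb_max < 0``: sugar from other sources alone exceeds the goal; all
  SSB sugar is removed (delta = -ssb_init) and the individual remains
  above the goal.

The survey-weighted mean of the per-individual reduction proportions
``prop_i = |delta_i| / ssb_init_i`` defines the population reformulation
target, which is then rounded down to a policy-friendly grid.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .errors import DomainError

__all__ = [
    "max_ssb_sugar",
    "delta_change",
    "compute_targets",
    "required_proportion",
    "round_target",
]


def _check_goal(goal: float) -> None:
    if not 0.0 < goal < 1.0:
        raise DomainError(f"goal must be in (0, 1), got {goal}")


def max_ssb_sugar(tei_init, ssb_init, others, goal: float = 0.10):
    """Maximum SSB added sugar (kcal/day) compatible with the intake goal.

    May be negative: that signals the regime where non-SSB added sugar
    alone already exceeds the goal.  Accepts scalars or arrays.
    """
    _check_goal(goal)
    tei = np.asarray(tei_init, dtype=float)
    ssb = np.asarray(ssb_init, dtype=float)
    oth = np.asarray(others, dtype=float)
    out = (goal * (tei - ssb) - oth) / (1.0 - goal)
    if out.ndim == 0:
        return float(out)
    return out


def delta_change(tei_init, ssb_init, others, goal: float = 0.10):
    """Change in SSB added sugar (kcal/day, <= 0) to meet the goal.

    Zero when already compliant; a cut to ``ssb_max`` otherwise; full
    removal when other-source sugar alone exceeds the goal.
    """
    smax = np.asarray(max_ssb_sugar(tei_init, ssb_init, others, goal))
    ssb = np.asarray(ssb_init, dtype=float)
    delta = np.where(
        smax < 0.0,
        -ssb,
        np.where(ssb > smax, smax - ssb, 0.0),
    )
    if delta.ndim == 0:
        return float(delta)
    return delta


def compute_targets(
    population: pd.DataFrame, goal: float = 0.10
) -> pd.DataFrame:
    """Per-individual target table: id, ssb_max, delta_change, prop.

    ``prop`` is |delta|/ssb_init, the proportion of the individual's SSB
    sugar removed; it is defined as 0 for non-consumers (ssb_init = 0),
    the continuous extension consistent with delta = 0.
    """
    ssb = population["sugar_ssb"].to_numpy(dtype=float)
    smax = max_ssb_sugar(
        population["tei_init"].to_numpy(dtype=float),
        ssb,
        population["sugar_other"].to_numpy(dtype=float),
        goal,
    )
    delta = delta_change(
        population["tei_init"].to_numpy(dtype=float),
        ssb,
        population["sugar_other"].to_numpy(dtype=float),
        goal,
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        prop = np.where(ssb > 0.0, -delta / np.where(ssb > 0, ssb, 1.0), 0.0)
    return pd.DataFrame(
        {
            "id": population["id"].to_numpy(),
            "ssb_max": np.asarray(smax),
            "delta_change": delta,
            "prop": prop,
        }
    )


def required_proportion(
    population: pd.DataFrame,
    goal: float = 0.10,
    denominator: str = "population",
) -> float:
    """Survey-weighted mean reduction proportion defining the policy target.

    ``denominator="population"`` averages prop over everyone (non-consumers
    contribute 0); ``"consumers"`` restricts to records with ssb_init > 0.
    """
    if len(population) == 0:
        raise DomainError("population is empty")
    if denominator not in ("population", "consumers"):
        raise DomainError(f"unknown denominator {denominator!r}")
    tab = compute_targets(population, goal)
    w = population["survey_weight"].to_numpy(dtype=float)
    prop = tab["prop"].to_numpy()
    if denominator == "consumers":
        mask = population["sugar_ssb"].to_numpy(dtype=float) > 0.0
        w, prop = w[mask], prop[mask]
    total = w.sum()
    if total <= 0.0:
        raise DomainError("total survey weight is zero")
    return float(np.sum(w * prop) / total)


def round_target(raw: float, step: float = 0.05, mode: str = "down") -> float:
    """Round a raw proportion onto a policy grid (default 5% steps, down)."""
    if not 0.0 <= raw <= 1.0:
        raise DomainError(f"raw proportion must be in [0, 1], got {raw}")
    if step <= 0.0:
        raise DomainError(f"step must be positive, got {step}")
    if mode != "down":
        raise DomainError(f"unsupported rounding mode {mode!r}")
    # nudge guards against 0.5/0.05 evaluating to 9.999... under floating point
    return math.floor(raw / step + 1e-9) * step
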