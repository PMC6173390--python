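"""Survey-weighted aggregation of individual results to population outcomes.

Estimates are ratio means under the survey weights.  Design-based
uncertainty is available two ways: a stratified clustered bootstrap that
resamples primary sampling units (PSUs) with replacement within each design
stratum (the default), and Taylor linearization of the ratio estimator with
the usual stratified between-PSU variance formula.  Both treat the weight
model as deterministic, so the intervals reflect sampling error only.

BMI categories follow WHO cut-points with underweight collapsed into the
normal range: normal < 25, overweight 25 to <30, obese >= 30 kg/m2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DomainError

__all__ = [
    "BMI_CATEGORIES",
    "classify_bmi",
    "weighted_mean",
    "weighted_summary",
    "project_cases",
    "sensitivity_matrix",
]

BMI_CATEGORIES = ("normal", "overweight", "obese")

AGE_GROUP_BOUNDS = ((20.0, 40.0, "20-39"), (40.0, 60.0, "40-59"), (60.0, np.inf, "60+"))


def classify_bmi(bmi):
    """BMI category with half-open boundaries; underweight counts as normal."""
    arr = np.asarray(bmi, dtype=float)
    if np.any(arr <= 0.0):
        raise DomainError("bmi must be positive")
    cat = np.select(
        [arr < 25.0, arr < 30.0], ["normal", "overweight"], default="obese"
    )
    if arr.ndim == 0:
        return str(cat)
    return cat


def weighted_mean(values, weights) -> float:
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    total = weights.sum()
    if total <= 0.0:
        raise DomainError("total weight must be positive")
    return float(np.sum(weights * values) / total)


def project_cases(delta_pp: float, projected_adults: float) -> float:
    """Signed count of individuals moved, from a prevalence change in pp."""
    if projected_adults <= 0.0:
        raise DomainError("projected_adults must be positive")
    return delta_pp / 100.0 * projected_adults


# ---------------------------------------------------------------------------
# design-based variance
# ---------------------------------------------------------------------------


def _ratio_mean(y, w):
    return np.sum(y * w) / np.sum(w)


def _taylor_se(y, w, strata, psu) -> float:
    """Taylor-linearized SE of the weighted ratio mean under the design."""
    r = _ratio_mean(y, w)
    wsum = np.sum(w)
    z = w * (y - r) / wsum
    df = pd.DataFrame({"z": z, "stratum": strata, "psu": psu})
    var = 0.0
    for _, g in df.groupby("stratum", sort=False):
        totals = g.groupby("psu", sort=False)["z"].sum().to_numpy()
        n_h = len(totals)
        if n_h > 1:
            var += n_h / (n_h - 1) * np.sum((totals - totals.mean()) ** 2)
    return float(np.sqrt(var))


def _bootstrap_ses(columns, w, strata, psu, n_boot, rng):
    """Stratified clustered bootstrap SEs for several ratio means at once.

    ``columns`` is a dict name -> values; PSU totals of w*y and w are
    precomputed, then PSUs are resampled with replacement within strata.
    """
    df = pd.DataFrame({"_w": w, "_stratum": strata, "_psu": psu})
    for name, vals in columns.items():
        df[name] = np.asarray(vals, dtype=float) * w
    agg = df.groupby(["_stratum", "_psu"], sort=False).sum(numeric_only=True)
    names = list(columns)
    stats = np.empty((n_boot, len(names)))
    strata_codes = agg.index.get_level_values(0)
    groups = [
        agg.loc[agg.index[strata_codes == s]].to_numpy()
        for s in strata_codes.unique()
    ]
    for b in range(n_boot):
        num = np.zeros(len(names))
        den = 0.0
        for block in groups:
            n_h = block.shape[0]
            take = rng.integers(0, n_h, size=n_h)
            picked = block[take]
            den += picked[:, 0].sum()
            num += picked[:, 1:].sum(axis=0)
        stats[b] = num / den
    return {name: float(stats[:, i].std(ddof=1)) for i, name in enumerate(names)}


# ---------------------------------------------------------------------------
# summary tables
# ---------------------------------------------------------------------------


def _default_strata(population: pd.DataFrame):
    age = population["age"].to_numpy(dtype=float)
    age_group = np.select(
        [age < b[1] for b in AGE_GROUP_BOUNDS],
        [b[2] for b in AGE_GROUP_BOUNDS],
        default="60+",
    )
    specs = [
        ("overall", pd.Series("all", index=population.index)),
        ("sex", population["sex"]),
        ("age_group", pd.Series(age_group, index=population.index)),
        ("ses", population["ses"]),
    ]
    if (population["sugar_ssb"] > 0).any():
        specs.append(
            (
                "consumers",
                pd.Series(
                    np.where(population["sugar_ssb"] > 0, "consumers", None),
                    index=population.index,
                ),
            )
        )
    return specs


def weighted_summary(
    population: pd.DataFrame,
    results: pd.DataFrame,
    strata_spec=None,
    ci_method: str = "bootstrap",
    n_boot: int = 500,
    seed: int = 0,
    projected_adults: float = 90_000_000.0,
    z: float = 1.96,
) -> pd.DataFrame:
    """Survey-weighted outcome summary, overall and stratified.

    ``results`` is the per-individual table from the weight simulation
    merged with the intake deltas (columns delta_sugar, delta_intake,
    delta_weight, delta_bmi, bmi_baseline, bmi_final).  Returns one row per
    stratum level with weighted mean changes, baseline and final BMI-category
    prevalences, absolute (pp) and relative (%) prevalence changes,
    projected case counts (millions), and 95% CIs for the mean changes and
    prevalence changes.
    """
    if ci_method not in ("bootstrap", "taylor", "none"):
        raise DomainError(f"unknown ci_method {ci_method!r}")
    merged = population.merge(results, on="id", validate="one_to_one")
    if strata_spec is None:
        strata_spec = _default_strata(population)
    rng = np.random.default_rng(seed)
    rows = []
    mean_cols = ("delta_sugar", "delta_intake", "delta_weight", "delta_bmi")
    for var, labels in strata_spec:
        labels = pd.Series(labels).reindex(population.index)
        for level in [lv for lv in labels.dropna().unique()]:
            sub = merged.loc[(labels == level).to_numpy()]
            if len(sub) == 0:
                continue
            w = sub["survey_weight"].to_numpy(dtype=float)
            row = {"stratum_var": var, "stratum": level, "n": len(sub),
                   "weight_sum": w.sum()}
            cols = {}
            for c in mean_cols:
                row[f"mean_{c}"] = weighted_mean(sub[c], w)
                cols[f"mean_{c}"] = sub[c].to_numpy(dtype=float)
            base_cat = classify_bmi(sub["bmi_baseline"].to_numpy())
            final_cat = classify_bmi(sub["bmi_final"].to_numpy())
            for cat in BMI_CATEGORIES:
                b = (base_cat == cat).astype(float)
                f = (final_cat == cat).astype(float)
                prev_b = weighted_mean(b, w)
                prev_f = weighted_mean(f, w)
                row[f"prev_baseline_{cat}"] = 100.0 * prev_b
                row[f"prev_final_{cat}"] = 100.0 * prev_f
                row[f"delta_pp_{cat}"] = 100.0 * (prev_f - prev_b)
                row[f"delta_rel_{cat}"] = (
                    100.0 * (prev_f - prev_b) / prev_b if prev_b > 0 else np.nan
                )
                row[f"cases_millions_{cat}"] = (
                    project_cases(row[f"delta_pp_{cat}"], projected_adults) / 1e6
                )
                cols[f"delta_pp_{cat}"] = f - b
            ses = {}
            if ci_method == "bootstrap":
                ses = _bootstrap_ses(
                    cols, w, sub["stratum"].to_numpy(), sub["psu"].to_numpy(),
                    n_boot, rng,
                )
            elif ci_method == "taylor":
                ses = {
                    name: _taylor_se(
                        vals, w, sub["stratum"].to_numpy(), sub["psu"].to_numpy()
                    )
                    for name, vals in cols.items()
                }
            for name, se in ses.items():
                scale = 100.0 if name.startswith("delta_pp") else 1.0
                center = row[name] if name in row else row[f"{name}"]
                row[f"{name}_se"] = scale * se
                row[f"{name}_ci_low"] = center - z * scale * se
                row[f"{name}_ci_high"] = center + z * scale * se
            rows.append(row)
    return pd.DataFrame(rows)


def sensitivity_matrix(
    population: pd.DataFrame,
    targets,
    compensations,
    scenario: str = "decreasing",
    years: int = 10,
    horizon_years: int = 12,
    params=None,
    dt: float = 1.0,
) -> pd.DataFrame:
    """Mean 12-year weight change over a target x compensation grid.

    One full pipeline run per cell (schedule, net intake change, weight
    simulation, weighted mean); rows are compensation percents, columns
    reduction targets.
    """
    from .bodyweight import simulate_population
    from .energy import yearly_net_change
    from .schedule import build_schedule

    w = population["survey_weight"].to_numpy(dtype=float)
    ssb = population["sugar_ssb"].to_numpy(dtype=float)
    out = np.zeros((len(compensations), len(targets)))
    for j, target in enumerate(targets):
        sched = None if target == 0.0 else build_schedule(scenario, target, years)
        for i, comp in enumerate(compensations):
            net = yearly_net_change(ssb, sched, comp, horizon_years)
            res = simulate_population(population, net, params=params, dt=dt)
            out[i, j] = weighted_mean(res["delta_weight"], w)
    return pd.DataFrame(
        out,
        index=pd.Index(list(compensations), name="compensation"),
        columns=pd.Index(list(targets), name="target"),
    )
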