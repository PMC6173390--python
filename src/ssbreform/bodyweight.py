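"""Adult dynamic energy-balance body-weight model.

Body weight is decomposed into fat mass F, lean tissue L, glycogen G with
its bound water, and extracellular fluid (ECF).  An energy imbalance is
partitioned between fat and lean tissue by the Forbes rule

    p = C / (C + F),        rho_f dF/dt = (1 - p) EB,
                            rho_l dL/dt = p EB,

where EB is the energy balance left after glycogen flux, and total energy
expenditure is

    TEE = K + gamma_f F + gamma_l L + delta_pa BW + TEF + AT
          + eta_f dF/dt + eta_l dL/dt.

TEF is the thermic effect of the intake change (beta_tef * dEI) and AT an
adaptive-thermogenesis offset relaxing toward beta_at * dEI with time
constant tau_at.  Glycogen tracks carbohydrate intake (dG/dt proportional
to the carbohydrate imbalance, with quadratic feedback that holds the
baseline store at steady state) and carries hydration_ratio grams of water
per gram; ECF relaxes toward an offset driven by the relative carbohydrate
change (sodium intake is unchanged by a sugar reformulation, so the sodium
channel is inert).

Each individual is calibrated to steady state at baseline: the constant K
absorbs whatever expenditure the tissue terms do not explain, so that
expenditure equals reported intake exactly and weight is constant absent
intervention.  Because dietary reports under- or over-state true intake, K
may be negative for some records; it is a residual offset, not a
physiological quantity.

Integration is a fixed-step classical Runge-Kutta scheme at 1-day steps by
default, vectorized over individuals, with steps aligned to policy-year
boundaries so the piecewise-constant forcing is exact.  An adaptive
(scipy) path is available for single-individual runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import CalibrationError, ConfigurationError, DomainError, IntegrationError

__all__ = [
    "ModelParams",
    "BodyState",
    "WeightTrajectory",
    "baseline_fat_mass",
    "initial_state",
    "total_energy_requirement",
    "calibrate_steady_state",
    "simulate_weight",
    "simulate_population",
]

DAYS_PER_YEAR = 365


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the energy-balance model (kcal, kg, days).

    Defaults are the canonical published values of the adult model family;
    every constant is overridable.
    """

    rho_f: float = 9440.0        # kcal/kg, energy density of fat
    rho_l: float = 1816.0        # kcal/kg, energy density of lean tissue
    rho_g: float = 4180.0        # kcal/kg, energy density of glycogen
    gamma_f: float = 3.2         # kcal/kg/d, fat-specific expenditure
    gamma_l: float = 22.0        # kcal/kg/d, lean-specific expenditure
    eta_f: float = 180.0         # kcal/kg, fat synthesis/turnover cost
    eta_l: float = 230.0         # kcal/kg, lean synthesis/turnover cost
    beta_tef: float = 0.10       # thermic effect of the intake change
    beta_at: float = 0.14        # adaptive-thermogenesis magnitude
    tau_at: float = 14.0         # d, adaptive-thermogenesis time constant
    forbes_c: float = 10.4 * 1816.0 / 9440.0  # kg, Forbes constant x rho_l/rho_f
    hydration_ratio: float = 3.7  # g water bound per g glycogen
    sodium_ecf: float = 3000.0   # mg/d per L, ECF restoring coefficient
    carb_ecf: float = 4000.0     # mg/d, ECF response to relative carb change
    na_conc: float = 3220.0      # mg sodium per L extracellular fluid
    delta_pa: float = 7.0        # kcal/kg/d, physical-activity slope on BW
    carb_share: float = 0.55     # baseline carbohydrate fraction of TEI
    glycogen_init: float = 0.5   # kg, baseline glycogen store
    ecf_frac: float = 0.235      # baseline ECF as fraction of body weight
    k_default: float = 500.0     # kcal/d, population-level expenditure offset
    fat_min_frac: float = 0.05   # clamp bounds for the fat-mass regression
    fat_max_frac: float = 0.60
    glycogen_enabled: bool = True  # False: two-compartment F/L core only
    k_expenditure: float | None = None  # kcal/d, set by calibration

    def __post_init__(self) -> None:
        for name in ("rho_f", "rho_l", "rho_g", "tau_at", "hydration_ratio"):
            if getattr(self, name) <= 0.0:
                raise ConfigurationError(f"{name} must be positive")

    def with_(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class BodyState:
    """Body composition at one time point."""

    fat: float
    lean: float
    glycogen: float
    ecf: float
    at: float = 0.0

    def weight(self, params: ModelParams) -> float:
        return (
            self.fat
            + self.lean
            + self.glycogen * (1.0 + params.hydration_ratio)
            + self.ecf
        )


@dataclass(frozen=True)
class WeightTrajectory:
    """Daily body-weight series for one individual."""

    days: np.ndarray = field(repr=False)
    weight: np.ndarray = field(repr=False)
    final_bmi: float = 0.0
    delta_weight: float = 0.0


def _is_male(sex) -> np.ndarray:
    arr = np.asarray(sex)
    if arr.dtype.kind in "USO":
        return np.char.lower(arr.astype(str)) == "male"
    return arr.astype(bool)


def baseline_fat_mass(sex, age, height, weight, params: ModelParams | None = None):
    """Baseline fat mass (kg) from the Deurenberg anthropometric regression.

    body fat %% = 1.20 BMI + 0.23 age - 10.8 (male) - 5.4; higher in women
    than men and increasing in BMI and age.  Implied fractions outside the
    configured bounds are clamped with a warning.
    """
    params = params or ModelParams()
    age = np.asarray(age, dtype=float)
    height = np.asarray(height, dtype=float)
    weight = np.asarray(weight, dtype=float)
    male = _is_male(sex)
    bmi = weight / height**2
    frac = (1.20 * bmi + 0.23 * age - 10.8 * male - 5.4) / 100.0
    clipped = np.clip(frac, params.fat_min_frac, params.fat_max_frac)
    if np.any(clipped != frac):
        warnings.warn(
            "fat fraction outside plausible bounds; clamped",
            stacklevel=2,
        )
    fat = clipped * weight
    if fat.ndim == 0:
        return float(fat)
    return fat


def initial_state(sex, age, height, weight, params: ModelParams | None = None):
    """Baseline BodyState (or arrays of compartments) at steady state."""
    params = params or ModelParams()
    weight = np.asarray(weight, dtype=float)
    fat = np.asarray(baseline_fat_mass(sex, age, height, weight, params))
    glycogen = np.broadcast_to(params.glycogen_init, weight.shape).astype(float)
    ecf = params.ecf_frac * weight
    lean = weight - fat - glycogen * (1.0 + params.hydration_ratio) - ecf
    if np.any(lean <= 0.0):
        raise DomainError("implied lean mass is non-positive; check anthropometry")
    if weight.ndim == 0:
        return BodyState(float(fat), float(lean), float(glycogen), float(ecf), 0.0)
    return fat, lean, glycogen, ecf


def total_energy_requirement(
    population: pd.DataFrame,
    params: ModelParams | None = None,
    model: str = "hall",
) -> np.ndarray:
    """Reference total energy requirement (kcal/day) per record.

    ``model="hall"``: the weight model's baseline expenditure at steady
    state with the population-level offset ``k_default`` (self-consistent
    with the simulation).  ``model="iom"``: the IOM estimated energy
    requirement for sedentary adults, as an external alternative.
    """
    params = params or ModelParams()
    if model == "hall":
        fat, lean, _, _ = initial_state(
            population["sex"], population["age"],
            population["height"], population["weight"], params,
        )
        bw = population["weight"].to_numpy(dtype=float)
        return (
            params.k_default
            + params.gamma_f * fat
            + params.gamma_l * lean
            + params.delta_pa * bw
        )
    if model == "iom":
        age = population["age"].to_numpy(dtype=float)
        wt = population["weight"].to_numpy(dtype=float)
        ht = population["height"].to_numpy(dtype=float)
        male = _is_male(population["sex"])
        eer_m = 662.0 - 9.53 * age + 15.91 * wt + 539.6 * ht
        eer_f = 354.0 - 6.91 * age + 9.36 * wt + 726.0 * ht
        return np.where(male, eer_m, eer_f)
    raise ConfigurationError(f"unknown TER model {model!r}")


def _get(individual, key):
    try:
        return individual[key]
    except (TypeError, IndexError, KeyError):
        return getattr(individual, key)


def _calibrate_k(fat, lean, weight, tei, params: ModelParams) -> np.ndarray:
    """Offset K such that baseline expenditure equals baseline intake."""
    return (
        np.asarray(tei, dtype=float)
        - params.gamma_f * np.asarray(fat)
        - params.gamma_l * np.asarray(lean)
        - params.delta_pa * np.asarray(weight, dtype=float)
    )


def calibrate_steady_state(individual, params: ModelParams | None = None) -> ModelParams:
    """Return params with ``k_expenditure`` solving intake = expenditure.

    At the baseline state the tissue terms are fixed, so K has the closed
    form K = tei - gamma_f F0 - gamma_l L0 - delta_pa BW0 and the residual
    is zero to machine precision.
    """
    params = params or ModelParams()
    state = initial_state(
        _get(individual, "sex"), _get(individual, "age"),
        _get(individual, "height"), _get(individual, "weight"), params,
    )
    tei = float(_get(individual, "tei_init"))
    k = float(
        _calibrate_k(state.fat, state.lean, state.weight(params), tei, params)
    )
    if not np.isfinite(k):
        raise CalibrationError(
            f"no finite expenditure offset for individual {_get(individual, 'id')!r}"
        )
    return params.with_(k_expenditure=k)


# ---------------------------------------------------------------------------
# vectorized integrator
# ---------------------------------------------------------------------------


def _derivs(F, L, G, EC, AT, EI, dEI, dCI, k, tei, ec_b, params: ModelParams):
    """Time derivatives of all compartments plus the energy-gap integrand."""
    p = params.forbes_c / (params.forbes_c + F)
    bw = F + L + G * (1.0 + params.hydration_ratio) + EC
    tef = params.beta_tef * dEI
    e0 = k + params.gamma_f * F + params.gamma_l * L + params.delta_pa * bw + tef + AT
    if params.glycogen_enabled:
        ci_b = params.carb_share * tei
        ci = ci_b + dCI
        gdot = (ci - ci_b * (G / params.glycogen_init) ** 2) / params.rho_g
        ecdot = (
            -params.carb_ecf * (1.0 - ci / ci_b)
            - params.sodium_ecf * (EC - ec_b)
        ) / params.na_conc
    else:
        gdot = np.zeros_like(F)
        ecdot = np.zeros_like(F)
    denom = (
        1.0
        + params.eta_f * (1.0 - p) / params.rho_f
        + params.eta_l * p / params.rho_l
    )
    eb_fl = (EI - params.rho_g * gdot - e0) / denom
    fdot = (1.0 - p) * eb_fl / params.rho_f
    ldot = p * eb_fl / params.rho_l
    atdot = (params.beta_at * dEI - AT) / params.tau_at
    expenditure = e0 + params.eta_f * fdot + params.eta_l * ldot
    egap = EI - expenditure  # equals rho_f fdot + rho_l ldot + rho_g gdot
    return fdot, ldot, gdot, ecdot, atdot, egap


def _rk4_segment(state, n_steps, dt, EI, dEI, dCI, k, tei, ec_b, params):
    """Advance all individuals ``n_steps`` steps under constant forcing."""
    F, L, G, EC, AT, E = state
    for _ in range(n_steps):
        k1 = _derivs(F, L, G, EC, AT, EI, dEI, dCI, k, tei, ec_b, params)
        k2 = _derivs(
            F + 0.5 * dt * k1[0], L + 0.5 * dt * k1[1], G + 0.5 * dt * k1[2],
            EC + 0.5 * dt * k1[3], AT + 0.5 * dt * k1[4],
            EI, dEI, dCI, k, tei, ec_b, params,
        )
        k3 = _derivs(
            F + 0.5 * dt * k2[0], L + 0.5 * dt * k2[1], G + 0.5 * dt * k2[2],
            EC + 0.5 * dt * k2[3], AT + 0.5 * dt * k2[4],
            EI, dEI, dCI, k, tei, ec_b, params,
        )
        k4 = _derivs(
            F + dt * k3[0], L + dt * k3[1], G + dt * k3[2],
            EC + dt * k3[3], AT + dt * k3[4],
            EI, dEI, dCI, k, tei, ec_b, params,
        )
        F = F + dt / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        L = L + dt / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        G = G + dt / 6.0 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
        EC = EC + dt / 6.0 * (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3])
        AT = AT + dt / 6.0 * (k1[4] + 2 * k2[4] + 2 * k3[4] + k4[4])
        E = E + dt / 6.0 * (k1[5] + 2 * k2[5] + 2 * k3[5] + k4[5])
    return F, L, G, EC, AT, E


def _check_state(state, ids, params):
    F, L, G, EC, AT, _ = state
    bad = ~(
        np.isfinite(F) & np.isfinite(L) & np.isfinite(G)
        & np.isfinite(EC) & np.isfinite(AT)
    ) | (F <= 0.0) | (L <= 0.0) | (G < 0.0)
    if np.any(bad):
        culprits = np.asarray(ids)[bad][:5]
        raise IntegrationError(
            f"non-finite or non-physical compartment for ids {list(culprits)}"
        )


def _run_population(
    fat, lean, gly, ecf, tei, ids,
    net_by_year: np.ndarray,
    carb_fraction: float,
    params: ModelParams,
    dt: float,
    record_daily: bool = False,
    record_yearly: bool = False,
):
    """Integrate all individuals over the horizon; yearly piecewise forcing."""
    n, horizon = net_by_year.shape
    k = _calibrate_k(fat, lean,
                     fat + lean + gly * (1.0 + params.hydration_ratio) + ecf,
                     tei, params)
    ec_b = ecf.astype(float).copy()
    state = (
        fat.astype(float).copy(), lean.astype(float).copy(),
        gly.astype(float).copy(), ecf.astype(float).copy(),
        np.zeros(n), np.zeros(n),
    )
    steps_per_day = int(round(1.0 / dt))
    if abs(steps_per_day * dt - 1.0) > 1e-9:
        raise ConfigurationError("dt must divide one day")
    daily = []
    yearly = []
    w0 = state[0] + state[1] + state[2] * (1.0 + params.hydration_ratio) + state[3]
    if record_daily:
        daily.append(w0.copy())
    for year in range(horizon):
        dEI = net_by_year[:, year]
        dCI = carb_fraction * dEI
        EI = tei + dEI
        if record_daily:
            for _ in range(DAYS_PER_YEAR):
                state = _rk4_segment(state, steps_per_day, dt, EI, dEI, dCI,
                                     k, tei, ec_b, params)
                daily.append(
                    state[0] + state[1]
                    + state[2] * (1.0 + params.hydration_ratio) + state[3]
                )
        else:
            state = _rk4_segment(
                state, DAYS_PER_YEAR * steps_per_day, dt, EI, dEI, dCI,
                k, tei, ec_b, params,
            )
        _check_state(state, ids, params)
        if record_yearly:
            yearly.append(
                state[0] + state[1]
                + state[2] * (1.0 + params.hydration_ratio) + state[3]
            )
    wf = state[0] + state[1] + state[2] * (1.0 + params.hydration_ratio) + state[3]
    out = {
        "weight_baseline": w0,
        "weight_final": wf,
        "energy_gap_integral": state[5],
        "k_expenditure": k,
        "final_state": state,
    }
    if record_daily:
        out["daily_weight"] = np.asarray(daily)
    if record_yearly:
        out["yearly_weight"] = np.asarray(yearly)
    return out


def simulate_population(
    population: pd.DataFrame,
    net_by_year: np.ndarray,
    params: ModelParams | None = None,
    dt: float = 1.0,
    carb_fraction: float = 1.0,
    record_yearly: bool = False,
):
    """Simulate every individual under yearly net intake changes.

    ``net_by_year`` has shape (n, horizon_years), kcal/day per policy year.
    Returns a per-individual results DataFrame; with ``record_yearly`` the
    year-end weight matrix is attached as ``.attrs["yearly_weight"]``.
    """
    params = params or ModelParams()
    fat, lean, gly, ecf = initial_state(
        population["sex"], population["age"],
        population["height"], population["weight"], params,
    )
    tei = population["tei_init"].to_numpy(dtype=float)
    ids = population["id"].to_numpy()
    out = _run_population(
        fat, lean, gly, ecf, tei, ids, np.asarray(net_by_year, dtype=float),
        carb_fraction, params, dt, record_yearly=record_yearly,
    )
    height = population["height"].to_numpy(dtype=float)
    res = pd.DataFrame(
        {
            "id": ids,
            "weight_baseline": out["weight_baseline"],
            "weight_final": out["weight_final"],
            "delta_weight": out["weight_final"] - out["weight_baseline"],
            "bmi_baseline": out["weight_baseline"] / height**2,
            "bmi_final": out["weight_final"] / height**2,
            "energy_gap_integral": out["energy_gap_integral"],
        }
    )
    res["delta_bmi"] = res["bmi_final"] - res["bmi_baseline"]
    res.attrs["initial_state"] = (fat, lean, gly, ecf)
    res.attrs["final_state"] = out["final_state"]
    res.attrs["k_expenditure"] = out["k_expenditure"]
    if record_yearly:
        res.attrs["yearly_weight"] = out["yearly_weight"]
    return res


def simulate_weight(
    individual,
    trajectory,
    params: ModelParams | None = None,
    dt: float = 1.0,
    method: str = "rk4",
) -> WeightTrajectory:
    """Simulate one individual from a daily IntakeTrajectory.

    ``method="rk4"`` uses the fixed-step engine (daily weight recorded);
    ``method="adaptive"`` integrates with scipy's LSODA and evaluates on
    the same daily grid.
    """
    params = params or ModelParams()
    delta = np.asarray(trajectory.delta_intake, dtype=float)
    n_days = len(delta) - 1
    if n_days % DAYS_PER_YEAR != 0:
        raise ConfigurationError("trajectory length must be whole years")
    horizon = n_days // DAYS_PER_YEAR
    # the series is piecewise constant per policy year by construction
    net_by_year = delta[1:].reshape(horizon, DAYS_PER_YEAR)[:, 0][None, :]
    row = pd.DataFrame(
        {
            "id": [_get(individual, "id") if _has(individual, "id") else 0],
            "sex": [_get(individual, "sex")],
            "age": [float(_get(individual, "age"))],
            "height": [float(_get(individual, "height"))],
            "weight": [float(_get(individual, "weight"))],
            "tei_init": [float(_get(individual, "tei_init"))],
        }
    )
    carb_frac = float(getattr(trajectory, "carb_fraction_of_change", 1.0))
    if method == "adaptive":
        return _simulate_adaptive(row, net_by_year, carb_frac, params)
    if method != "rk4":
        raise ConfigurationError(f"unknown method {method!r}")
    fat, lean, gly, ecf = initial_state(
        row["sex"], row["age"], row["height"], row["weight"], params,
    )
    out = _run_population(
        fat, lean, gly, ecf, row["tei_init"].to_numpy(dtype=float),
        row["id"].to_numpy(), net_by_year, carb_frac, params, dt,
        record_daily=True,
    )
    weight = out["daily_weight"][:, 0]
    days = np.arange(len(weight))
    h = float(row["height"].iloc[0])
    return WeightTrajectory(
        days=days,
        weight=weight,
        final_bmi=float(weight[-1] / h**2),
        delta_weight=float(weight[-1] - weight[0]),
    )


def _has(obj, key) -> bool:
    try:
        _get(obj, key)
        return True
    except (AttributeError, KeyError):
        return False


def _simulate_adaptive(row, net_by_year, carb_fraction, params: ModelParams):
    from scipy.integrate import solve_ivp

    fat, lean, gly, ecf = initial_state(
        row["sex"], row["age"], row["height"], row["weight"], params,
    )
    tei = row["tei_init"].to_numpy(dtype=float)
    k = _calibrate_k(
        fat, lean, fat + lean + gly * (1.0 + params.hydration_ratio) + ecf,
        tei, params,
    )
    ec_b = ecf.astype(float).copy()
    levels = net_by_year[0]
    horizon = len(levels)

    def rhs(t, y):
        year = min(int(t) // DAYS_PER_YEAR, horizon - 1)
        dEI = np.array([levels[year]])
        d = _derivs(
            y[0:1], y[1:2], y[2:3], y[3:4], y[4:5],
            tei + dEI, dEI, carb_fraction * dEI, k, tei, ec_b, params,
        )
        return np.concatenate(d[:5])

    y0 = np.concatenate([fat, lean, gly, ecf, [0.0]])
    t_eval = np.arange(horizon * DAYS_PER_YEAR + 1, dtype=float)
    sol = solve_ivp(
        rhs, (0.0, t_eval[-1]), y0, method="LSODA",
        t_eval=t_eval, max_step=float(DAYS_PER_YEAR),
        rtol=1e-8, atol=1e-8,
    )
    if not sol.success:
        raise IntegrationError(f"adaptive integration failed: {sol.message}")
    weight = (
        sol.y[0] + sol.y[1] + sol.y[2] * (1.0 + params.hydration_ratio) + sol.y[3]
    )
    h = float(row["height"].iloc[0])
    return WeightTrajectory(
        days=t_eval.astype(int),
        weight=weight,
        final_bmi=float(weight[-1] / h**2),
        delta_weight=float(weight[-1] - weight[0]),
    )
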