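"""Adult dynamic energy-balance (Hall) model of body-weight change.

The model tracks fat mass F, lean mass L, glycogen G (with bound water),
extracellular fluid ECF, and an adaptive-thermogenesis term AT under a
sustained change in energy intake.  Energy expenditure responds to body
composition (regression slopes gamma_F, gamma_L), to physical activity
(delta * BW, with delta set by the baseline PAL), to the thermic effect of
food and to adaptive thermogenesis; the energy imbalance is partitioned
between lean and fat tissue along the Forbes body-composition curve
(dL/dF = 10.4/F), giving an energy share to lean of
p = C/(C + F) with C = 10.4 rho_L / rho_F (~2 kg), with biochemical
deposition costs eta_F, eta_L.  Body weight is the sum of fat mass and the
fat-free components:

    dG/dt   = (CI - k G^2) / rho_G,           k = CI_b / G_b^2
    dAT/dt  = (beta_AT dEI - AT) / tau_AT
    dECF/dt = -(xi_Na (ECF - ECF_b) + xi_CI (1 - CI/CI_b)) / [Na]
    rho_F dF/dt + rho_L dL/dt = EI - EE - rho_G dG/dt
    dL/dt : dF/dt given by p : (1 - p) in energy terms

Each person is initialised at energy balance: baseline intake equals
PAL x RMR (Mifflin-St Jeor), the constant expenditure offset K absorbs the
baseline terms, so a zero intake change gives an exactly flat trajectory.

Integration is deterministic fixed-step classical Runge-Kutta (RK4) at
dt = 1 day, vectorised across the whole cohort; the dynamics are smooth
with time constants from ~1 day (glycogen, fluid) to ~1 year (fat), for
which this is accurate to well under 0.01 kg over 10 years (verified in
tests against an adaptive solver and a fine-step Euler oracle).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .reference import hall_constants

DAYS_PER_YEAR = 365


@dataclass
class BodyState:
    """Vectorised model state plus per-person baseline quantities."""

    fat: np.ndarray
    lean: np.ndarray
    glycogen: np.ndarray
    ecf: np.ndarray
    at: np.ndarray  # adaptive thermogenesis, kcal/day
    # frozen baseline quantities
    ei_baseline: np.ndarray
    k_const: np.ndarray
    delta_pa: np.ndarray  # physical-activity coefficient, kcal/kg/day
    ecf_baseline: np.ndarray
    height: np.ndarray

    @property
    def n(self) -> int:
        return len(self.fat)

    def body_weight(self, params: dict | None = None) -> np.ndarray:
        c = params or hall_constants()
        return self.fat + self.lean + (1.0 + c["hydration_G"]) * self.glycogen + self.ecf


@dataclass
class Trajectory:
    """Weight/BMI series on a day grid for a cohort."""

    days: np.ndarray  # (T,)
    weight: np.ndarray  # (n, T) kg
    height: np.ndarray  # (n,) m
    #: stacked [F, L, G, ECF, AT] state at the end of the horizon
    final_state: np.ndarray | None = None

    @property
    def bmi(self) -> np.ndarray:
        return self.weight / self.height[:, None] ** 2

    def weight_change(self) -> np.ndarray:
        """Final minus initial weight per person."""
        return self.weight[:, -1] - self.weight[:, 0]


def resting_metabolic_rate(sex, age, weight, height) -> np.ndarray:
    """Mifflin-St Jeor RMR in kcal/day (height in meters)."""
    c = hall_constants()["rmr"]
    sex = np.asarray(sex)
    inter = np.where(sex == "male", c["intercept_male"], c["intercept_female"])
    return (
        c["weight_coef"] * np.asarray(weight, float)
        + c["height_coef"] * np.asarray(height, float) * 100.0
        + c["age_coef"] * np.asarray(age, float)
        + inter
    )


def initial_fat_mass(sex, age, weight, height) -> np.ndarray:
    """Baseline fat mass from the sex-specific body-fat regression."""
    c = hall_constants()["fat_init"]
    sex = np.asarray(sex)
    b = np.asarray(weight, float) / np.asarray(height, float) ** 2
    coef = np.where(sex == "male", c["log_bmi_coef_male"], c["log_bmi_coef_female"])
    inter = np.where(sex == "male", c["intercept_male"], c["intercept_female"])
    frac = (c["age_coef"] * np.asarray(age, float) + coef * np.log(b) + inter) / 100.0
    return np.clip(frac, 0.05, 0.60) * np.asarray(weight, float)


def initialize_state(sex, age, weight, height, pal: float | np.ndarray | None = None) -> BodyState:
    """Initialise a cohort at energy balance.

    Baseline intake is PAL-scaled RMR; the expenditure constant K is solved
    so that expenditure equals intake at the initial composition.
    """
    c = hall_constants()
    sex = np.atleast_1d(np.asarray(sex))
    age = np.atleast_1d(np.asarray(age, float))
    weight = np.atleast_1d(np.asarray(weight, float))
    height = np.atleast_1d(np.asarray(height, float))
    if pal is None:
        pal = c["pal_default"]
    pal = np.broadcast_to(np.asarray(pal, float), weight.shape).copy()

    for name, arr, lo, hi in (
        ("age", age, 18.0, 105.0),
        ("weight", weight, 30.0, 250.0),
        ("height", height, 1.2, 2.2),
        ("pal", pal, 1.0, 2.5),
    ):
        if np.any(arr < lo) or np.any(arr > hi):
            raise ValidationError(f"'{name}' outside plausible adult range [{lo}, {hi}]")

    fat = initial_fat_mass(sex, age, weight, height)
    g0 = np.full_like(weight, c["glycogen_init"])
    # extracellular fluid ~45% of total body water (60%/50% of BW by sex)
    tbw_frac = np.where(sex == "male", 0.60, 0.50)
    ecf = 0.45 * tbw_frac * weight
    lean = weight - fat - (1.0 + c["hydration_G"]) * g0 - ecf
    if np.any(lean <= 0):
        raise ValidationError("non-positive lean mass at initialisation")

    rmr = resting_metabolic_rate(sex, age, weight, height)
    ei_b = pal * rmr
    delta_pa = ((1.0 - c["beta_TEF"]) * pal - 1.0) * rmr / weight
    k_const = ei_b - c["gamma_F"] * fat - c["gamma_L"] * lean - delta_pa * weight
    return BodyState(
        fat=fat,
        lean=lean,
        glycogen=g0,
        ecf=ecf,
        at=np.zeros_like(weight),
        ei_baseline=ei_b,
        k_const=k_const,
        delta_pa=delta_pa,
        ecf_baseline=ecf.copy(),
        height=height,
    )


def derivatives(y: np.ndarray, state: BodyState, delta_ei: np.ndarray) -> np.ndarray:
    """Time derivative of the stacked state array y = [F, L, G, ECF, AT]."""
    c = hall_constants()
    F, L, G, ECF, AT = y
    ei = state.ei_baseline + delta_ei
    ci_b = c["carb_fraction"] * state.ei_baseline
    ci = c["carb_fraction"] * ei
    k_g = ci_b / c["glycogen_init"] ** 2

    dG = (ci - k_g * G**2) / c["rho_G"]
    dAT = (c["beta_AT"] * delta_ei - AT) / c["tau_AT"]
    dECF = -(c["xi_Na"] * (ECF - state.ecf_baseline) + c["xi_CI"] * (1.0 - ci / ci_b)) / c[
        "na_concentration"
    ]

    bw = F + L + (1.0 + c["hydration_G"]) * G + ECF
    forbes_c = c["forbes_mass_C"] * c["rho_L"] / c["rho_F"]
    p = forbes_c / (forbes_c + F)
    avail = (
        ei
        - state.k_const
        - c["gamma_F"] * F
        - c["gamma_L"] * L
        - state.delta_pa * bw
        - c["beta_TEF"] * delta_ei
        - AT
        - c["rho_G"] * dG
    )
    psi = avail / (1.0 + c["eta_F"] * (1.0 - p) / c["rho_F"] + c["eta_L"] * p / c["rho_L"])
    dF = (1.0 - p) * psi / c["rho_F"]
    dL = p * psi / c["rho_L"]
    return np.stack([dF, dL, dG, dECF, dAT])


def energy_imbalance(y: np.ndarray, state: BodyState, delta_ei: np.ndarray) -> np.ndarray:
    """Residual rate of stored energy change (kcal/day) at state y."""
    c = hall_constants()
    d = derivatives(y, state, delta_ei)
    return c["rho_F"] * d[0] + c["rho_L"] * d[1] + c["rho_G"] * d[2]


def simulate_population(
    state: BodyState,
    delta_kcal,
    horizon_days: int = 10 * DAYS_PER_YEAR,
    dt: float = 1.0,
    output_days: np.ndarray | None = None,
) -> Trajectory:
    """Integrate the cohort under a sustained intake change of `delta_kcal`/day.

    `delta_kcal` is scalar or per-person; the change is applied as a step at
    t = 0 and held.  Deterministic; output on `output_days` (default daily).
    """
    delta = np.broadcast_to(np.asarray(delta_kcal, float), (state.n,))
    if not np.all(np.isfinite(delta)):
        raise ValidationError("delta_kcal must be finite")
    if output_days is None:
        output_days = np.arange(0, horizon_days + 1)
    output_days = np.asarray(output_days)

    c = hall_constants()
    y = np.stack([state.fat, state.lean, state.glycogen, state.ecf, state.at])
    hyd = 1.0 + c["hydration_G"]

    n_steps = int(round(horizon_days / dt))
    out = np.empty((state.n, len(output_days)))
    out_idx = {int(d): j for j, d in enumerate(output_days)}

    def record(day_float):
        j = out_idx.get(int(round(day_float)))
        if j is not None and abs(day_float - round(day_float)) < 1e-9:
            out[:, j] = y[0] + y[1] + hyd * y[2] + y[3]

    record(0.0)
    t = 0.0
    for _ in range(n_steps):
        k1 = derivatives(y, state, delta)
        k2 = derivatives(y + 0.5 * dt * k1, state, delta)
        k3 = derivatives(y + 0.5 * dt * k2, state, delta)
        k4 = derivatives(y + dt * k3, state, delta)
        y = y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        t += dt
        record(t)
    if not np.all(np.isfinite(y)):
        raise ValidationError("non-finite state during integration (check inputs)")
    return Trajectory(days=output_days, weight=out, height=state.height, final_state=y)


def simulate_individual(
    state: BodyState, delta_kcal: float, horizon_days: int = 10 * DAYS_PER_YEAR, dt: float = 1.0
) -> Trajectory:
    """Single-person convenience wrapper around :func:`simulate_population`."""
    return simulate_population(state, delta_kcal, horizon_days, dt)


def simulate_groups(
    groups,
    horizon_days: int = 10 * DAYS_PER_YEAR,
    expected_groups: int = 14,
) -> "object":
    """Aggregated sensitivity mode: run the model on group-average persons.

    `groups` is a DataFrame with columns sex, age, weight, height,
    delta_kcal (one row per sex x age x SES group).  Returns the frame with
    a `weight_change_kg` column (10-year change of the group-average
    individual).  A group count different from the conventional 14 only
    warns — the grouping scheme is configurable.
    """
    import warnings

    import pandas as pd

    groups = pd.DataFrame(groups)
    if len(groups) != expected_groups:
        warnings.warn(
            f"{len(groups)} groups supplied (conventional scheme has {expected_groups})",
            stacklevel=2,
        )
    st = initialize_state(
        groups["sex"].to_numpy(),
        groups["age"].to_numpy(float),
        groups["weight"].to_numpy(float),
        groups["height"].to_numpy(float),
    )
    traj = simulate_population(
        st,
        groups["delta_kcal"].to_numpy(float),
        horizon_days,
        output_days=np.array([0, horizon_days]),
    )
    out = groups.copy()
    out["weight_change_kg"] = traj.weight_change()
    return out
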