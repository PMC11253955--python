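"""Dynamic energy-balance model: equilibrium, oracles, monotonicity."""

import numpy as np
import pandas as pd
import pytest

from ssbtax import hall
from ssbtax.errors import ValidationError


@pytest.fixture(scope="module")
def two_adults():
    return hall.initialize_state(
        ["female", "male"], [40.0, 40.0], [68.0, 77.0], [1.585, 1.715]
    )


class TestInitialization:
    def test_equilibrium_by_construction(self, two_adults):
        traj = hall.simulate_population(
            two_adults, 0.0, 3650, output_days=np.array([0, 1825, 3650])
        )
        assert np.abs(traj.weight - traj.weight[:, [0]]).max() < 0.2

    def test_identical_inputs_identical_states(self):
        a = hall.initialize_state("male", 30.0, 80.0, 1.75)
        b = hall.initialize_state("male", 30.0, 80.0, 1.75)
        np.testing.assert_array_equal(a.fat, b.fat)
        np.testing.assert_array_equal(a.ei_baseline, b.ei_baseline)

    def test_fat_mass_increases_with_bmi(self):
        weights = np.arange(50.0, 121.0, 5.0)
        st = hall.initialize_state(
            ["female"] * len(weights), [40.0] * len(weights), weights, [1.60] * len(weights)
        )
        assert (np.diff(st.fat) > 0).all()

    def test_women_carry_more_fat_at_same_bmi(self):
        st = hall.initialize_state(["female", "male"], [40, 40], [70.0, 70.0], [1.65, 1.65])
        assert st.fat[0] > st.fat[1]

    def test_out_of_range_anthropometry_rejected(self):
        with pytest.raises(ValidationError, match="weight"):
            hall.initialize_state("male", 30.0, 400.0, 1.75)
        with pytest.raises(ValidationError, match="height"):
            hall.initialize_state("male", 30.0, 80.0, 0.9)

    def test_baseline_intake_is_pal_times_rmr(self):
        st = hall.initialize_state("male", 30.0, 80.0, 1.75, pal=1.5)
        rmr = hall.resting_metabolic_rate("male", 30.0, 80.0, 1.75)
        assert st.ei_baseline[0] == pytest.approx(1.5 * float(rmr))


class TestIntegration:
    def test_euler_oracle_agreement(self, two_adults):
        """RK4 at dt=1 d matches brute-force Euler at dt=0.1 d within 0.01 kg."""
        horizon = 3650
        marks = np.arange(0, horizon + 1, 365)
        traj = hall.simulate_population(two_adults, -17.3, horizon, output_days=marks)

        y = np.stack(
            [
                two_adults.fat,
                two_adults.lean,
                two_adults.glycogen,
                two_adults.ecf,
                two_adults.at,
            ]
        )
        dt = 0.1
        delta = np.full(two_adults.n, -17.3)
        euler = [y[0] + y[1] + 3.7 * y[2] + y[3]]
        for step in range(int(horizon / dt)):
            y = y + dt * hall.derivatives(y, two_adults, delta)
            if (step + 1) % 3650 == 0:
                euler.append(y[0] + y[1] + 3.7 * y[2] + y[3])
        euler = np.array(euler).T
        np.testing.assert_allclose(traj.weight, euler, atol=0.01)

    def test_adaptive_solver_agreement(self, two_adults):
        """Independent adaptive integration (scipy RK45) agrees within 0.01 kg."""
        from scipy.integrate import solve_ivp

        delta = np.full(two_adults.n, -30.0)
        y0 = np.concatenate(
            [
                two_adults.fat,
                two_adults.lean,
                two_adults.glycogen,
                two_adults.ecf,
                two_adults.at,
            ]
        )
        n = two_adults.n

        def rhs(t, y):
            return hall.derivatives(y.reshape(5, n), two_adults, delta).ravel()

        sol = solve_ivp(rhs, (0, 3650), y0, max_step=1.0, rtol=1e-8, atol=1e-10)
        yf = sol.y[:, -1].reshape(5, n)
        w_scipy = yf[0] + yf[1] + 3.7 * yf[2] + yf[3]
        traj = hall.simulate_population(
            two_adults, -30.0, 3650, output_days=np.array([0, 3650])
        )
        np.testing.assert_allclose(traj.weight[:, -1], w_scipy, atol=0.01)

    def test_weight_change_monotone_in_deficit(self, two_adults):
        mags = []
        for d in (-5.0, -10.0, -20.0, -40.0):
            traj = hall.simulate_population(
                two_adults, d, 3650, output_days=np.array([0, 3650])
            )
            mags.append(-traj.weight_change().mean())
        assert all(b > a for a, b in zip(mags, mags[1:]))

    def test_energy_conservation_at_steady_state(self, two_adults):
        """At year 10 the sustained deficit is offset by expenditure change."""
        for d in (-10.0, -50.0):
            traj = hall.simulate_population(
                two_adults, d, 3650, output_days=np.array([0, 3650])
            )
            resid = hall.energy_imbalance(
                traj.final_state, two_adults, np.full(two_adults.n, d)
            )
            assert np.abs(resid).max() < 1.0

    def test_scale_sanity_weight_per_kcal(self):
        """10-yr response per kcal/day within the physiological bracket."""
        st = hall.initialize_state(
            ["female", "male", "female", "male"],
            [25.0, 35.0, 55.0, 70.0],
            [55.0, 95.0, 70.0, 85.0],
            [1.55, 1.80, 1.60, 1.70],
        )
        traj = hall.simulate_population(st, -17.3, 3650, output_days=np.array([0, 3650]))
        per_kcal = traj.weight_change() / -17.3
        assert (per_kcal > 0.02).all() and (per_kcal < 0.07).all()

    def test_nonfinite_delta_rejected(self, two_adults):
        with pytest.raises(ValidationError):
            hall.simulate_population(two_adults, np.nan, 365)

    def test_single_individual_equals_population_member(self, two_adults):
        solo = hall.initialize_state("female", 40.0, 68.0, 1.585)
        t_solo = hall.simulate_individual(solo, -17.3, 365)
        t_pop = hall.simulate_population(two_adults, -17.3, 365)
        np.testing.assert_allclose(t_solo.weight[0], t_pop.weight[0], atol=1e-10)

    def test_permutation_equivariance(self):
        st = hall.initialize_state(
            ["female", "male", "male"], [30, 45, 60], [60.0, 80.0, 90.0], [1.6, 1.7, 1.8]
        )
        perm = [2, 0, 1]
        st_p = hall.initialize_state(
            np.array(["female", "male", "male"])[perm],
            np.array([30.0, 45.0, 60.0])[perm],
            np.array([60.0, 80.0, 90.0])[perm],
            np.array([1.6, 1.7, 1.8])[perm],
        )
        t = hall.simulate_population(st, -20.0, 365, output_days=np.array([0, 365]))
        t_p = hall.simulate_population(st_p, -20.0, 365, output_days=np.array([0, 365]))
        np.testing.assert_allclose(t.weight[perm], t_p.weight, atol=1e-12)


class TestGroupMode:
    def test_single_group_zero_delta(self):
        g = pd.DataFrame(
            [{"sex": "female", "age": 40.0, "weight": 68.0, "height": 1.585, "delta_kcal": 0.0}]
        )
        with pytest.warns(UserWarning, match="groups"):
            out = hall.simulate_groups(g)
        assert out["weight_change_kg"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_group_results_within_microsimulation_cis(self):
        """Aggregated 14-group mode is consistent with the individual model."""
        from ssbtax import synthetic
        from ssbtax.categories import age_group

        cfg = synthetic.IndividualConfig(n_individuals=1500, seed=77)
        cohort = synthetic.generate_individuals(cfg)
        delta = -0.2 * 1.2 * cohort["kcal_ssb"].to_numpy()  # ~20% tax, elastic
        st = hall.initialize_state(
            cohort["sex"].to_numpy(),
            cohort["age"].to_numpy(),
            cohort["weight_true"].to_numpy(),
            cohort["height_true"].to_numpy(),
        )
        traj = hall.simulate_population(st, delta, 3650, output_days=np.array([0, 3650]))
        change = traj.weight_change()

        cohort = cohort.assign(change=change, delta=delta, band=[age_group(a) for a in cohort["age"]])
        # younger bands split by SES tertile, 60+ pooled: 2 x (2x3 + 1) = 14 groups
        ses = cohort["income_tertile"].astype(str)
        cohort["ses"] = np.where(cohort["band"] == "60+", "all", ses)
        grouped = cohort.groupby(["sex", "band", "ses"], observed=True)
        groups = grouped.agg(
            age=("age", "mean"),
            weight=("weight_true", "mean"),
            height=("height_true", "mean"),
            delta_kcal=("delta", "mean"),
        ).reset_index()
        assert len(groups) == 14
        agg = hall.simulate_groups(groups)

        rng = np.random.default_rng(3)
        hits = 0
        for i, (key, g) in enumerate(grouped):
            x = g["change"].to_numpy()
            boots = x[rng.integers(0, len(x), (500, len(x)))].mean(axis=1)
            lo, hi = np.quantile(boots, [0.025, 0.975])
            if lo <= agg["weight_change_kg"].iloc[i] <= hi:
                hits += 1
        assert hits >= 12
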