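"""Unit values, price imputation and elasticity regressions."""

import numpy as np
import pandas as pd
import pytest

from ssbtax import demand, synthetic
from ssbtax.categories import ALL_CATEGORIES
from ssbtax.errors import EstimationError, ValidationError


def _mini_purchases(qty, exp, state=None, metro=None):
    n = len(qty)
    return pd.DataFrame(
        {
            "household_id": range(n),
            "qty_ssb": qty,
            "exp_ssb": exp,
            "state": state if state is not None else [0] * n,
            "metro": metro if metro is not None else [0] * n,
        }
    )


class TestUnitValues:
    def test_price_is_expenditure_over_quantity(self):
        df = _mini_purchases([10.0, 5.0], [30.0, 20.0])
        prices = demand.unit_values(df, categories=("ssb",))
        assert prices["price_ssb"].tolist() == [3.0, 4.0]

    def test_zero_quantity_gives_missing_not_zero_or_inf(self):
        df = _mini_purchases([0.0, 5.0], [0.0, 20.0])
        prices = demand.unit_values(df, categories=("ssb",))
        assert np.isnan(prices["price_ssb"].iloc[0])

    def test_scale_invariance(self):
        df1 = _mini_purchases([10.0, 5.0], [30.0, 20.0])
        df2 = _mini_purchases([20.0, 10.0], [60.0, 40.0])
        p1 = demand.unit_values(df1, categories=("ssb",))
        p2 = demand.unit_values(df2, categories=("ssb",))
        pd.testing.assert_series_equal(p1["price_ssb"], p2["price_ssb"])

    def test_all_zero_category_is_error(self):
        df = _mini_purchases([0.0, 0.0], [0.0, 0.0])
        with pytest.raises(ValidationError, match="ssb"):
            demand.unit_values(df, categories=("ssb",))


class TestImputePrices:
    def test_same_region_median(self):
        # three observed prices {2, 3, 10} in the household's metro -> median 3
        df = _mini_purchases([0.0, 1, 1, 1], [0.0, 2, 3, 10])
        prices = demand.unit_values(df, categories=("ssb",))
        full = demand.impute_prices(prices, df, min_obs=3, categories=("ssb",))
        assert full["price_ssb"].iloc[0] == 3.0

    def test_escalates_to_national_median(self):
        # no observed price in state 0 -> national median of the other state
        df = _mini_purchases(
            [0.0, 1, 1, 1], [0.0, 4, 5, 6], state=[0, 1, 1, 1], metro=[0, 0, 0, 1]
        )
        prices = demand.unit_values(df, categories=("ssb",))
        full = demand.impute_prices(prices, df, min_obs=5, categories=("ssb",))
        assert full["price_ssb"].iloc[0] == 5.0

    def test_metro_preferred_over_state(self):
        df = _mini_purchases(
            [0.0, 1, 1, 1, 1, 1],
            [0.0, 7, 7, 2, 2, 2],
            state=[0, 0, 0, 0, 0, 0],
            metro=[0, 0, 0, 1, 1, 1],
        )
        prices = demand.unit_values(df, categories=("ssb",))
        full = demand.impute_prices(prices, df, min_obs=2, categories=("ssb",))
        assert full["price_ssb"].iloc[0] == 7.0

    def test_identity_when_complete(self, households_small):
        cfg = synthetic.HouseholdConfig(
            n_households=200, seed=1, zero_purchase_prob={c: 0.0 for c in ALL_CATEGORIES}
        )
        hh = synthetic.generate_households(cfg)
        prices = demand.unit_values(hh)
        full = demand.impute_prices(prices, hh)
        pd.testing.assert_frame_equal(prices, full)


class TestFitDemand:
    def test_matches_normal_equations_on_small_fixture(self, rng):
        """Unweighted, non-interacted fit equals a direct linear-algebra solve."""
        n = 80
        cfg = synthetic.HouseholdConfig(
            n_households=n,
            seed=21,
            zero_purchase_prob={c: 0.0 for c in ALL_CATEGORIES},
        )
        hh = synthetic.generate_households(cfg)
        hh["survey_weight"] = 1.0
        spec = demand.ElasticitySpec(tertile_interaction=False, cov_type="HC1")
        row = demand.fit_demand(hh, spec).iloc[0]

        prices = demand.unit_values(hh)
        df = hh.merge(prices, on="household_id")
        X = np.column_stack(
            [np.ones(n)]
            + [np.log(df[f"price_{c}"]) for c in ALL_CATEGORIES]
            + [df["income_pc"], df["income_pc"] ** 2]
            + [df[c].astype(float) for c in spec.controls]
        )
        beta = np.linalg.solve(X.T @ X, X.T @ np.log(df["qty_ssb"]))
        assert row["elasticity"] == pytest.approx(beta[1], abs=1e-8)

    def test_null_elasticity_when_quantity_ignores_price(self):
        cfg = synthetic.HouseholdConfig(
            n_households=6000,
            seed=31,
            own_elasticity_by_tertile=(0.0, 0.0, 0.0),
            cross_elasticities={},
        )
        hh = synthetic.generate_households(cfg)
        tab = demand.fit_demand(hh, demand.ElasticitySpec(cov_type="HC1"))
        z = tab["elasticity"] / tab["se"]
        assert (z.abs() < 3).all()

    def test_recovers_embedded_elasticities(self):
        cfg = synthetic.HouseholdConfig(n_households=8000, seed=41)
        hh = synthetic.generate_households(cfg)
        tab = demand.fit_demand(hh, demand.ElasticitySpec(cov_type="HC1"))
        truth = np.array(cfg.own_elasticity_by_tertile)
        z = (tab["elasticity"].to_numpy() - truth) / tab["se"].to_numpy()
        assert (np.abs(z) < 3).all()

    def test_zero_quantity_households_excluded(self, households_small):
        tab = demand.fit_demand(households_small, demand.ElasticitySpec(cov_type="HC1"))
        n_pos = int((households_small["qty_ssb"] > 0).sum())
        assert tab["n_observations"].iloc[0] == n_pos

    def test_collinear_prices_raise(self, households_small):
        hh = households_small.copy()
        # make the diet price identical to the unsweetened price
        hh["qty_diet"] = hh["qty_unsweetened"]
        hh["exp_diet"] = hh["exp_unsweetened"]
        with pytest.raises(EstimationError, match="collinear"):
            demand.fit_demand(hh, demand.ElasticitySpec(cov_type="HC1"))

    def test_too_few_rows_raise(self, households_small):
        with pytest.raises(EstimationError):
            demand.fit_demand(households_small.head(20), demand.ElasticitySpec())

    def test_single_tertile_spec_collapses_to_basic_regression(self, households_small):
        tab = demand.fit_demand(
            households_small,
            demand.ElasticitySpec(tertile_interaction=False, cov_type="HC1"),
        )
        assert len(tab) == 1
        assert tab["tertile"].isna().all()

    def test_cluster_spec_warns_on_few_clusters(self, households_small):
        with pytest.warns(UserWarning, match="clusters"):
            demand.fit_demand(households_small, demand.ElasticitySpec())

    def test_invalid_dependent_category(self):
        with pytest.raises(ValidationError):
            demand.ElasticitySpec(dependent_category="fruits")


class TestElasticityMatrix:
    def test_four_categories_three_tertiles(self, households_small):
        tab = demand.elasticity_matrix(
            households_small, demand.ElasticitySpec(cov_type="HC1")
        )
        assert len(tab) == 12
        assert set(tab["category"]) == {"ssb", "unsweetened", "alcoholic", "diet"}

    def test_cross_elasticity_sign_recovered(self):
        """A positive embedded substitution effect is estimated as positive."""
        cfg = synthetic.HouseholdConfig(
            n_households=12_000,
            seed=51,
            cross_elasticities={"unsweetened": (0.3, 0.3, 0.3)},
        )
        hh = synthetic.generate_households(cfg)
        import dataclasses

        spec = dataclasses.replace(
            demand.ElasticitySpec(cov_type="HC1"), dependent_category="unsweetened"
        )
        tab = demand.fit_demand(hh, spec)
        assert (tab["elasticity"] > 0).all()
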