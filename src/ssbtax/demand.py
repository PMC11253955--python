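"""Price-elasticity estimation from household purchase data.

Unit values (expenditure / quantity) serve as implicit prices; a household
that bought nothing in a category has no price, and gets the median price
of the smallest enclosing region with enough observations (metro area
within state, then state, then national).  Elasticities come from
survey-weighted log-log demand regressions per beverage category, with all
11 category log prices as regressors — interacted with income-tertile
indicators — plus income, squared income and household controls.  The
coefficient on log(SSB price) x tertile is the (own or cross) elasticity
with respect to the SSB price.

Households with zero purchases of the *dependent* category are excluded
from that category's regression (log of zero is undefined); imputed prices
mean they still contribute as price observations to other regressions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .categories import ALL_CATEGORIES, BEVERAGE_CATEGORIES, TAXED_CATEGORY, TERTILES
from .errors import EstimationError, ValidationError

DEFAULT_CONTROLS = (
    "head_gender",
    "head_schooling",
    "head_race",
    "head_marital",
    "n_members",
    "n_children",
)


@dataclass
class ElasticitySpec:
    """Specification of one demand regression."""

    dependent_category: str = TAXED_CATEGORY
    price_categories: tuple[str, ...] = ALL_CATEGORIES
    tertile_interaction: bool = True
    controls: tuple[str, ...] = DEFAULT_CONTROLS
    #: "cluster" reproduces the published analysis (SES clusters; fragile with
    #: 3 groups, a warning is raised); "HC1" gives heteroskedasticity-robust SEs
    cov_type: str = "cluster"
    cluster_variable: str = "income_tertile"  # SES, as in the reference analysis
    weight_variable: str = "survey_weight"
    #: include income as levels + quadratic (default) or as log income
    income_in_logs: bool = False
    #: minimum observations per region cell for the price-imputation median
    impute_min_obs: int = 5

    def __post_init__(self):
        if self.dependent_category not in BEVERAGE_CATEGORIES:
            raise ValidationError(
                f"dependent_category must be one of {BEVERAGE_CATEGORIES}, "
                f"got '{self.dependent_category}'"
            )


# ---------------------------------------------------------------------------
# prices
# ---------------------------------------------------------------------------


def unit_values(purchases: pd.DataFrame, categories=ALL_CATEGORIES) -> pd.DataFrame:
    """Implicit prices: expenditure / quantity per household and category.

    Zero-quantity cells are NaN (no price observed, never 0 or inf).
    Raises if a category has no positive quantity anywhere (no price
    information at all).
    """
    out = purchases[["household_id"]].copy()
    for cat in categories:
        qty = purchases[f"qty_{cat}"].to_numpy(float)
        exp = purchases[f"exp_{cat}"].to_numpy(float)
        if np.any(qty < 0) or np.any(exp < 0):
            raise ValidationError(f"negative quantity or expenditure in '{cat}'")
        if not np.any(qty > 0):
            raise ValidationError(f"category '{cat}' has zero purchases in every household")
        with np.errstate(divide="ignore", invalid="ignore"):
            price = np.where(qty > 0, exp / qty, np.nan)
        out[f"price_{cat}"] = price
    return out


def impute_prices(
    prices: pd.DataFrame,
    regions: pd.DataFrame,
    min_obs: int = 5,
    categories=ALL_CATEGORIES,
) -> pd.DataFrame:
    """Fill missing prices by enclosing-region medians.

    For each category the median observed price is taken over the smallest
    region level with at least `min_obs` observations: metro area within
    state, then state, then the national median.
    """
    df = prices.merge(regions[["household_id", "state", "metro"]], on="household_id")
    out = prices.copy()
    key = pd.MultiIndex.from_arrays([df["state"], df["metro"]])
    for cat in categories:
        col = f"price_{cat}"
        s = df[col]
        if s.notna().all():
            continue
        obs = df[s.notna()]
        metro_med = obs.groupby(["state", "metro"])[col].agg(["median", "size"])
        metro_ok = metro_med.loc[metro_med["size"] >= min_obs, "median"]
        state_med = obs.groupby("state")[col].agg(["median", "size"])
        state_ok = state_med.loc[state_med["size"] >= min_obs, "median"]
        national = obs[col].median()

        fill = pd.Series(key.map(metro_ok), index=df.index)
        fill = fill.fillna(df["state"].map(state_ok)).fillna(national)
        out[col] = s.fillna(fill).to_numpy()
    return out


# ---------------------------------------------------------------------------
# regression
# ---------------------------------------------------------------------------


def _build_design(
    df: pd.DataFrame, spec: ElasticitySpec
) -> tuple[pd.DataFrame, pd.Series]:
    """Design matrix (with intercept) and log-quantity response."""
    y = np.log(df[f"qty_{spec.dependent_category}"])
    X = pd.DataFrame(index=df.index)
    X["const"] = 1.0
    for cat in spec.price_categories:
        lp = np.log(df[f"price_{cat}"])
        if spec.tertile_interaction:
            for t in TERTILES:
                X[f"lp_{cat}_t{t}"] = lp * (df["income_tertile"] == t)
        else:
            X[f"lp_{cat}"] = lp
    if spec.income_in_logs:
        linc = np.log(df["income_pc"])
        X["inc"] = linc
        X["inc2"] = linc**2
    else:
        X["inc"] = df["income_pc"]
        X["inc2"] = df["income_pc"] ** 2
    for c in spec.controls:
        X[c] = df[c].astype(float)
    return X, y


def fit_demand(
    purchases: pd.DataFrame,
    spec: ElasticitySpec,
    prices: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Estimate the elasticity of one beverage category w.r.t. the SSB price.

    Returns one row per tertile (or a single row when the spec has no
    tertile interaction) with columns: category, tertile, elasticity, se,
    p_value, n_observations.  A precomputed complete price table can be
    passed to avoid re-imputation.
    """
    if prices is None:
        prices = unit_values(purchases, spec.price_categories)
        prices = impute_prices(
            prices, purchases, spec.impute_min_obs, spec.price_categories
        )
    df = purchases.merge(prices, on="household_id")
    df = df[df[f"qty_{spec.dependent_category}"] > 0]

    X, y = _build_design(df, spec)
    n, p = X.shape
    if n <= p:
        raise EstimationError(
            f"{n} observations for {p} parameters in '{spec.dependent_category}' regression"
        )
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < p:
        _, r = np.linalg.qr(X.to_numpy())
        bad = [X.columns[j] for j in range(p) if abs(r[j, j]) < 1e-8 * abs(r).max()]
        raise EstimationError(f"collinear price regressors: {bad}")

    w = df[spec.weight_variable]
    if (w <= 0).any():
        raise ValidationError("survey weights must be positive")
    model = sm.WLS(y, X, weights=w)
    if spec.cov_type == "cluster":
        groups = df[spec.cluster_variable]
        if groups.nunique() < 10:
            warnings.warn(
                f"only {groups.nunique()} clusters on '{spec.cluster_variable}'; "
                "cluster-robust standard errors are fragile with so few clusters",
                stacklevel=2,
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # statsmodels df-correction chatter
            res = model.fit(cov_type="cluster", cov_kwds={"groups": groups})
    else:
        res = model.fit(cov_type=spec.cov_type)

    rows = []
    if spec.tertile_interaction:
        for t in TERTILES:
            name = f"lp_{TAXED_CATEGORY}_t{t}"
            rows.append(
                {
                    "category": spec.dependent_category,
                    "tertile": t,
                    "elasticity": res.params[name],
                    "se": res.bse[name],
                    "p_value": res.pvalues[name],
                    "n_observations": int(n),
                }
            )
    else:
        name = f"lp_{TAXED_CATEGORY}"
        rows.append(
            {
                "category": spec.dependent_category,
                "tertile": pd.NA,
                "elasticity": res.params[name],
                "se": res.bse[name],
                "p_value": res.pvalues[name],
                "n_observations": int(n),
            }
        )
    return pd.DataFrame(rows)


def elasticity_matrix(
    purchases: pd.DataFrame, spec: ElasticitySpec | None = None
) -> pd.DataFrame:
    """Elasticity table for all 4 beverage categories x 3 tertiles."""
    import dataclasses

    base = spec or ElasticitySpec()
    prices = unit_values(purchases, base.price_categories)
    prices = impute_prices(prices, purchases, base.impute_min_obs, base.price_categories)
    tables = []
    for cat in BEVERAGE_CATEGORIES:
        s = dataclasses.replace(base, dependent_category=cat)
        tables.append(fit_demand(purchases, s, prices=prices))
    return pd.concat(tables, ignore_index=True)
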