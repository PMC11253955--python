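"""Obesity cost savings: cost per case, discounting, benefit lag.

The annual societal cost of overweight and obesity is scaled by the share
attributable to obesity, divided by the number of prevalent obesity cases
to give a cost per case per year, and inflated to the analysis year.
Savings in a year are averted cases times cost per case, zeroed during the
initial no-benefit lag (obesity-related morbidity and mortality respond
with delay) and discounted to present value with an end-of-year
convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .reference import brazil_reference


@dataclass
class CostParameters:
    total_ow_ob_cost: float  # US$/yr, overweight + obesity
    direct_cost: float
    indirect_cost: float
    obesity_share: float  # fraction of that cost attributable to obesity
    baseline_obesity_cases: float  # prevalent cases used for the per-case cost
    inflation_factor: float  # maps base-year to analysis-year US$
    discount_rate: float  # per year
    lag_years: int  # initial years with zero benefit
    horizon_years: int

    def __post_init__(self):
        if not 0.0 < self.obesity_share <= 1.0:
            raise ValidationError("obesity_share must be in (0, 1]")
        if self.lag_years >= self.horizon_years:
            raise ValidationError("lag_years must be smaller than horizon_years")
        if abs(self.direct_cost + self.indirect_cost - self.total_ow_ob_cost) > 0.01 * self.total_ow_ob_cost:
            raise ValidationError("direct + indirect costs must sum to the total")

    @classmethod
    def brazil_default(cls) -> "CostParameters":
        ref = brazil_reference()
        c = ref["costs"]
        return cls(
            total_ow_ob_cost=float(c["total_ow_ob_cost_usd"]),
            direct_cost=float(c["direct_cost_usd"]),
            indirect_cost=float(c["indirect_cost_usd"]),
            obesity_share=float(c["obesity_share"]),
            baseline_obesity_cases=float(ref["obesity"]["baseline_cases_m"]) * 1e6,
            inflation_factor=float(c["inflation_factor_2019_2021"]),
            discount_rate=float(c["discount_rate"]),
            lag_years=int(c["lag_years"]),
            horizon_years=int(c["horizon_years"]),
        )


def obesity_attributable_cost(total: float, share: float) -> float:
    """Annual cost attributable to obesity alone."""
    if not 0.0 < share <= 1.0:
        raise ValidationError("share must be in (0, 1]")
    return total * share


def cost_per_case(attributable_cost: float, cases: float) -> float:
    """Annual cost per prevalent obesity case."""
    if cases <= 0:
        raise ValidationError("cases must be > 0")
    return attributable_cost / cases


def cumulative_savings(
    yearly_cases_averted,
    cost_per_case_yr: float,
    params: CostParameters,
) -> tuple[float, pd.DataFrame]:
    """Discounted cumulative savings and the yearly audit ledger.

    savings_y = cases_y x cost, zero for y <= lag, discounted by
    (1 + r)^-y (end-of-year, to year 0).  Returns (total, ledger).
    """
    cases = np.asarray(yearly_cases_averted, float)
    if cost_per_case_yr < 0:
        raise ValidationError("cost per case must be >= 0")
    if len(cases) != params.horizon_years:
        raise ValidationError(
            f"series length {len(cases)} != horizon {params.horizon_years}"
        )
    years = np.arange(1, params.horizon_years + 1)
    paying = years > params.lag_years
    nominal = np.where(paying, cases * cost_per_case_yr, 0.0)
    disc_factor = (1.0 + params.discount_rate) ** (-years.astype(float))
    discounted = nominal * disc_factor
    ledger = pd.DataFrame(
        {
            "year": years,
            "cases_averted": cases,
            "nominal_savings": nominal,
            "discount_factor": disc_factor,
            "discounted_savings": discounted,
        }
    )
    return float(discounted.sum()), ledger


def savings_split(
    yearly_cases_averted, params: CostParameters
) -> dict[str, float]:
    """Total discounted savings and its direct/indirect decomposition.

    Cost per case is derived from the parameters (attributable cost over
    baseline cases, inflated); the split scales by the direct/indirect
    shares of the total cost, so direct + indirect equals the total.
    """
    attrib = obesity_attributable_cost(params.total_ow_ob_cost, params.obesity_share)
    per_case = cost_per_case(attrib, params.baseline_obesity_cases) * params.inflation_factor
    total, ledger = cumulative_savings(yearly_cases_averted, per_case, params)
    dshare = params.direct_cost / params.total_ow_ob_cost
    return {
        "cost_per_case": per_case,
        "total": total,
        "direct": total * dshare,
        "indirect": total * (1.0 - dshare),
        "ledger": ledger,
    }
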