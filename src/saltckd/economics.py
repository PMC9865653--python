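"""Healthcare-cost offsets: per-case CKD costs and discounting.

Annual CKD expenditure per stratum and cause is divided by prevalent cases
to give a per-case annual cost; prevented prevalence then translates into
savings, discounted to the 2019 base year.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bundle import InputBundle
from .strata import BASE_YEAR


@dataclass
class CostModel:
    """Per-case annual CKD costs (AUD) and discount settings."""

    per_capita_cost: pd.DataFrame  # stratum x cause, AUD / prevalent case / year
    discount_rate_cost: float = 0.03
    discount_rate_haly: float = 0.0
    base_year: int = BASE_YEAR

    def __post_init__(self) -> None:
        for r in (self.discount_rate_cost, self.discount_rate_haly):
            if not (0.0 <= r <= 0.2):
                raise ValueError(f"discount rate {r} outside [0, 0.2]")
        if (self.per_capita_cost.to_numpy() < 0).any():
            raise ValueError("negative per-case costs")


def per_capita_costs(
    bundle: InputBundle,
    discount_rate_cost: float = 0.03,
    discount_rate_haly: float = 0.0,
) -> CostModel:
    """Annual cost per prevalent case: total spend / (prevalence x population)."""
    cases = bundle.prevalence.mul(bundle.population, axis=0)
    spend = bundle.cost_total
    bad = (cases.to_numpy() <= 0) & (spend.to_numpy() > 0)
    if bad.any():
        loc = np.argwhere(bad)[0]
        raise ValueError(
            f"spending without prevalent cases at stratum {spend.index[loc[0]]}, "
            f"cause {spend.columns[loc[1]]}"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        cpc = np.where(cases.to_numpy() > 0, spend.to_numpy() / cases.to_numpy(), 0.0)
    return CostModel(
        pd.DataFrame(cpc, index=spend.index, columns=spend.columns),
        discount_rate_cost=discount_rate_cost,
        discount_rate_haly=discount_rate_haly,
    )


def discount(amount, year, rate: float, base_year: int = BASE_YEAR):
    """Present value at ``base_year`` of an amount accruing in ``year``."""
    year = np.asarray(year)
    if (year < base_year).any():
        raise ValueError("cannot discount before the base year")
    return amount / (1.0 + rate) ** (year - base_year)


def discount_factors(years: np.ndarray, rate: float, base_year: int = BASE_YEAR) -> np.ndarray:
    return 1.0 / (1.0 + rate) ** (np.asarray(years) - base_year)
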