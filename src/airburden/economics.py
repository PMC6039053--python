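"""Cost accrual: four care categories per prevalent case-year, palliative
per-death costs, flat-rate inflation and discounting of outputs.

Costs are expressed in British pounds per prevalent case per year (or
per death where flagged), valued in a 2015 base year; simulation outputs
are discounted back to that base year at a flat 1.5%/year, matching the
1.5% HCHS-style inflation assumption used to bring cost inputs to 2015.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CARE_CATEGORIES = ("primary", "secondary", "medication", "social")


@dataclass
class EconConfig:
    inflation_rate: float = 0.015
    discount_rate: float = 0.015
    value_base_year: int = 2015

    def __post_init__(self):
        if self.inflation_rate < 0 or self.discount_rate < 0:
            raise ValueError("rates must be non-negative")


@dataclass
class CostSpec:
    """Annual cost per prevalent case (GBP) by care category for one
    condition; ``per_death`` flags categories costed per death
    (palliative care) rather than per case-year."""

    disease: str
    amounts: dict = field(default_factory=dict)       # category -> GBP
    per_death: dict = field(default_factory=dict)     # category -> bool
    base_year: int = 2015

    def __post_init__(self):
        for cat in CARE_CATEGORIES:
            self.amounts.setdefault(cat, 0.0)
            self.per_death.setdefault(cat, False)
        if any(v < 0 for v in self.amounts.values()):
            raise ValueError("cost amounts must be non-negative")


#: Default cost-per-case(/death) table, GBP per year, 2015 values.
#: per-death (palliative) flags: all four lung-cancer categories; social
#: care for asthma, COPD, stroke and diabetes. Low birth weight has no
#: cost inputs and is epidemiology-only.
DEFAULT_COSTS = {
    "asthma": CostSpec(
        "asthma",
        {"primary": 21.28, "secondary": 27.02, "medication": 87.57, "social": 0.50},
        {"social": True},
    ),
    "copd": CostSpec(
        "copd",
        {"primary": 400.43, "secondary": 587.48, "medication": 126.79, "social": 85.30},
        {"social": True},
    ),
    "chd": CostSpec(
        "chd",
        {"primary": 71.57, "secondary": 1460.46, "medication": 818.60, "social": 109.70},
    ),
    "stroke": CostSpec(
        "stroke",
        {"primary": 36.45, "secondary": 722.84, "medication": 504.10, "social": 76.05},
        {"social": True},
    ),
    "diabetes": CostSpec(
        "diabetes",
        {"primary": 375.00, "secondary": 536.75, "medication": 276.88, "social": 601.56},
        {"social": True},
    ),
    "lung_cancer": CostSpec(
        "lung_cancer",
        {"primary": 51.73, "secondary": 466.63, "medication": 35.10, "social": 89.38},
        {"primary": True, "secondary": True, "medication": True, "social": True},
    ),
    "dementia": CostSpec(
        "dementia",
        {"primary": 430.62, "secondary": 197.24, "medication": 310.24, "social": 6174.47},
    ),
}

_warned_missing: set = set()


def cost_spec_for(disease: str, costs: dict) -> CostSpec | None:
    """Exact or prefix match (the three asthma age strata share the
    asthma cost row); None — logged once — if no cost input exists."""
    if disease in costs:
        return costs[disease]
    for key in costs:
        if disease.startswith(key):
            return costs[key]
    if disease not in _warned_missing:
        _warned_missing.add(disease)
        logger.info("no cost inputs for %s; contributes zero cost", disease)
    return None


def annual_cost(prevalent_counts: dict, deaths: dict, costs: dict) -> pd.DataFrame:
    """Cost per (disease, care category) for one year, GBP.

    Per-case categories contribute amount × prevalent count; per-death
    categories contribute amount × deaths that year. Diseases without a
    cost spec contribute zero.
    """
    rows = []
    for disease, prev in prevalent_counts.items():
        if prev < 0 or deaths.get(disease, 0) < 0:
            raise ValueError("counts must be non-negative")
        spec = cost_spec_for(disease, costs)
        for cat in CARE_CATEGORIES:
            if spec is None:
                c = 0.0
            elif spec.per_death[cat]:
                c = spec.amounts[cat] * deaths.get(disease, 0)
            else:
                c = spec.amounts[cat] * prev
            rows.append({"disease": disease, "category": cat, "cost": c})
    return pd.DataFrame(rows)


def inflate(amount, from_year: int, to_year: int, rate: float = 0.015):
    """Compound flat-rate inflation: amount × (1 + rate)^(to − from)."""
    return amount * (1.0 + rate) ** (to_year - from_year)


def discount(amount, year: int, base_year: int = 2015, rate: float = 0.015):
    """Discount a cost accrued in ``year`` back to the base year."""
    if year < base_year:
        raise ValueError("cannot discount a year before the base year")
    return amount / (1.0 + rate) ** (year - base_year)


def discount_factors(years, base_year: int = 2015, rate: float = 0.015) -> np.ndarray:
    years = np.asarray(years)
    if (years < base_year).any():
        raise ValueError("cannot discount a year before the base year")
    return 1.0 / (1.0 + rate) ** (years - base_year)
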