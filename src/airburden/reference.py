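"""Published England-level reference estimates (central values).

These are the England 2017–2035 projection aggregates that the
reporting layer's structure must reproduce arithmetically: per-category
cost rows summing to total-cost rows, avoided cases equalling
baseline-minus-scenario cumulative incidence, combined two-pollutant
totals equalling the sum of the per-pollutant columns, and the 2017
attributable share equalling attributable / baseline cumulative cases.
They serve as worked-example inputs for those identities and for the
reproduction script; they are published outputs, not inputs to the
simulation engine.

All costs are millions of GBP (discounted, 2015 values); case counts
are persons in the England mid-2015 population.
"""

from __future__ import annotations

import pandas as pd

from .economics import CARE_CATEGORIES
from .reporting import WINDOWS, per_100k

#: England mid-2015 scaling denominator implied by the per-100,000 rows.
ENGLAND_POPULATION = 55_600_000

_T4 = {
    # (pollutant, parameter): {window: central value}
    ("pm25", "cases_per_100k"): [114, 1062, 2248],
    ("pm25", "cases"): [63_430, 607_917, 1_327_424],
    ("pm25", "cost_total"): [76.10, 2814.79, 9408.71],
    ("pm25", "cost_primary"): [10.45, 332.02, 1070.37],
    ("pm25", "cost_secondary"): [36.83, 1368.70, 4537.67],
    ("pm25", "cost_medication"): [18.81, 718.53, 2425.98],
    ("pm25", "cost_social"): [10.01, 395.54, 1374.69],
    ("no2", "cases_per_100k"): [109, 943, 1933],
    ("no2", "cases"): [60_648, 539_527, 1_140_018],
    ("no2", "cost_total"): [81.06, 2749.91, 9159.22],
    ("no2", "cost_primary"): [12.61, 469.87, 1660.39],
    ("no2", "cost_secondary"): [17.09, 642.75, 2302.76],
    ("no2", "cost_medication"): [10.95, 399.80, 1424.00],
    ("no2", "cost_social"): [40.41, 1237.49, 3772.07],
}

_T5 = {
    # (scenario, pollutant, parameter): {window: central value}
    ("baseline", "pm25", "cumulative_cases"): [644_873, 6_119_754, 13_654_072],
    ("baseline", "no2", "cumulative_cases"): [661_566, 6_215_963, 13_855_589],
    ("reduction_1ug", "pm25", "cumulative_cases"):
        [636_526, 6_033_265, 13_465_656],
    ("reduction_1ug", "no2", "cumulative_cases"):
        [659_896, 6_198_788, 13_822_000],
    ("reduction_1ug", "pm25", "cases_avoided"): [8_345, 86_483, 188_415],
    ("reduction_1ug", "no2", "cases_avoided"): [1_669, 17_173, 33_589],
    ("reduction_1ug", "pm25", "cost_total_avoided"): [11.6, 408.3, 1424.2],
    ("reduction_1ug", "no2", "cost_total_avoided"): [4.09, 108.71, 353.33],
    ("reduction_1ug", "pm25", "cost_primary_avoided"): [1.59, 50.27, 167.16],
    ("reduction_1ug", "pm25", "cost_secondary_avoided"): [5.56, 196.62, 683.71],
    ("reduction_1ug", "pm25", "cost_medication_avoided"): [2.91, 102.95, 362.59],
    ("reduction_1ug", "pm25", "cost_social_avoided"): [1.51, 58.48, 210.73],
    ("reduction_1ug", "no2", "cost_primary_avoided"): [0.69, 19.89, 65.63],
    ("reduction_1ug", "no2", "cost_secondary_avoided"): [0.97, 27.94, 92.10],
    ("reduction_1ug", "no2", "cost_medication_avoided"): [0.56, 16.07, 53.05],
    ("reduction_1ug", "no2", "cost_social_avoided"): [1.87, 44.81, 142.55],
    ("eu_limit", "no2", "cumulative_cases"):
        [652_106, 6_119_176, 13_630_127],
    ("eu_limit", "no2", "cases_avoided"): [9_458, 96_786, 225_465],
    ("eu_limit", "no2", "cost_total_avoided"): [12.92, 442.81, 1692.87],
    ("eu_limit", "no2", "cost_primary_avoided"): [2.34, 83.19, 324.10],
    ("eu_limit", "no2", "cost_secondary_avoided"): [3.25, 116.90, 456.06],
    ("eu_limit", "no2", "cost_medication_avoided"): [2.02, 71.70, 280.19],
    ("eu_limit", "no2", "cost_social_avoided"): [5.31, 171.02, 632.52],
}

_WINDOW_NAMES = list(WINDOWS)


def attributable_central() -> pd.DataFrame:
    """Attributable cases/costs per pollutant and window (long form)."""
    rows = [dict(pollutant=p, parameter=param, window=w, value=v)
            for (p, param), vals in _T4.items()
            for w, v in zip(_WINDOW_NAMES, vals)]
    return pd.DataFrame(rows)


def scenario_central() -> pd.DataFrame:
    """Baseline/scenario cumulative incidence and avoided cases/costs
    (long form)."""
    rows = [dict(scenario=s, pollutant=p, parameter=param, window=w, value=v)
            for (s, p, param), vals in _T5.items()
            for w, v in zip(_WINDOW_NAMES, vals)]
    return pd.DataFrame(rows)


def _t4(pollutant, parameter, window):
    return _T4[(pollutant, parameter)][_WINDOW_NAMES.index(window)]


def _t5(scenario, pollutant, parameter, window):
    return _T5[(scenario, pollutant, parameter)][_WINDOW_NAMES.index(window)]


def category_cost_sum(pollutant: str, window: str) -> float:
    """Total attributable cost recomputed as the sum of the four
    care-category rows (millions GBP)."""
    return sum(_t4(pollutant, f"cost_{c}", window) for c in CARE_CATEGORIES)


def combined_cost_billion(window: str = "2017-2035") -> float:
    """Two-pollutant total attributable cost, billions GBP, as the sum
    of the per-pollutant columns."""
    return (_t4("pm25", "cost_total", window)
            + _t4("no2", "cost_total", window)) / 1000.0


def combined_cases(window: str = "2017-2035") -> float:
    """Two-pollutant attributable incident cases as the sum of the
    per-pollutant columns."""
    return _t4("pm25", "cases", window) + _t4("no2", "cases", window)


def attributable_share_pct(pollutant: str, window: str = "2017") -> float:
    """Attributable share of the total disease burden: attributable
    cases / baseline cumulative cases, as a percentage."""
    return 100.0 * _t4(pollutant, "cases", window) / _t5(
        "baseline", pollutant, "cumulative_cases", window)


def cases_avoided_recomputed(scenario: str, pollutant: str,
                             window: str) -> float:
    """Avoided cases recomputed as baseline − scenario cumulative
    incidence."""
    return (_t5("baseline", pollutant, "cumulative_cases", window)
            - _t5(scenario, pollutant, "cumulative_cases", window))


def cases_avoided_published(scenario: str, pollutant: str,
                            window: str) -> float:
    return _t5(scenario, pollutant, "cases_avoided", window)
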