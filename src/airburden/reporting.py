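"""Scenario definitions, scenario differencing, and summary tables.

Four scenarios are modelled: a no-change baseline; a reduction of each
individual's exposure to natural (non-anthropogenic) levels, whose
difference from baseline is the burden attributable to the pollutant; a
sustained 1 μg/m³ reduction from the scenario start year; and an annual-
average concentration cap (the 40 μg/m³ NO2 limit value). Comparisons
use common random numbers — both arms share seeds and individuals — so
replicate-wise differencing isolates the scenario effect; differenced
cells may be negative in noisy cells and are reported as-is.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .economics import CARE_CATEGORIES
from .exposure import NO2, PM25, Transform

#: Reporting windows (inclusive): the scenario start year alone, and the
#: cumulative horizons to 2025 and 2035.
WINDOWS = {
    "2017": (2017, 2017),
    "2017-2025": (2017, 2025),
    "2017-2035": (2017, 2035),
}


@dataclass(frozen=True)
class ScenarioSpec:
    """One counterfactual exposure scenario.

    kind: 'baseline' | 'natural_counterfactual' | 'delta_reduction'
    (sustained δ μg/m³ reduction from ``effective_year``) | 'limit_cap'
    (annual-average cap of ``limit`` μg/m³).
    """

    kind: str = "baseline"
    pollutants: tuple = (PM25, NO2)
    delta: float = 1.0
    limit: float = 40.0
    effective_year: int = 2017

    def __post_init__(self):
        if self.kind not in ("baseline", "natural_counterfactual",
                             "delta_reduction", "limit_cap"):
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.delta < 0:
            raise ValueError("delta must be non-negative")
        if not self.limit > 0:
            raise ValueError("limit must be positive")

    def transform(self) -> Transform:
        if self.kind == "baseline":
            return Transform("identity")
        if self.kind == "natural_counterfactual":
            return Transform("to_natural")
        if self.kind == "delta_reduction":
            return Transform("subtract", delta=self.delta)
        return Transform("cap", limit=self.limit)

    def affects(self, pollutant: str, year: int) -> bool:
        return (self.kind != "baseline" and pollutant in self.pollutants
                and year >= self.effective_year)


def baseline() -> ScenarioSpec:
    return ScenarioSpec("baseline")


def natural_counterfactual(*pollutants) -> ScenarioSpec:
    return ScenarioSpec("natural_counterfactual",
                        pollutants=tuple(pollutants) or (PM25, NO2))


def delta_reduction(delta: float = 1.0, *pollutants) -> ScenarioSpec:
    return ScenarioSpec("delta_reduction", pollutants=tuple(pollutants)
                        or (PM25, NO2), delta=delta)


def limit_cap(limit: float = 40.0, *pollutants) -> ScenarioSpec:
    return ScenarioSpec("limit_cap", pollutants=tuple(pollutants) or (NO2,),
                        limit=limit)


def _check_comparable(a, b):
    if (a.n_individuals != b.n_individuals or a.seed != b.seed
            or a.incident.shape != b.incident.shape
            or not np.array_equal(a.years, b.years)
            or a.diseases != b.diseases):
        raise ValueError(
            "runs are not comparable: scenario arms must share config, "
            "seed and replicate count (common random numbers)"
        )


def attributable(baseline_run, counterfactual_run):
    """Replicate-wise difference baseline − counterfactual.

    Requires common random numbers (same config and seeds in both arms).
    The result has the same structure as a run; negative cells are kept.
    """
    _check_comparable(baseline_run, counterfactual_run)
    return replace(
        baseline_run,
        scenario=counterfactual_run.scenario,
        is_difference=True,
        incident=baseline_run.incident - counterfactual_run.incident,
        at_risk=baseline_run.at_risk - counterfactual_run.at_risk,
        prevalent=baseline_run.prevalent - counterfactual_run.prevalent,
        deaths=baseline_run.deaths - counterfactual_run.deaths,
        cost=baseline_run.cost - counterfactual_run.cost,
        alive=baseline_run.alive - counterfactual_run.alive,
        births=baseline_run.births - counterfactual_run.births,
        deaths_total=baseline_run.deaths_total - counterfactual_run.deaths_total,
    )


def _mc_ci(per_rep: np.ndarray):
    """Normal-approximation Monte Carlo CI over replicates."""
    per_rep = np.asarray(per_rep, dtype=float)
    mean = per_rep.mean(axis=0)
    r = per_rep.shape[0]
    if r < 2:
        nan = np.full_like(mean, np.nan, dtype=float)
        return mean, nan, nan
    half = 1.96 * per_rep.std(axis=0, ddof=1) / np.sqrt(r)
    return mean, mean - half, mean + half


def cumulate(result, window=(2017, 2035), diseases=None) -> dict:
    """Scaled cumulative incident cases and discounted costs over an
    inclusive year window, with Monte Carlo CIs across replicates."""
    lo_y, hi_y = window
    years = result.years
    if lo_y < years[0] or hi_y > years[-1] or lo_y > hi_y:
        raise ValueError(f"window {window} outside run span "
                         f"({years[0]}-{years[-1]})")
    ymask = (years >= lo_y) & (years <= hi_y)
    if diseases is None:
        dmask = np.ones(len(result.diseases), dtype=bool)
    else:
        dmask = np.array([d in diseases for d in result.diseases])
    f = result.scale_factor
    cases_rep = result.incident[:, ymask][:, :, dmask].sum(axis=(1, 2)) * f
    out = {}
    out["cases"] = _mc_ci(cases_rep)
    cost = result.cost[:, ymask][:, :, dmask, :] * f
    for c, cat in enumerate(CARE_CATEGORIES):
        out[f"cost_{cat}"] = _mc_ci(cost[:, :, :, c].sum(axis=(1, 2)))
    out["cost_total"] = _mc_ci(cost.sum(axis=(1, 2, 3)))
    return out


def per_100k(count, population):
    """Rate per 100,000 persons."""
    if not population > 0:
        raise ValueError("population must be positive")
    return np.asarray(count, dtype=float) * 1e5 / population


def strong_evidence_diseases(evidence: dict) -> list:
    return [d for d, e in evidence.items() if e == "strong"]


def _rows_for(diff, window, diseases, population):
    agg = cumulate(diff, window, diseases)
    rows = {}
    m, lo, hi = agg["cases"]
    rows["cases"] = (m, lo, hi)
    rows["cases_per_100k"] = tuple(per_100k(v, population) for v in (m, lo, hi))
    for key in ["cost_total"] + [f"cost_{c}" for c in CARE_CATEGORIES]:
        rows[key] = agg[key]
    return rows


def attributable_table(baseline_run, counterfactual_runs: dict,
                       evidence_filter: str | None = None) -> pd.DataFrame:
    """Attributable cases and costs per pollutant and reporting window.

    ``counterfactual_runs`` maps pollutant -> the natural-counterfactual
    run for that pollutant alone. Rows: attributable incident cases (raw
    and per 100,000 of the reference population) and total plus per-
    category costs; ``evidence_filter='strong'`` restricts to diseases
    with strong causal evidence.
    """
    records = []
    for pollutant, cf in counterfactual_runs.items():
        diff = attributable(baseline_run, cf)
        diseases = None
        if evidence_filter:
            diseases = [d for d, e in baseline_run.evidence.items()
                        if e == evidence_filter]
        for wname, window in WINDOWS.items():
            rows = _rows_for(diff, window, diseases,
                             baseline_run.reference_population)
            for param, (m, lo, hi) in rows.items():
                records.append(dict(pollutant=pollutant, window=wname,
                                    parameter=param, mean=m, lo=lo, hi=hi))
    return pd.DataFrame(records)


def scenario_table(baseline_run, scenario_runs: dict) -> pd.DataFrame:
    """Cases and costs avoided relative to baseline for each comparison
    scenario, cumulative by reporting window (Table-5-shaped, long form).

    Includes the baseline and scenario cumulative incidence rows, so
    avoided = baseline − scenario can be checked against the explicit
    differenced row.
    """
    records = []

    def emit(scen, pollutant, wname, param, trip):
        m, lo, hi = trip
        records.append(dict(scenario=scen, pollutant=pollutant, window=wname,
                            parameter=param, mean=m, lo=lo, hi=hi))

    for name, run in scenario_runs.items():
        pollutant = ",".join(run.scenario.pollutants)
        diff = attributable(baseline_run, run)
        for wname, window in WINDOWS.items():
            base_agg = cumulate(baseline_run, window)
            scen_agg = cumulate(run, window)
            diff_agg = cumulate(diff, window)
            emit(name, pollutant, wname, "baseline_cases", base_agg["cases"])
            emit(name, pollutant, wname, "scenario_cases", scen_agg["cases"])
            emit(name, pollutant, wname, "cases_avoided", diff_agg["cases"])
            emit(name, pollutant, wname, "cost_total_avoided",
                 diff_agg["cost_total"])
            for cat in CARE_CATEGORIES:
                emit(name, pollutant, wname, f"cost_{cat}_avoided",
                     diff_agg[f"cost_{cat}"])
    return pd.DataFrame(records)


def check_consistency(table: pd.DataFrame, rtol: float = 1e-9) -> pd.DataFrame:
    """Assert the construction invariant that per-category cost rows sum
    to the total cost row in every (pollutant/scenario, window) block;
    returns the per-block residuals."""
    keys = [c for c in ("scenario", "pollutant", "window") if c in table.columns]
    total_name = ("cost_total_avoided"
                  if "cost_total_avoided" in set(table["parameter"]) else "cost_total")
    cat_names = [total_name.replace("total", c) for c in CARE_CATEGORIES]
    out = []
    for key, g in table.groupby(keys):
        g = g.set_index("parameter")["mean"]
        resid = g[total_name] - sum(g[c] for c in cat_names)
        out.append(dict(zip(keys, key if isinstance(key, tuple) else (key,)),
                        residual=resid))
    res = pd.DataFrame(out)
    scale = max(float(table["mean"].abs().max()), 1.0)
    if (res["residual"].abs() > rtol * scale).any():
        raise AssertionError("category cost rows do not sum to the total")
    return res
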