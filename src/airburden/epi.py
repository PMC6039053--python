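"""Disease parameter completion, exposure–response arithmetic, calibration.

Each modelled condition carries age/sex tables of annual incidence,
prevalence, disease-specific mortality and case fatality (or multi-year
survival for lung cancer), plus per-pollutant exposure–response values
expressed per 10 μg/m³. National statistics typically publish only a
subset of these; the remainder is completed with incidence–prevalence–
mortality bookkeeping in the style of the WHO DISMOD II tool, and the
reference-level hazard is calibrated so that simulating the observed
(baseline) exposure distribution reproduces the observed incidence.

Risk ratios, odds ratios and hazard ratios are all treated as rate
ratios on the annual incidence hazard h = -ln(1 - p): the hazard is
multiplied and back-transformed, which keeps annual probabilities below
one at any exposure.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .exposure import ExposureDistribution, N_BANDS, age_to_band_index

logger = logging.getLogger(__name__)

#: Single-year age grid used by all rate tables (the open-ended 90+
#: exposure band covers ages 90-99).
AGES = np.arange(0, 100)
N_AGES = AGES.size

#: Excess-risk fraction removed from published NO2 estimates to account
#: for overlap with PM2.5 effects (COMEAP recommendation).
NO2_OVERLAP_REDUCTION = 0.60

STRONG = "strong"
WEAKER = "weaker"


class InconsistentRatesError(ValueError):
    """Published rate tables imply an impossible (negative or >1) rate."""


@dataclass
class DiseaseSpec:
    """One condition's epidemiological tables and exposure–response values.

    Rate tables are (n_ages, 2) arrays over the single-year age grid and
    sex (female=0, male=1), as annual probabilities:

    - ``incidence``: onset events per disease-free person-year
    - ``prevalence``: proportion of the population with the condition
    - ``mortality``: condition-specific deaths per person-year (whole
      population denominator)
    - ``case_fatality``: deaths per case-year among the prevalent
    - ``survival``: alternatively, {1: S1, 5: S5, 10: S10} net survival
      proportions since diagnosis (lung cancer), converted to a
      piecewise-constant annual case fatality by years since onset

    ``er_pm25`` / ``er_no2`` are published central exposure–response
    ratios per 10 μg/m³ (None where no estimate exists ⇒ multiplier 1);
    NO2 values are reduced by 60% of their excess risk before use.
    Non-terminal conditions (type 2 diabetes, low birth weight) carry no
    excess mortality. ``birth_outcome`` marks low birth weight, which is
    drawn once per birth from the mother's exposure rather than annually.
    """

    name: str
    terminal: bool
    age_min: int
    age_max: int
    evidence: str = STRONG
    er_pm25: float | None = None
    er_no2: float | None = None
    incidence: np.ndarray | None = None
    prevalence: np.ndarray | None = None
    mortality: np.ndarray | None = None
    case_fatality: np.ndarray | None = None
    survival: dict | None = None
    birth_outcome: bool = False

    def eligible(self, ages) -> np.ndarray:
        a = np.asarray(ages)
        return (a >= self.age_min) & (a <= self.age_max)

    def er(self, pollutant: str) -> float | None:
        """Exposure–response ratio actually used in simulation (NO2
        values COMEAP-adjusted); None means no effect."""
        if pollutant == "pm25":
            return self.er_pm25
        if self.er_no2 is None:
            return None
        return adjust_no2(self.er_no2)

    def validate(self):
        for attr in ("incidence", "prevalence", "mortality", "case_fatality"):
            tab = getattr(self, attr)
            if tab is not None and ((tab < 0).any() or (tab > 1).any()):
                raise InconsistentRatesError(f"{self.name}.{attr} outside [0, 1]")
        if self.survival is not None:
            vals = [self.survival[k] for k in sorted(self.survival)]
            if any(b > a + 1e-12 for a, b in zip(vals, vals[1:])):
                raise InconsistentRatesError(
                    f"{self.name} survival must be non-increasing in horizon"
                )


def rr_multiplier(er_per_10, concentration, reference):
    """Risk multiplier er^((C - C_ref)/10) for exposure C above the
    reference level; equals 1 at the reference. Concentrations below the
    reference are clamped to a multiplier of 1 with a logged warning."""
    er_per_10 = np.asarray(er_per_10, dtype=float)
    if (er_per_10 <= 0).any():
        raise ValueError("er_per_10 must be positive")
    delta = np.asarray(concentration, dtype=float) - np.asarray(reference, dtype=float)
    if (delta < -1e-9).any():
        logger.warning(
            "concentration below reference; clamping risk multiplier to 1"
        )
    delta = np.maximum(delta, 0.0)
    return er_per_10 ** (delta / 10.0)


def adjust_no2(published: float, reduction: float = NO2_OVERLAP_REDUCTION) -> float:
    """Scale a published NO2 excess risk down by ``reduction`` on the
    linear scale: 1 + (1 - reduction)·(published - 1)."""
    if published < 1:
        raise ValueError(
            "protective NO2 estimates (ratio < 1) are out of scope"
        )
    if not 0 <= reduction <= 1:
        raise ValueError("reduction must lie in [0, 1]")
    return 1.0 + (1.0 - reduction) * (published - 1.0)


def survival_to_case_fatality(survival: dict, horizon: int = 30) -> np.ndarray:
    """Convert {1, 5, 10}-year survival-since-diagnosis proportions to a
    piecewise-constant annual case fatality by years since onset.

    Within each interval the annual conditional survival is the
    geometric interpolant of the interval's survival ratio; beyond the
    last horizon the final annual rate persists.
    """
    ks = sorted(survival)
    out = np.empty(horizon)
    prev_k, prev_s = 0, 1.0
    for k in ks:
        s = survival[k]
        ratio = s / prev_s if prev_s > 0 else 0.0
        annual = 1.0 - ratio ** (1.0 / (k - prev_k))
        out[prev_k:k] = annual
        prev_k, prev_s = k, s
    out[prev_k:] = out[prev_k - 1]
    return np.clip(out, 0.0, 1.0)


def _other_cause(life_table: np.ndarray, mortality: np.ndarray) -> np.ndarray:
    # residual (non-this-disease) death probability; floored at 0
    return np.clip(life_table - mortality, 0.0, 1.0)


def forward_simulate(incidence, case_fatality, life_table,
                     p0: float = 0.0):
    """Deterministic single-cohort recursion: from annual incidence i(a)
    and case fatality f(a) (plus all-cause mortality), produce the
    implied prevalence p(a) and condition mortality m(a) = p(a)·f(a).

    The annual step, among survivors of age a:

        p(a+1) = [p(a)(1 - f - μ) + (1 - p(a)) i] / [1 - μ - p(a) f]

    with μ the other-cause death probability. This is the exact inverse
    of :func:`complete_epi_params`' incidence recovery.
    """
    incidence = np.asarray(incidence, dtype=float)
    case_fatality = np.asarray(case_fatality, dtype=float)
    shape = incidence.shape
    prevalence = np.zeros(shape)
    mortality = np.zeros(shape)
    n_ages = shape[0]
    cols = shape[1] if incidence.ndim > 1 else None

    def run(i, f, lt):
        p = np.zeros(n_ages)
        m = np.zeros(n_ages)
        cur = p0
        for a in range(n_ages):
            p[a] = cur
            m[a] = cur * f[a]
            mu = max(lt[a] - m[a], 0.0)
            alive = 1.0 - mu - cur * f[a]
            if alive <= 0:
                cur = 0.0
                continue
            cur = (cur * (1.0 - f[a] - mu) + (1.0 - cur) * i[a]) / alive
            cur = min(max(cur, 0.0), 1.0)
        return p, m

    if cols is None:
        return run(incidence, case_fatality, life_table)
    for s in range(cols):
        prevalence[:, s], mortality[:, s] = run(
            incidence[:, s], case_fatality[:, s], life_table[:, s]
        )
    return prevalence, mortality


def complete_epi_params(spec: DiseaseSpec, life_table: np.ndarray) -> DiseaseSpec:
    """Fill the rate tables a source did not publish.

    - non-terminal: case fatality and condition mortality ≡ 0
    - lung-cancer-style survival input: converted to annual case
      fatality by years since onset (age-invariant)
    - case fatality from (prevalence, mortality): f = m / p
    - incidence from (prevalence, mortality): inverted cohort
      bookkeeping; an implied negative incidence or a case fatality
      above 1 raises :class:`InconsistentRatesError` naming the age.
    """
    spec = replace(spec)
    if not spec.terminal:
        spec.case_fatality = np.zeros((N_AGES, 2))
        spec.mortality = np.zeros((N_AGES, 2))
        if spec.incidence is None:
            raise InconsistentRatesError(
                f"{spec.name}: non-terminal condition needs published incidence"
            )
        spec.validate()
        return spec

    if spec.case_fatality is None and spec.survival is None:
        if spec.prevalence is None or spec.mortality is None:
            raise InconsistentRatesError(
                f"{spec.name}: need (prevalence, mortality) to derive case fatality"
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(spec.prevalence > 0,
                         spec.mortality / np.maximum(spec.prevalence, 1e-300), 0.0)
        if ((spec.mortality > 0) & (spec.prevalence <= 0)).any():
            bad = int(np.argwhere((spec.mortality > 0) & (spec.prevalence <= 0))[0][0])
            raise InconsistentRatesError(
                f"{spec.name}: mortality without prevalence at age {bad}"
            )
        if (f > 1 + 1e-9).any():
            bad = int(np.argwhere(f > 1 + 1e-9)[0][0])
            raise InconsistentRatesError(
                f"{spec.name}: mortality exceeds prevalence-compatible bound "
                f"at age {bad}"
            )
        spec.case_fatality = np.clip(f, 0.0, 1.0)

    if spec.incidence is None:
        p, m = spec.prevalence, spec.mortality
        f = spec.case_fatality
        inc = np.zeros((N_AGES, 2))
        for s in range(2):
            for a in range(N_AGES - 1):
                mu = max(life_table[a, s] - m[a, s], 0.0)
                alive = 1.0 - mu - p[a, s] * f[a, s]
                if alive <= 0 or p[a, s] >= 1:
                    continue
                i = (p[a + 1, s] * alive - p[a, s] * (1.0 - f[a, s] - mu)) / (
                    1.0 - p[a, s]
                )
                if i < -1e-9:
                    raise InconsistentRatesError(
                        f"{spec.name}: implied negative incidence at age {a}"
                        f" ({'female' if s == 0 else 'male'})"
                    )
                inc[a, s] = min(max(i, 0.0), 1.0)
            inc[N_AGES - 1, s] = inc[N_AGES - 2, s]
        spec.incidence = inc

    if spec.prevalence is None and spec.survival is None:
        f = spec.case_fatality
        spec.prevalence, spec.mortality = forward_simulate(
            spec.incidence, f, life_table
        )
    spec.validate()
    return spec


def expected_rr(dist: ExposureDistribution, er_per_10: float | None,
                band_idx: int, sex_idx: int) -> float:
    """E[RR(C)] over one stratum's tertile-weighted exposure distribution,
    with the reference level taken as the matched-percentile natural
    component (so the multiplier acts on the anthropogenic increment)."""
    if er_per_10 is None:
        return 1.0
    delta = (dist.q_total[band_idx, sex_idx] - dist.q_natural[band_idx, sex_idx])
    rr = np.asarray(er_per_10, dtype=float) ** (np.maximum(delta, 0.0) / 10.0)
    w = dist.weights[band_idx, sex_idx]
    return float(np.sum(w * rr.mean(axis=1)))


def calibrate_reference_hazard(observed_incidence, *dist_er_pairs,
                               band_idx: int = 0, sex_idx: int = 0) -> float:
    """Reference-level annual incidence h0 = observed / E[∏ RR_pollutant],
    so that simulating the observed exposure distribution with hazard
    h0·∏RR(C) recovers the observed incidence in expectation.

    ``dist_er_pairs`` are (ExposureDistribution, er_per_10) pairs, one
    per pollutant; pollutant exposures are assigned independently, so
    the expectation factorises.
    """
    observed_incidence = float(observed_incidence)
    if not 0 <= observed_incidence <= 1:
        raise ValueError("observed incidence must lie in [0, 1]")
    denom = 1.0
    for dist, er in dist_er_pairs:
        denom *= expected_rr(dist, er, band_idx, sex_idx)
    return observed_incidence / denom
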