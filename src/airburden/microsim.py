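"""The individual-level discrete-time simulation engine.

A virtual population with the 2015 England-like age/sex structure is
tracked in annual cycles from 2015 to 2035. Each person carries, per
pollutant, a lifetime-fixed (tertile, percentile) exposure assignment;
their concentration in any year is the quantile of the (possibly
scenario-transformed) distribution for their current 5-year age band
and sex. Each year a person may develop an eligible condition (annual
probability = reference hazard × RR_PM2.5 × RR_NO2 on the hazard
scale), die of an existing terminal condition (case fatality), or die
of other causes (all-cause life-table mortality minus the modelled
condition mortalities, floored at zero). The event order within a year
is: incidence draws, then mortality draws, then aging and births.
Birth cohorts are sized to keep the age-0 population constant
(stationary demography); low birth weight is drawn once per birth from
the mother's exposure.

The modelling object follows the fit/results idiom:
``PollutionMicrosim(world, config).fit()`` calibrates the reference-
level hazards so the baseline arm reproduces the observed incidence
tables, and returns a :class:`MicrosimResults` whose ``simulate``
method runs replicate Monte Carlo simulations of one scenario under
common random numbers (replicate r uses stream ``seed + r``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import epi
from .economics import CARE_CATEGORIES, CostSpec, EconConfig, cost_spec_for, \
    discount_factors
from .epi import DiseaseSpec, N_AGES, survival_to_case_fatality
from .exposure import (AGE_BANDS, N_BANDS, NO2, PM25, POLLUTANTS, SEXES,
                       ExposureDistribution, age_to_band_index,
                       transform_for_scenario)
from .reporting import ScenarioSpec
from .synthetic_world import PopulationProfile

MOTHER_AGE_MIN, MOTHER_AGE_MAX = 15, 49


@dataclass
class RunConfig:
    """Simulation run settings; the desk-scale default population is
    100,000 individuals (the full-scale analysis uses 50 million)."""

    n_individuals: int = 100_000
    start_year: int = 2015
    scenario_start: int = 2017
    end_year: int = 2035
    replicates: int = 10
    seed: int = 0
    reference_population: float | None = None   # default: profile's

    def __post_init__(self):
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if not (self.start_year <= self.scenario_start <= self.end_year):
            raise ValueError("need start_year <= scenario_start <= end_year")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class World:
    """Everything the engine consumes: population structure, baseline
    exposure distributions per pollutant, disease specs (published
    cells), cost specs, and the all-cause life table."""

    profile: PopulationProfile
    distributions: dict            # pollutant -> ExposureDistribution
    diseases: list                 # DiseaseSpec (possibly incomplete)
    costs: dict                    # name -> CostSpec
    life_table: np.ndarray         # (n_ages, 2)
    econ: EconConfig = field(default_factory=EconConfig)

    def __post_init__(self):
        for p in POLLUTANTS:
            if p not in self.distributions:
                raise ValueError(f"missing exposure distribution for {p}")


@dataclass
class RunResult:
    """Replicate-level outputs of one scenario run (or a replicate-wise
    difference of two runs, ``is_difference=True``).

    Count arrays are raw simulated counts (scale by ``scale_factor`` to
    the reference population); ``cost`` is discounted GBP at simulation
    scale. Shapes: (replicates, years, diseases[, categories]).
    """

    scenario: ScenarioSpec
    years: np.ndarray
    diseases: list
    categories: tuple
    incident: np.ndarray
    prevalent: np.ndarray
    deaths: np.ndarray
    at_risk: np.ndarray
    cost: np.ndarray
    alive: np.ndarray
    births: np.ndarray
    deaths_total: np.ndarray
    n_individuals: int
    reference_population: float
    seed: int
    evidence: dict
    is_difference: bool = False

    @property
    def replicates(self) -> int:
        return self.incident.shape[0]

    @property
    def scale_factor(self) -> float:
        return self.reference_population / self.n_individuals

    def summarise(self, metric: str = "incident") -> pd.DataFrame:
        """Scaled per-(year, disease) replicate mean and normal-
        approximation Monte Carlo CI (undefined with one replicate)."""
        arr = getattr(self, metric) * self.scale_factor
        mean = arr.mean(axis=0)
        r = arr.shape[0]
        if r > 1:
            half = 1.96 * arr.std(axis=0, ddof=1) / np.sqrt(r)
        else:
            half = np.full_like(mean, np.nan, dtype=float)
        rows = []
        for yi, year in enumerate(self.years):
            for di, dis in enumerate(self.diseases):
                rows.append(dict(year=int(year), disease=dis,
                                 mean=mean[yi, di],
                                 lo=mean[yi, di] - half[yi, di],
                                 hi=mean[yi, di] + half[yi, di]))
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            f"Scenario: {self.scenario.kind} "
            f"(pollutants={','.join(self.scenario.pollutants)})",
            f"Replicates: {self.replicates}; individuals: "
            f"{self.n_individuals:,}; scaled to "
            f"{self.reference_population:,.0f}",
            "",
            "Scaled incident cases by disease, cumulative "
            f"{self.years[0]}-{self.years[-1]}:",
        ]
        f = self.scale_factor
        tot = self.incident.sum(axis=1) * f
        mean = tot.mean(axis=0)
        for di, dis in enumerate(self.diseases):
            lines.append(f"  {dis:<16s} {mean[di]:>14,.0f}")
        lines.append(f"  {'total':<16s} {mean.sum():>14,.0f}")
        return "\n".join(lines)

    def plot(self, metric: str = "incident", ax=None):
        """Scaled annual counts per disease over the run."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        arr = getattr(self, metric).mean(axis=0) * self.scale_factor
        for di, dis in enumerate(self.diseases):
            ax.plot(self.years, arr[:, di], label=dis)
        ax.set_xlabel("year")
        ax.set_ylabel(f"{metric} cases (scaled)")
        ax.legend(fontsize="small")
        return ax


def _eval_quantile(q: np.ndarray, grid: np.ndarray, rows: np.ndarray,
                   pct: np.ndarray) -> np.ndarray:
    """Vectorised equal-mass-atom quantile evaluation: a percentile in
    [0, 1) selects one of the P grid values with probability 1/P each
    (matching the point-mean expectation used in calibration).

    q: (..., P) quantile values; rows: flat row index per person;
    pct: lifetime percentile per person.
    """
    P = grid.size
    idx = np.minimum((np.clip(pct, 0.0, 1.0) * P).astype(int), P - 1)
    flat = q.reshape(-1, P)
    return flat[rows, idx]


class PollutionMicrosim:
    """Microsimulation model bound to a :class:`World` and
    :class:`RunConfig`; ``fit`` performs the reference-hazard
    calibration and returns a results object."""

    def __init__(self, world: World, config: RunConfig | None = None):
        self.world = world
        self.config = config or RunConfig()
        self._validate_inputs()

    @classmethod
    def from_world(cls, world: World, **config_kwargs) -> "PollutionMicrosim":
        return cls(world, RunConfig(**config_kwargs))

    def _validate_inputs(self):
        for p, dist in self.world.distributions.items():
            if not np.isfinite(dist.q_total).all():
                raise ValueError(f"non-finite quantiles in {p} distribution")
            if (dist.weights.sum(axis=2) <= 0).any():
                raise ValueError(f"empty stratum in {p} distribution")
        if self.world.life_table.shape != (N_AGES, 2):
            raise ValueError("life table must cover the full age grid")

    def fit(self) -> "MicrosimResults":
        """Complete the disease rate tables (DISMOD-style bookkeeping)
        and calibrate reference-level hazards so the baseline arm
        reproduces the observed incidence under the observed exposure
        distribution: h0(age, sex) = incidence / E[RR_PM2.5 · RR_NO2]
        over the person's age band stratum."""
        lt = self.world.life_table
        completed = [epi.complete_epi_params(s, lt) for s in self.world.diseases]
        dists = self.world.distributions
        hazards = {}
        diag = []
        for spec in completed:
            h0 = np.zeros((N_AGES, 2))
            mean_rr = np.ones((N_BANDS, 2))
            for b in range(N_BANDS):
                for s in range(2):
                    m = 1.0
                    for p in POLLUTANTS:
                        m *= epi.expected_rr(dists[p], spec.er(p), b, s)
                    mean_rr[b, s] = m
            bands = age_to_band_index(epi.AGES)
            for s in range(2):
                h0[:, s] = spec.incidence[:, s] / mean_rr[bands, s]
            hazards[spec.name] = h0
            diag.append(dict(disease=spec.name,
                             mean_rr=float(mean_rr.mean()),
                             max_h0=float(h0.max())))
        return MicrosimResults(self, completed, hazards,
                               pd.DataFrame(diag))


@dataclass
class MicrosimResults:
    """Calibrated model: completed disease specs plus reference-level
    hazard tables; scenario simulation hangs off this object."""

    model: PollutionMicrosim
    diseases: list
    reference_hazards: dict
    calibration: pd.DataFrame

    def summary(self) -> str:
        lines = ["Calibrated reference hazards "
                 "(h0 = observed incidence / E[RR]):", ""]
        for _, row in self.calibration.iterrows():
            lines.append(f"  {row['disease']:<16s} mean E[RR]="
                         f"{row['mean_rr']:.4f}  max h0={row['max_h0']:.4g}")
        return "\n".join(lines)

    # ------------------------------------------------------------------
    def simulate(self, scenario: ScenarioSpec | None = None,
                 replicates: int | None = None,
                 seed: int | None = None) -> RunResult:
        """Run replicate simulations of one scenario.

        Replicate r uses random stream ``seed + r``; runs of different
        scenarios with the same seed share every random draw (common
        random numbers), so replicate-wise differences isolate the
        scenario effect.
        """
        scenario = scenario or ScenarioSpec("baseline")
        cfg = self.model.config
        replicates = replicates or cfg.replicates
        seed = cfg.seed if seed is None else seed
        world = self.model.world
        years = np.arange(cfg.start_year, cfg.end_year + 1)
        nY, nD = years.size, len(self.diseases)

        # pre/post scenario distributions per pollutant
        base_dists = world.distributions
        scen_dists = {
            p: (transform_for_scenario(base_dists[p], scenario.transform())
                if scenario.affects(p, scenario.effective_year) else base_dists[p])
            for p in POLLUTANTS
        }

        out = dict(incident=np.zeros((replicates, nY, nD)),
                   prevalent=np.zeros((replicates, nY, nD)),
                   deaths=np.zeros((replicates, nY, nD)),
                   at_risk=np.zeros((replicates, nY, nD)),
                   alive=np.zeros((replicates, nY)),
                   births=np.zeros((replicates, nY)),
                   deaths_total=np.zeros((replicates, nY)))
        for r in range(replicates):
            rng = np.random.default_rng(seed + r)
            rec = self._run_once(scenario, base_dists, scen_dists, rng, years)
            for k in out:
                out[k][r] = rec[k]

        cost = self._costs(out["prevalent"], out["deaths"], years)
        ref_pop = (cfg.reference_population
                   or world.profile.reference_population)
        evidence = {s.name: s.evidence for s in self.diseases}
        return RunResult(
            scenario=scenario, years=years,
            diseases=[s.name for s in self.diseases],
            categories=CARE_CATEGORIES,
            incident=out["incident"], prevalent=out["prevalent"],
            deaths=out["deaths"], at_risk=out["at_risk"], cost=cost,
            alive=out["alive"],
            births=out["births"], deaths_total=out["deaths_total"],
            n_individuals=cfg.n_individuals, reference_population=ref_pop,
            seed=seed, evidence=evidence,
        )

    # ------------------------------------------------------------------
    def _costs(self, prevalent, deaths, years):
        """Discounted cost per (replicate, year, disease, category).

        Per-case categories accrue on prevalent case-years from the
        onset year inclusive; per-death (palliative) categories accrue
        in the year of death. Low birth weight has no cost inputs and
        contributes zero.
        """
        world = self.model.world
        econ = world.econ
        disc = discount_factors(years, econ.value_base_year,
                                econ.discount_rate)
        R, nY, nD = prevalent.shape
        cost = np.zeros((R, nY, nD, len(CARE_CATEGORIES)))
        for di, spec in enumerate(self.diseases):
            cs = cost_spec_for(spec.name, world.costs)
            if cs is None:
                continue
            for ci, cat in enumerate(CARE_CATEGORIES):
                base = deaths[:, :, di] if cs.per_death[cat] \
                    else prevalent[:, :, di]
                cost[:, :, di, ci] = base * cs.amounts[cat] * disc[None, :]
        return cost

    # ------------------------------------------------------------------
    def _run_once(self, scenario, base_dists, scen_dists, rng, years):
        cfg = self.model.config
        world = self.model.world
        profile = world.profile
        lt = world.life_table
        n0 = cfg.n_individuals
        nY = years.size
        specs = self.diseases
        nD = len(specs)
        lbw_idx = [i for i, s in enumerate(specs) if s.birth_outcome]
        annual_idx = [i for i in range(nD) if i not in lbw_idx]

        # stationary birth cohort: expected age-0 count per sex
        births_f = int(round(n0 * profile.share_by_age_sex[0, 0] / 5.0))
        births_m = int(round(n0 * profile.share_by_age_sex[0, 1] / 5.0))
        B = births_f + births_m
        cap = n0 + B * nY

        age = np.zeros(cap, dtype=np.int32)
        sex = np.zeros(cap, dtype=np.int8)
        alive = np.zeros(cap, dtype=bool)
        tert = np.zeros((2, cap), dtype=np.int8)      # pollutant-major
        pct = np.zeros((2, cap), dtype=np.float64)
        has = np.zeros((cap, nD), dtype=bool)
        onset = np.full(cap, -1, dtype=np.int32)      # lung-cancer durations

        # --- initial population -------------------------------------------
        p = profile.share_by_age_sex.ravel()
        cells = rng.choice(p.size, size=n0, p=p)
        band0 = cells // 2
        sex[:n0] = cells % 2
        age[:n0] = band0 * 5 + rng.integers(0, 5, size=n0)
        hi90 = band0 == N_BANDS - 1
        age[:n0][hi90] = 90 + rng.integers(0, 10, size=int(hi90.sum()))
        alive[:n0] = True
        self._assign_exposure(rng, slice(0, n0), age[:n0], sex[:n0],
                              tert, pct, base_dists)
        # initialise disease states from the completed prevalence tables
        for di, spec in enumerate(specs):
            u = rng.random(n0)
            if spec.birth_outcome or spec.prevalence is None:
                continue
            pr = spec.prevalence[np.minimum(age[:n0], N_AGES - 1), sex[:n0]]
            has[:n0, di] = u < pr
        onset[:n0] = years[0] - 1

        # duration-based case fatality (survival-published conditions)
        cf_by_duration = {
            di: survival_to_case_fatality(spec.survival)
            for di, spec in enumerate(specs) if spec.survival is not None
        }

        rec = dict(incident=np.zeros((nY, nD)), prevalent=np.zeros((nY, nD)),
                   deaths=np.zeros((nY, nD)), at_risk=np.zeros((nY, nD)),
                   alive=np.zeros(nY),
                   births=np.zeros(nY), deaths_total=np.zeros(nY))

        hz = self.reference_hazards
        n_cur = n0
        P = base_dists[PM25].grid.size
        for yi, year in enumerate(years):
            sl = slice(0, n_cur)
            a = np.minimum(age[sl], N_AGES - 1)
            sx = sex[sl]
            band = np.minimum(a // 5, N_BANDS - 1)

            # 1. anthropogenic exposure increment per pollutant
            delta = np.empty((2, n_cur))
            for pi, pol in enumerate(POLLUTANTS):
                dist = (scen_dists[pol] if scenario.affects(pol, year)
                        else base_dists[pol])
                rows = (band * 2 + sx) * 3 + tert[pi, sl]
                ct = _eval_quantile(dist.q_total, dist.grid, rows, pct[pi, sl])
                cn = _eval_quantile(dist.q_natural, dist.grid, rows,
                                    pct[pi, sl])
                delta[pi] = np.maximum(ct - cn, 0.0)

            # per-disease risk multiplier on the anthropogenic increment
            rr = np.ones((nD, n_cur))
            for di, spec in enumerate(specs):
                lrr = np.zeros(n_cur)
                for pi, pol in enumerate(POLLUTANTS):
                    er = spec.er(pol)
                    if er is not None:
                        lrr += delta[pi] * (np.log(er) / 10.0)
                if lrr.any():
                    rr[di] = np.exp(lrr)

            # 2. incidence draws (hazard-scale multiplication)
            for di in annual_idx:
                spec = specs[di]
                u = rng.random(n_cur)
                at_risk = alive[sl] & ~has[:n_cur, di] & spec.eligible(a)
                p0 = hz[spec.name][a, sx]
                prob = -np.expm1(np.log1p(-np.minimum(p0, 1 - 1e-12)) * rr[di])
                new = at_risk & (u < prob)
                has[:n_cur, di][new] = True
                onset[:n_cur][new] = year
                rec["incident"][yi, di] = new.sum()
                rec["at_risk"][yi, di] = at_risk.sum()

            # 3. mortality: condition case fatality, then other causes
            dead = np.zeros(n_cur, dtype=bool)
            mort_sum = np.zeros((N_AGES, 2))
            for di, spec in enumerate(specs):
                if spec.mortality is not None:
                    mort_sum += spec.mortality
            for di, spec in enumerate(specs):
                u = rng.random(n_cur)
                if not spec.terminal:
                    continue
                cases = alive[sl] & has[:n_cur, di]
                if di in cf_by_duration:
                    cf_d = cf_by_duration[di]
                    dur = np.clip(year - onset[:n_cur], 0, cf_d.size - 1)
                    f = cf_d[dur]
                else:
                    f = spec.case_fatality[a, sx]
                d = cases & (u < f)
                rec["deaths"][yi, di] = d.sum()
                dead |= d
            mu = np.clip(lt - mort_sum, 0.0, 1.0)[a, sx]
            u = rng.random(n_cur)
            dead |= alive[sl] & (u < mu)
            died = alive[sl] & dead
            alive[:n_cur][died] = False
            rec["deaths_total"][yi] = died.sum()

            # prevalent cases surviving the year
            for di in annual_idx:
                rec["prevalent"][yi, di] = (alive[sl] & has[:n_cur, di]).sum()

            # 4. aging, births, birth outcomes
            age[:n_cur][alive[sl]] += 1
            mother_pool = np.flatnonzero(alive[sl] & (sx == 0)
                                         & (age[:n_cur] - 1 >= MOTHER_AGE_MIN)
                                         & (age[:n_cur] - 1 <= MOTHER_AGE_MAX))
            midx = rng.integers(0, max(mother_pool.size, 1), size=B)
            u_lbw = rng.random(B)
            for di in lbw_idx:
                spec = specs[di]
                if mother_pool.size == 0:
                    continue
                mothers = mother_pool[midx]
                p0 = hz[spec.name][np.minimum(age[mothers] - 1, N_AGES - 1), 0]
                prob = -np.expm1(np.log1p(-np.minimum(p0, 1 - 1e-12))
                                 * rr[di, mothers])
                n_lbw = int((u_lbw < prob).sum())
                rec["incident"][yi, di] = n_lbw
                rec["prevalent"][yi, di] = n_lbw
                rec["at_risk"][yi, di] = B
            new_sl = slice(n_cur, n_cur + B)
            age[new_sl] = 0
            sex[new_sl] = np.repeat([0, 1], [births_f, births_m])
            alive[new_sl] = True
            self._assign_exposure(rng, new_sl, age[new_sl], sex[new_sl],
                                  tert, pct, base_dists)
            n_cur += B
            rec["births"][yi] = B
            rec["alive"][yi] = alive[:n_cur].sum()
        return rec

    def _assign_exposure(self, rng, sl, ages, sexes, tert, pct, dists):
        """Lifetime-fixed (tertile, percentile) per pollutant, drawn from
        the person's initial stratum's tertile weights."""
        band = np.minimum(np.minimum(ages, N_AGES - 1) // 5, N_BANDS - 1)
        n = ages.size
        for pi, pol in enumerate(POLLUTANTS):
            w = dists[pol].weights[band, sexes]          # (n, 3)
            cw = np.cumsum(w, axis=1)
            cw /= cw[:, -1:]
            u = rng.random(n)
            tert[pi, sl] = (u[:, None] > cw).sum(axis=1)
            pct[pi, sl] = rng.random(n)


def scale_and_summarise(result: RunResult,
                        reference_population: float | None = None
                        ) -> pd.DataFrame:
    """Scale counts to the reference population and summarise across
    replicates (mean ± 1.96·sd/√R per year and disease); with a single
    replicate the CI columns are NaN (undefined width)."""
    if reference_population is not None:
        result = replace(result, reference_population=reference_population)
    frames = []
    for metric in ("incident", "prevalent", "deaths"):
        df = result.summarise(metric)
        df["metric"] = metric
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
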