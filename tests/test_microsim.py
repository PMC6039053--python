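import numpy as np
import pytest

from airburden import reporting
from airburden.epi import N_AGES, complete_epi_params
from airburden.exposure import N_BANDS
from airburden.microsim import (PollutionMicrosim, RunConfig, RunResult,
                                World, scale_and_summarise)
from airburden.reporting import ScenarioSpec
from airburden.synthetic_world import PopulationProfile
from conftest import flat_disease, make_uniform_dist, toy_world


def tiny_model(diseases=None, n=5000, reps=2, seed=11, **world_kw):
    w = toy_world(diseases if diseases is not None else [flat_disease()],
                  **world_kw)
    return PollutionMicrosim(w, RunConfig(n_individuals=n, replicates=reps,
                                          seed=seed)).fit()


class TestRunMechanics:
    def test_same_seed_reproduces_run_exactly(self):
        fit = tiny_model()
        a = fit.simulate(reporting.baseline())
        b = fit.simulate(reporting.baseline())
        assert np.array_equal(a.incident, b.incident)
        assert np.array_equal(a.cost, b.cost)

    def test_population_accounting_exact(self):
        fit = tiny_model(n=4000, reps=2)
        run = fit.simulate(reporting.baseline())
        for r in range(run.replicates):
            alive = run.alive[r]
            expected0 = 4000 + run.births[r, 0] - run.deaths_total[r, 0]
            assert alive[0] == expected0
            for t in range(1, alive.size):
                assert alive[t] == alive[t - 1] + run.births[r, t] \
                    - run.deaths_total[r, t]

    def test_zero_incidence_world_produces_nothing(self):
        fit = tiny_model([flat_disease(incidence=0.0)])
        run = fit.simulate(reporting.baseline())
        assert run.incident.sum() == 0
        assert run.cost.sum() == 0

    def test_null_exposure_response_gives_zero_attributable(self):
        """With all exposure–response values at 1 the counterfactual arm
        is draw-for-draw identical to baseline (common random numbers),
        so attributable counts vanish."""
        fit = tiny_model([flat_disease(er_pm25=1.0, er_no2=1.0)])
        base = fit.simulate(reporting.baseline())
        cf = fit.simulate(reporting.natural_counterfactual("pm25", "no2"))
        diff = reporting.attributable(base, cf)
        assert np.all(diff.incident == 0)
        assert np.all(diff.cost == 0)

    def test_prevalence_balance_per_disease(self):
        """Prevalent(t) can exceed prevalent(t-1)+incident(t)-deaths(t)
        only through never — other-cause deaths also remove cases."""
        fit = tiny_model(n=8000)
        run = fit.simulate(reporting.baseline())
        for r in range(run.replicates):
            prev = run.prevalent[r, :, 0]
            inc = run.incident[r, :, 0]
            dth = run.deaths[r, :, 0]
            for t in range(1, prev.size):
                assert prev[t] <= prev[t - 1] + inc[t] - dth[t] + 1e-9

    def test_missing_distribution_rejected_before_simulation(self):
        w = toy_world([flat_disease()])
        del w.distributions["no2"]
        with pytest.raises(ValueError, match="no2"):
            World(profile=w.profile, distributions=w.distributions,
                  diseases=w.diseases, costs=w.costs,
                  life_table=w.life_table)


class TestDrawExposure:
    def test_constant_tertile_returns_constant(self):
        dist = make_uniform_dist("pm25", [6.5, 6.5, 6.5])
        assert dist.quantile(3, 0, 1, 0.5) == 6.5

    def test_quantile_monotone_in_percentile(self):
        dist = make_uniform_dist("pm25", [2.0, 5.0, 9.0, 12.0])
        assert dist.quantile(0, 0, 0, 0.9) >= dist.quantile(0, 0, 0, 0.1)

    def test_identical_band_distributions_preserve_concentration(self):
        # aging across a band boundary with identical distributions
        dist = make_uniform_dist("pm25", [3.0, 8.0, 11.0])
        for p in (0.1, 0.5, 0.95):
            assert dist.quantile(4, 1, 2, p) == dist.quantile(5, 1, 2, p)


class TestScaleAndSummarise:
    def _result(self, counts, n=100, ref=100.0):
        counts = np.asarray(counts, dtype=float)[:, None, None]
        r = counts.shape[0]
        z = np.zeros_like(counts)
        return RunResult(
            scenario=ScenarioSpec("baseline"), years=np.array([2015]),
            diseases=["toy"], categories=("primary",), incident=counts,
            prevalent=z, deaths=z, at_risk=z,
            cost=np.zeros((r, 1, 1, 1)), alive=np.zeros((r, 1)),
            births=np.zeros((r, 1)), deaths_total=np.zeros((r, 1)),
            n_individuals=n, reference_population=ref, seed=0, evidence={})

    def test_hand_computed_normal_approximation_ci(self):
        res = self._result([10, 12, 14])
        df = res.summarise("incident")
        assert df["mean"].iloc[0] == pytest.approx(12.0)
        half = 1.96 * 2.0 / np.sqrt(3)
        assert df["hi"].iloc[0] - df["mean"].iloc[0] == pytest.approx(half)

    def test_single_replicate_ci_flagged_undefined(self):
        df = self._result([10]).summarise("incident")
        assert np.isnan(df["lo"].iloc[0]) and np.isnan(df["hi"].iloc[0])

    def test_unit_scaling_factor_is_identity(self):
        res = self._result([10, 12, 14], n=100, ref=100.0)
        assert res.scale_factor == 1.0
        assert res.summarise("incident")["mean"].iloc[0] == 12.0

    def test_scale_and_summarise_rescales(self):
        res = self._result([10], n=100, ref=1000.0)
        df = scale_and_summarise(res)
        inc = df[(df.metric == "incident")]
        assert inc["mean"].iloc[0] == pytest.approx(100.0)


def cohort_oracle(fit, scenario, years, n0):
    """Deterministic multi-state cohort recursion on the same rates as
    the engine: expected counts by (age, sex, exposure atom, state) for a
    single-disease world with a two-atom PM2.5 exposure distribution."""
    world = fit.model.world
    spec = fit.diseases[0]
    h0 = fit.reference_hazards[spec.name]
    lt = world.life_table
    profile = world.profile
    dist = world.distributions["pm25"]
    atoms = dist.q_total[0, 0, 0]                 # identical in all strata
    nat = dist.q_natural[0, 0, 0]
    nA = atoms.size
    er = spec.er("pm25")

    # expected initial population density per (age, sex, atom)
    dens = np.zeros((N_AGES, 2, nA))
    for b in range(N_BANDS):
        width = 10 if b == N_BANDS - 1 else 5
        for s in range(2):
            share = profile.share_by_age_sex[b, s]
            for a in range(b * 5, min(b * 5 + width, N_AGES)):
                dens[a, s, :] = n0 * share / width / nA
    healthy = dens * (1.0 - spec.prevalence[:, :, None])
    diseased = dens * spec.prevalence[:, :, None]

    births_f = round(n0 * profile.share_by_age_sex[0, 0] / 5.0)
    births_m = round(n0 * profile.share_by_age_sex[0, 1] / 5.0)

    inc_y, prev_y, death_y = [], [], []
    for year in years:
        delta = np.maximum(atoms - nat, 0.0)
        if scenario.affects("pm25", year):
            tq = scenario.transform()
            if tq.kind == "to_natural":
                delta = np.zeros_like(delta)
        rr = (er ** (delta / 10.0)) if er is not None else np.ones(nA)
        p0 = np.minimum(h0, 1 - 1e-12)
        prob = -np.expm1(np.log1p(-p0)[:, :, None] * rr[None, None, :])
        new = healthy * prob
        healthy = healthy - new
        diseased = diseased + new
        inc_y.append(new.sum())
        f = spec.case_fatality[:, :, None]
        m_tab = spec.mortality
        mu = np.clip(lt - m_tab, 0.0, 1.0)[:, :, None]
        death_y.append((diseased * f).sum())
        diseased = diseased * (1.0 - f) * (1.0 - mu)
        healthy = healthy * (1.0 - mu)
        prev_y.append(diseased.sum())
        # age one year (the last bin absorbs ages past the grid, as the
        # engine clamps table lookups at the top age) and add births
        for arr in (healthy, diseased):
            top = arr[-1].copy()
            arr[1:] = arr[:-1]
            arr[-1] += top
            arr[0] = 0.0
        healthy[0, 0, :] = births_f / nA
        healthy[0, 1, :] = births_m / nA
    return np.array(inc_y), np.array(prev_y), np.array(death_y)


class TestCohortOracleEquivalence:
    def test_simulation_matches_deterministic_cohort(self):
        """Simulated incident/prevalent/death counts agree with a
        deterministic multi-state cohort computation on the same rates
        within 3 Monte Carlo standard errors."""
        spec = flat_disease(incidence=0.008, case_fatality=0.05, er_pm25=1.5)
        n0, reps = 40_000, 6
        w = toy_world([spec], pm_totals=(0.0, 10.0))
        fit = PollutionMicrosim(
            w, RunConfig(n_individuals=n0, replicates=reps, seed=5)).fit()
        run = fit.simulate(reporting.baseline())
        oi, op, od = cohort_oracle(fit, run.scenario, run.years, n0)
        for sim, oracle in ((run.incident[:, :, 0], oi),
                            (run.prevalent[:, :, 0], op),
                            (run.deaths[:, :, 0], od)):
            tot = sim.sum(axis=1)
            se = tot.std(ddof=1) / np.sqrt(reps)
            assert abs(tot.mean() - oracle.sum()) < 3 * max(se, 1.0)


class TestCalibrationClosure:
    def test_baseline_incidence_matches_input_tables(self):
        """With calibrated reference hazards the baseline arm's incidence
        rate among the at-risk equals the input incidence within 3 MC SE
        (the calibration loop closes)."""
        i0 = 0.006
        spec = flat_disease(incidence=i0, case_fatality=0.02, er_pm25=1.5)
        fit = tiny_model([spec], n=40_000, reps=6, seed=3)
        run = fit.simulate(reporting.baseline())
        rate = run.incident[:, :, 0].sum(axis=1) / run.at_risk[:, :, 0].sum(axis=1)
        se = rate.std(ddof=1) / np.sqrt(run.replicates)
        assert abs(rate.mean() - i0) < 3 * se

    def test_mc_error_shrinks_with_population_size(self):
        """Doubling the population roughly halves the variance of scaled
        outputs (√2 shrinkage of the MC standard error)."""
        spec = flat_disease(incidence=0.005, case_fatality=0.02, er_pm25=1.3)
        seeds = range(40)
        sds = []
        for n in (1500, 3000):
            w = toy_world([spec])
            fit = PollutionMicrosim(
                w, RunConfig(n_individuals=n, replicates=1, seed=0)).fit()
            vals = [fit.simulate(reporting.baseline(), replicates=1, seed=s)
                    for s in seeds]
            scaled = [v.incident[0, :, 0].sum() * v.scale_factor for v in vals]
            sds.append(np.std(scaled, ddof=1))
        ratio = sds[0] / sds[1]
        assert 1.0 < ratio < 2.0
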