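import numpy as np
import pytest

from airburden.economics import EconConfig
from airburden.epi import DiseaseSpec, N_AGES
from airburden.exposure import (AGE_BANDS, N_BANDS, NO2, PM25,
                                ExposureDistribution)
from airburden.microsim import PollutionMicrosim, RunConfig, World
from airburden.pipeline import generate_world
from airburden.synthetic_world import PopulationProfile, gen_life_table


def make_uniform_dist(pollutant, totals, naturals=None, weights=None):
    """An ExposureDistribution in which every (band, sex, tertile)
    stratum carries the same quantile function: ``totals`` are the
    quantile values on an even percentile grid."""
    totals = np.asarray(totals, dtype=float)
    P = totals.size
    grid = np.linspace(0.0, 1.0, P)
    q_total = np.broadcast_to(totals, (N_BANDS, 2, 3, P)).copy()
    if naturals is None:
        naturals = np.zeros(P)
    q_natural = np.broadcast_to(np.asarray(naturals, dtype=float),
                                (N_BANDS, 2, 3, P)).copy()
    if weights is None:
        w = np.full((N_BANDS, 2, 3), 1.0 / 3.0)
    else:
        w = np.broadcast_to(np.asarray(weights, dtype=float),
                            (N_BANDS, 2, 3)).copy()
    return ExposureDistribution(pollutant, grid, q_total, q_natural, w)


def flat_disease(name="toy", incidence=0.005, case_fatality=0.02,
                 er_pm25=1.5, er_no2=None, age_min=0, age_max=99,
                 terminal=True, evidence="strong"):
    """A single condition with age/sex-constant rates (zero outside the
    eligible ages), suitable for closed-form oracles."""
    ages = np.arange(N_AGES)
    elig = (ages >= age_min) & (ages <= age_max)
    inc = np.where(elig, incidence, 0.0)[:, None].repeat(2, axis=1)
    cf = np.where(elig, case_fatality, 0.0)[:, None].repeat(2, axis=1)
    return DiseaseSpec(name=name, terminal=terminal, age_min=age_min,
                       age_max=age_max, evidence=evidence, er_pm25=er_pm25,
                       er_no2=er_no2, incidence=inc,
                       case_fatality=cf if terminal else None)


def toy_world(diseases, pm_totals=(0.0, 10.0), no2_totals=(0.0, 0.0),
              life_table=None, costs=None):
    """A minimal world: uniform two-point exposure distributions shared
    by all strata, caller-supplied diseases, optional flat life table."""
    if life_table is None:
        life_table = np.full((N_AGES, 2), 0.01)
    dists = {
        PM25: make_uniform_dist(PM25, pm_totals),
        NO2: make_uniform_dist(NO2, no2_totals),
    }
    return World(profile=PopulationProfile(), distributions=dists,
                 diseases=list(diseases), costs=costs or {},
                 life_table=np.asarray(life_table, dtype=float),
                 econ=EconConfig())


@pytest.fixture(scope="session")
def world():
    return generate_world(seed=7, n_points=400)


@pytest.fixture(scope="session")
def fitted(world):
    cfg = RunConfig(n_individuals=30_000, replicates=3, seed=7)
    return PollutionMicrosim(world, cfg).fit()


@pytest.fixture(scope="session")
def baseline_run(fitted):
    from airburden import reporting
    return fitted.simulate(reporting.baseline())
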