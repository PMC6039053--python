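"""Synthetic study inputs: population pyramid, pollutant surfaces,
population point locations, life table, disease and cost tables.

Every generator is a pure function of its parameters and a seed. The
statistical structure mirrors what the analysis assumes about England:
spatially correlated, approximately log-normal annual-average pollutant
fields with a non-anthropogenic (dust/sea-salt) floor for PM2.5 and none
for NO2; a 2015-style age/sex pyramid; disease rate tables that are
internally consistent by construction (prevalence and condition
mortality are forward-simulated from the chosen incidence and case
fatality, then only the cells a national source would publish are
retained, leaving the rest to be re-derived downstream).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from . import epi
from .economics import DEFAULT_COSTS, CostSpec
from .epi import AGES, N_AGES, DiseaseSpec, STRONG, WEAKER, forward_simulate
from .exposure import AGE_BANDS, N_BANDS, NO2, PM25, SEXES, ExposureSurface

#: England mid-2015 population estimate (persons), the scaling denominator.
ENGLAND_MID_2015 = 54_786_300

# Approximate England 2015 age distribution (share per 5-year band) and
# female share per band; smooth stand-in for the ONS mid-year pyramid.
_BAND_SHARES = np.array([
    0.063, 0.060, 0.056, 0.059, 0.065, 0.069, 0.067, 0.063, 0.067,
    0.071, 0.069, 0.060, 0.053, 0.052, 0.040, 0.031, 0.024, 0.015, 0.008,
])
_FEMALE_SHARE = np.array([
    0.488, 0.488, 0.488, 0.489, 0.495, 0.501, 0.503, 0.504, 0.506,
    0.508, 0.508, 0.509, 0.512, 0.517, 0.525, 0.540, 0.565, 0.610, 0.690,
])


@dataclass
class PopulationProfile:
    """Age/sex population structure plus the real-population denominator
    every simulated count is scaled to."""

    age_bands: tuple = AGE_BANDS
    share_by_age_sex: np.ndarray = None      # (n_bands, 2), sums to 1
    reference_population: float = ENGLAND_MID_2015

    def __post_init__(self):
        if self.share_by_age_sex is None:
            shares = _BAND_SHARES / _BAND_SHARES.sum()
            self.share_by_age_sex = np.stack(
                [shares * _FEMALE_SHARE, shares * (1.0 - _FEMALE_SHARE)], axis=1
            )
        self.share_by_age_sex = np.asarray(self.share_by_age_sex, dtype=float)
        if self.share_by_age_sex.shape != (len(self.age_bands), 2):
            raise ValueError("share_by_age_sex must be (n_bands, 2)")
        if (self.share_by_age_sex < 0).any():
            raise ValueError("population shares must be non-negative")
        if abs(self.share_by_age_sex.sum() - 1.0) > 1e-9:
            raise ValueError("population shares must sum to 1")
        if not self.reference_population > 0:
            raise ValueError("reference_population must be positive")


@dataclass
class SurfaceParams:
    """Parameters of a synthetic log-normal concentration field."""

    grid_nx: int = 50
    grid_ny: int = 50
    cell_size: float = 1000.0                # metres
    log_mean: float = np.log(10.0)           # log μg/m³
    log_sd: float = 0.25
    spatial_correlation_range: float = 5000.0
    natural_floor_mean: float = 0.0          # μg/m³

    def __post_init__(self):
        if self.grid_nx <= 0 or self.grid_ny <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.log_sd < 0:
            raise ValueError("log_sd must be non-negative")
        if self.natural_floor_mean < 0:
            raise ValueError("natural_floor_mean must be non-negative")


def gen_population(n_individuals: int, profile: PopulationProfile,
                   seed: int) -> pd.DataFrame:
    """Sample a virtual population table of (age, sex).

    Band/sex membership is multinomial on the profile shares; ages are
    uniform within the 5-year band (90+ treated as 90-99). Deterministic
    in (n_individuals, profile, seed).
    """
    if n_individuals < 0:
        raise ValueError("n_individuals must be non-negative")
    rng = np.random.default_rng(seed)
    n_bands = len(profile.age_bands)
    p = profile.share_by_age_sex.ravel()
    cells = rng.choice(p.size, size=n_individuals, p=p)
    band = cells // 2
    sex = cells % 2
    age = band * 5 + rng.integers(0, 5, size=n_individuals)
    # 90+ band spans ten single-year ages
    hi = band == n_bands - 1
    age[hi] = 90 + rng.integers(0, 10, size=int(hi.sum()))
    return pd.DataFrame(
        {"age": age.astype(int), "sex": np.array(SEXES)[sex]}
    )


def _correlated_field(shape, sigma_cells, rng):
    z = rng.standard_normal(shape)
    if sigma_cells > 0:
        z = ndimage.gaussian_filter(z, sigma=sigma_cells, mode="reflect")
        sd = z.std()
        if sd > 0:
            z = (z - z.mean()) / sd
    return z


def gen_surface(params: SurfaceParams, seed: int, pollutant: str = PM25,
                year: int = 2015) -> ExposureSurface:
    """Generate a spatially correlated log-normal concentration surface
    with an independent low-variance natural-component field clipped to
    [0, total]. With log_sd = 0 the field is constant at exp(log_mean);
    with natural_floor_mean = 0 the natural component is identically 0.
    """
    rng = np.random.default_rng(seed)
    shape = (params.grid_ny, params.grid_nx)
    sigma = params.spatial_correlation_range / params.cell_size
    z = _correlated_field(shape, sigma, rng)
    total = np.exp(params.log_mean + params.log_sd * z)
    if params.natural_floor_mean > 0:
        zn = _correlated_field(shape, sigma, rng)
        natural = params.natural_floor_mean * np.exp(0.2 * zn - 0.02)
        natural = np.clip(natural, 0.0, total)
    else:
        natural = np.zeros(shape)
    x = (np.arange(params.grid_nx) + 0.5) * params.cell_size
    y = (np.arange(params.grid_ny) + 0.5) * params.cell_size
    return ExposureSurface(pollutant, year, x, y, total, natural,
                           params.cell_size)


def gen_points(n_points: int, params: SurfaceParams, seed: int) -> pd.DataFrame:
    """Population point locations (postcode-centroid stand-ins) with
    log-normal population weights, uniform over the surface extent."""
    if n_points <= 0:
        raise ValueError("n_points must be positive")
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, params.grid_nx * params.cell_size, n_points)
    y = rng.uniform(0, params.grid_ny * params.cell_size, n_points)
    weight = rng.lognormal(mean=np.log(40.0), sigma=0.6, size=n_points)
    return pd.DataFrame({"x": x, "y": y, "weight": weight})


def gen_life_table() -> np.ndarray:
    """All-cause annual death probability by (age, sex): Gompertz–Makeham
    with an infant-mortality bump, female rates below male, England-like
    magnitudes. Shape (n_ages, 2), female column first."""
    age = AGES.astype(float)
    out = np.empty((N_AGES, 2))
    for s, scale in enumerate((0.75, 1.0)):   # female, male
        q = 2.0e-4 + scale * 2.5e-5 * np.exp(0.095 * age)
        q[0] += 0.0035
        out[:, s] = np.clip(q, 0.0, 0.7)
    return out


def _age_curve(base, slope, start, cap):
    a = np.maximum(AGES - start, 0.0)
    curve = np.where(AGES >= start, base * np.exp(slope * a), 0.0)
    return np.minimum(curve, cap)


def _by_sex(curve, male_factor):
    return np.stack([curve, np.minimum(curve * male_factor, 1.0)], axis=1)


def gen_disease_tables(seed: int = 0) -> tuple[list[DiseaseSpec], np.ndarray]:
    """Build the modelled conditions with internally consistent tables.

    For each condition a ground-truth annual incidence and case fatality
    are chosen (England-like orders of magnitude), prevalence and
    condition mortality are produced by the deterministic cohort
    recursion, and then only the cells a national source would publish
    are kept on the returned spec — the remainder is left for
    :func:`airburden.epi.complete_epi_params` to re-derive:

    - asthma (three age strata), CHD, stroke: incidence, prevalence and
      mortality published; case fatality derived
    - COPD, dementia: prevalence and mortality published; incidence and
      case fatality derived
    - type 2 diabetes: incidence and prevalence published; non-terminal
    - lung cancer: incidence, mortality and {1, 5, 10}-year survival
      published; prevalence not needed
    - low birth weight: incidence per birth; non-terminal, drawn per
      birth from the mother's exposure

    The ``seed`` argument is part of the generator contract but the
    default tables are deterministic; it perturbs nothing unless a
    future variant chooses to.

    Returns (specs, life_table).
    """
    del seed  # deterministic defaults
    lt = gen_life_table()

    # name -> (eligible ages, truth incidence f(age), truth case fatality,
    #          er_pm25, er_no2 published, evidence, publish pattern)
    defs = []

    def add(name, lo, hi, inc, cf, er_pm, er_no2, evidence, publish,
            birth_outcome=False, survival=None, terminal=True):
        defs.append(dict(name=name, lo=lo, hi=hi, inc=inc, cf=cf,
                         er_pm=er_pm, er_no2=er_no2, evidence=evidence,
                         publish=publish, birth_outcome=birth_outcome,
                         survival=survival, terminal=terminal))

    flat = lambda v: np.full(N_AGES, v)
    add("asthma_0_6", 0, 6, _age_curve(0.013, 0.0, 0, 0.013), flat(2e-5),
        None, 1.08, STRONG, "ipm")
    add("asthma_7_18", 7, 18, _age_curve(0.004, 0.0, 7, 0.004), flat(2e-5),
        1.48, 1.03, STRONG, "ipm")
    add("asthma_adult", 19, 99, _age_curve(0.0015, 0.0, 19, 0.0015),
        _age_curve(5e-5, 0.03, 19, 0.01), None, 1.04, STRONG, "ipm")
    add("copd", 19, 99, _age_curve(1.2e-4, 0.075, 40, 0.014),
        _age_curve(0.03, 0.02, 45, 0.25), 1.49, None, STRONG, "pm")
    add("chd", 19, 99, _age_curve(1.5e-4, 0.07, 30, 0.02),
        _age_curve(0.025, 0.02, 40, 0.30), 1.41, None, STRONG, "ipm")
    add("stroke", 19, 99, _age_curve(8e-5, 0.075, 30, 0.015),
        _age_curve(0.05, 0.0, 0, 0.05), 1.13, None, STRONG, "ipm")
    add("diabetes", 19, 99, _age_curve(9e-4, 0.045, 20, 0.012), flat(0.0),
        1.10, 1.05, STRONG, "ip", terminal=False)
    add("lung_cancer", 19, 99, _age_curve(6e-6, 0.095, 40, 0.004), None,
        1.09, 1.02, STRONG, "ims",
        survival={1: 0.40, 5: 0.16, 10: 0.10})
    add("dementia", 65, 99, _age_curve(2.5e-4, 0.13, 65, 0.09),
        flat(0.12), None, 1.01, WEAKER, "pm")
    add("low_birth_weight", 15, 49, flat(0.07), flat(0.0),
        1.39, 1.04, WEAKER, "i", birth_outcome=True, terminal=False)

    specs = []
    for d in defs:
        inc = _by_sex(d["inc"], 1.0 if d["name"].startswith(("asthma", "low"))
                      else 1.3)
        eligible = (AGES >= d["lo"]) & (AGES <= d["hi"])
        inc[~eligible] = 0.0
        if d["birth_outcome"]:
            specs.append(DiseaseSpec(
                name=d["name"], terminal=False, age_min=d["lo"],
                age_max=d["hi"], evidence=d["evidence"],
                er_pm25=d["er_pm"], er_no2=d["er_no2"],
                incidence=inc, birth_outcome=True,
            ))
            continue
        if d["survival"] is not None:
            cf_annual = epi.survival_to_case_fatality(d["survival"])
            cf = _by_sex(flat(float(cf_annual[0])), 1.0)
        else:
            cf = _by_sex(d["cf"], 1.0)
            cf[~eligible] = 0.0
        prev, mort = forward_simulate(inc, cf if d["terminal"] else
                                      np.zeros_like(cf), lt)
        spec = DiseaseSpec(
            name=d["name"], terminal=d["terminal"], age_min=d["lo"],
            age_max=d["hi"], evidence=d["evidence"],
            er_pm25=d["er_pm"], er_no2=d["er_no2"],
        )
        pub = d["publish"]
        if "i" in pub:
            spec.incidence = inc
        if "p" in pub:
            spec.prevalence = prev
        if "m" in pub:
            spec.mortality = mort
        if "s" in pub:
            spec.survival = d["survival"]
        specs.append(spec)
    return specs, lt


def gen_cost_tables() -> dict[str, CostSpec]:
    """Default cost-per-case(/death) inputs by care category (GBP,
    2015 values); low birth weight intentionally absent."""
    return dict(DEFAULT_COSTS)


def default_surface_params(pollutant: str) -> SurfaceParams:
    """Surface parameters sized so that, after the source-year-to-2015
    extrapolation offsets, PM2.5 sits near England urban annual means
    (~10 μg/m³ with a ~1 μg/m³ natural dust/sea-salt floor) and NO2 near
    ~22 μg/m³ with a fat enough upper tail that an annual-average
    40 μg/m³ cap binds somewhere."""
    if pollutant == PM25:
        return SurfaceParams(log_mean=np.log(11.4), log_sd=0.22,
                             natural_floor_mean=1.0)
    return SurfaceParams(log_mean=np.log(25.0), log_sd=0.40,
                         natural_floor_mean=0.0)
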