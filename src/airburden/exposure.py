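"""Exposure surfaces and population exposure distributions.

A gridded annual-average concentration surface (total and natural, i.e.
non-anthropogenic, components) is intersected with population point
locations to yield, per 5-year age band and sex, a tertile-structured
exposure distribution: each stratum's population-weighted concentrations
are split into three equal-weight tertiles, and within each tertile an
empirical weighted quantile function maps a lifetime percentile to a
concentration in μg/m³.

Scenario counterfactuals (reduction to natural levels, a fixed-δ
reduction, a concentration cap) act pointwise on the quantile functions,
so every transform is monotone and preserves quantile monotonicity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

PM25 = "pm25"
NO2 = "no2"
POLLUTANTS = (PM25, NO2)

SEXES = ("female", "male")

#: 5-year age bands, 0-4 ... 90+ (open band treated as 90-99).
AGE_BANDS = tuple(
    [f"{lo}-{lo + 4}" for lo in range(0, 90, 5)] + ["90+"]
)
N_BANDS = len(AGE_BANDS)
N_TERTILES = 3

#: Temporal extrapolation offsets (μg/m³) bringing the source-year
#: surfaces (2010 PM2.5, 2009 NO2) to 2015 rural-background levels.
EXTRAPOLATION_OFFSET = {PM25: -1.2, NO2: -2.3}


def age_to_band_index(age) -> np.ndarray:
    """Map integer age(s) to 5-year band index (90+ is the last band)."""
    return np.minimum(np.asarray(age) // 5, N_BANDS - 1)


class OutOfDomainError(ValueError):
    """A query point falls outside the surface's padded bounding box."""


class EmptyStratumError(ValueError):
    """An (age band, sex) stratum has no positive population weight."""


@dataclass
class ExposureSurface:
    """Gridded concentrations for one pollutant and year.

    ``total`` and ``natural`` are (ny, nx) arrays in μg/m³ on a regular
    grid of cell centres ``x`` (ascending, length nx) by ``y`` (ascending,
    length ny); ``natural <= total`` holds cellwise.
    """

    pollutant: str
    year: int
    x: np.ndarray
    y: np.ndarray
    total: np.ndarray
    natural: np.ndarray
    cell_size: float

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.total = np.asarray(self.total, dtype=float)
        self.natural = np.asarray(self.natural, dtype=float)
        if self.total.shape != (self.y.size, self.x.size):
            raise ValueError("total must have shape (len(y), len(x))")
        if self.natural.shape != self.total.shape:
            raise ValueError("natural must match total's shape")
        if (self.total < 0).any() or (self.natural < 0).any():
            raise ValueError("concentrations must be non-negative")
        if (self.natural > self.total + 1e-12).any():
            raise ValueError("natural component exceeds total concentration")

    def to_frame(self) -> pd.DataFrame:
        """Long-format (x, y, total, natural) table of all cells."""
        xx, yy = np.meshgrid(self.x, self.y)
        return pd.DataFrame(
            {
                "x": xx.ravel(),
                "y": yy.ravel(),
                "total": self.total.ravel(),
                "natural": self.natural.ravel(),
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, pollutant: str, year: int,
                   cell_size: float) -> "ExposureSurface":
        x = np.unique(frame["x"].to_numpy())
        y = np.unique(frame["y"].to_numpy())
        pivot_t = frame.pivot_table(index="y", columns="x", values="total")
        pivot_n = frame.pivot_table(index="y", columns="x", values="natural")
        return cls(pollutant, year, x, y,
                   pivot_t.to_numpy(), pivot_n.to_numpy(), cell_size)


def extrapolate_surface(surface: ExposureSurface, offset: float) -> ExposureSurface:
    """Shift every total concentration by ``offset`` μg/m³, flooring at the
    cell's natural component (the anthropogenic share cannot go negative).

    The natural component is unchanged.
    """
    if not math.isfinite(offset):
        raise ValueError("offset must be finite")
    total = np.maximum(surface.total + offset, surface.natural)
    return replace(surface, total=total, natural=surface.natural.copy())


def _nearest_index(coords: np.ndarray, q: np.ndarray, step: float) -> np.ndarray:
    # nearest cell centre; exact midpoints resolve to the lower index
    t = (np.asarray(q, dtype=float) - coords[0]) / step
    idx = np.ceil(t - 0.5).astype(int)
    return np.clip(idx, 0, coords.size - 1)


def lookup_concentration(surface: ExposureSurface, point):
    """Nearest-cell (total, natural) at ``point`` = (x, y) or arrays thereof.

    Points must lie within the grid bounding box expanded by half a cell;
    midpoint ties break to the lower x, then lower y, cell centre.
    """
    px = np.asarray(point[0], dtype=float)
    py = np.asarray(point[1], dtype=float)
    half = surface.cell_size / 2.0
    if (
        (px < surface.x[0] - half).any() or (px > surface.x[-1] + half).any()
        or (py < surface.y[0] - half).any() or (py > surface.y[-1] + half).any()
    ):
        raise OutOfDomainError(
            "point outside surface bounding box (padded by half a cell)"
        )
    ix = _nearest_index(surface.x, px, surface.cell_size)
    iy = _nearest_index(surface.y, py, surface.cell_size)
    return surface.total[iy, ix], surface.natural[iy, ix]


def weighted_quantile(values, weights, probs) -> np.ndarray:
    """Type-1 (left-continuous step) weighted empirical quantile function."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    order = np.argsort(values, kind="stable")
    v = values[order]
    cum = np.cumsum(weights[order])
    cum /= cum[-1]
    idx = np.searchsorted(cum, np.asarray(probs, dtype=float) - 1e-12, side="left")
    return v[np.clip(idx, 0, v.size - 1)]


@dataclass
class ExposureDistribution:
    """Per-(age band, sex, tertile) quantile functions for one pollutant.

    ``q_total`` and ``q_natural`` have shape (n_bands, 2, 3, P) where P is
    the length of the percentile ``grid``; ``weights`` (n_bands, 2, 3) are
    the tertile population shares within each stratum (≈ 1/3 each). The
    natural quantile function is the tertile's own natural-component
    distribution; because natural ≤ total pointwise at the source points,
    q_natural ≤ q_total at every percentile.
    """

    pollutant: str
    grid: np.ndarray
    q_total: np.ndarray
    q_natural: np.ndarray
    weights: np.ndarray
    age_bands: tuple = AGE_BANDS
    sexes: tuple = SEXES

    def quantile(self, band_idx, sex_idx, tertile, percentile, which="total"):
        """Concentration at a lifetime percentile within one tertile.

        The P grid points are equal-probability atoms: a uniform
        percentile selects each grid value with mass 1/P, so expectation
        over percentiles equals the plain mean of the grid values (the
        quantity the hazard calibration uses).
        """
        q = self.q_total if which == "total" else self.q_natural
        P = self.grid.size
        idx = np.minimum((np.asarray(percentile, dtype=float) * P).astype(int),
                         P - 1)
        return q[band_idx, sex_idx, tertile][idx]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for b, band in enumerate(self.age_bands):
            for s, sex in enumerate(self.sexes):
                for t in range(N_TERTILES):
                    rows.append(
                        pd.DataFrame(
                            {
                                "pollutant": self.pollutant,
                                "age_band": band,
                                "sex": sex,
                                "tertile": t + 1,
                                "tertile_weight": self.weights[b, s, t],
                                "percentile": self.grid,
                                "total": self.q_total[b, s, t],
                                "natural": self.q_natural[b, s, t],
                            }
                        )
                    )
        return pd.concat(rows, ignore_index=True)


def _split_tertiles(conc, natural, w):
    """Split a sorted-by-concentration weighted sample into three
    equal-weight groups, dividing boundary-straddling points."""
    order = np.argsort(conc, kind="stable")
    conc, natural, w = conc[order], natural[order], w[order]
    W = w.sum()
    edges = [0.0, W / 3.0, 2.0 * W / 3.0, W]
    cum_hi = np.cumsum(w)
    cum_lo = cum_hi - w
    groups = []
    for t in range(3):
        lo, hi = edges[t], edges[t + 1]
        ov = np.minimum(cum_hi, hi) - np.maximum(cum_lo, lo)
        mask = ov > 1e-12 * max(W, 1.0)
        groups.append((conc[mask], natural[mask], ov[mask]))
    return groups


def build_distributions(points: pd.DataFrame, pollutant: str,
                        grid: np.ndarray | None = None) -> ExposureDistribution:
    """Build per-stratum tertile exposure distributions from a table of
    (concentration, natural, weight, age_band, sex) population points.

    Within each (age band, sex) stratum, points are split by total
    concentration into three equal-weight tertiles (points straddling a
    boundary have their weight divided); the per-tertile quantile
    functions are weighted empirical quantiles evaluated on ``grid``.
    Doubling all weights leaves the result unchanged.
    """
    if grid is None:
        grid = np.linspace(0.0, 1.0, 101)
    grid = np.asarray(grid, dtype=float)
    if "natural" not in points.columns:
        points = points.assign(natural=0.0)
    if (points["weight"] < 0).any():
        raise ValueError("population weights must be non-negative")

    P = grid.size
    q_total = np.zeros((N_BANDS, 2, N_TERTILES, P))
    q_natural = np.zeros_like(q_total)
    weights = np.zeros((N_BANDS, 2, N_TERTILES))
    by = points.groupby(["age_band", "sex"], sort=False)
    for b, band in enumerate(AGE_BANDS):
        for s, sex in enumerate(SEXES):
            try:
                g = by.get_group((band, sex))
            except KeyError:
                raise EmptyStratumError(
                    f"no population points for stratum ({band}, {sex})"
                ) from None
            w = g["weight"].to_numpy(dtype=float)
            if w.sum() <= 0:
                raise EmptyStratumError(
                    f"zero total weight in stratum ({band}, {sex})"
                )
            conc = g["concentration"].to_numpy(dtype=float)
            nat = g["natural"].to_numpy(dtype=float)
            W = w.sum()
            for t, (c_t, n_t, w_t) in enumerate(_split_tertiles(conc, nat, w)):
                q_total[b, s, t] = weighted_quantile(c_t, w_t, grid)
                q_natural[b, s, t] = weighted_quantile(n_t, w_t, grid)
                weights[b, s, t] = w_t.sum() / W
    return ExposureDistribution(pollutant, grid, q_total, q_natural, weights)


@dataclass(frozen=True)
class Transform:
    """A counterfactual acting pointwise on total-concentration quantiles.

    kind: 'identity' | 'to_natural' | 'subtract' (δ μg/m³, floored at the
    natural level) | 'cap' (min with limit L μg/m³).
    """

    kind: str = "identity"
    delta: float = 0.0
    limit: float = float("inf")

    def __post_init__(self):
        if self.kind not in ("identity", "to_natural", "subtract", "cap"):
            raise ValueError(f"unknown transform kind {self.kind!r}")
        if self.kind == "subtract" and self.delta < 0:
            raise ValueError("subtract requires delta >= 0")
        if self.kind == "cap" and not self.limit > 0:
            raise ValueError("cap requires a positive limit")


def transform_for_scenario(dist: ExposureDistribution,
                           transform: Transform) -> ExposureDistribution:
    """Apply a scenario counterfactual to every quantile function.

    All transforms are monotone non-increasing on concentrations, never
    take the total below the natural level, and preserve quantile
    monotonicity; ``to_natural`` is idempotent.
    """
    qt, qn = dist.q_total, dist.q_natural
    if transform.kind == "identity":
        new = qt.copy()
    elif transform.kind == "to_natural":
        new = qn.copy()
    elif transform.kind == "subtract":
        new = np.maximum(qt - transform.delta, qn)
    elif transform.kind == "cap":
        new = np.maximum(np.minimum(qt, transform.limit), qn)
    return replace(dist, q_total=new, q_natural=qn.copy())
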