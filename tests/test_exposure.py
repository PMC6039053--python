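import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from airburden.exposure import (AGE_BANDS, NO2, PM25, EmptyStratumError,
                                ExposureSurface, OutOfDomainError, Transform,
                                build_distributions, extrapolate_surface,
                                lookup_concentration, transform_for_scenario,
                                weighted_quantile)
from conftest import make_uniform_dist


def small_surface(nx=4, ny=3, cell=100.0, total=None, natural=None):
    x = (np.arange(nx) + 0.5) * cell
    y = (np.arange(ny) + 0.5) * cell
    if total is None:
        total = np.arange(nx * ny, dtype=float).reshape(ny, nx) + 5.0
    if natural is None:
        natural = np.full((ny, nx), 1.0)
    return ExposureSurface(PM25, 2010, x, y, total, natural, cell)


class TestExtrapolateSurface:
    def test_pm25_offset_shifts_concentration(self):
        s = small_surface(total=np.full((3, 4), 12.0))
        out = extrapolate_surface(s, -1.2)
        assert np.allclose(out.total, 10.8)

    def test_zero_offset_is_identity(self):
        s = small_surface()
        out = extrapolate_surface(s, 0.0)
        assert np.array_equal(out.total, s.total)

    def test_shift_floors_at_natural_component(self):
        s = small_surface(total=np.full((3, 4), 1.0),
                          natural=np.full((3, 4), 0.9))
        out = extrapolate_surface(s, -2.3)
        # elementwise-max oracle
        assert np.array_equal(out.total, np.maximum(1.0 - 2.3, 0.9)
                              * np.ones((3, 4)))
        assert np.allclose(out.total, 0.9)
        assert np.array_equal(out.natural, s.natural)

    def test_non_finite_offset_rejected(self):
        with pytest.raises(ValueError):
            extrapolate_surface(small_surface(), float("nan"))


class TestLookupConcentration:
    def test_point_at_cell_centre(self):
        s = small_surface()
        t, n = lookup_concentration(s, (s.x[2], s.y[1]))
        assert t == s.total[1, 2] and n == s.natural[1, 2]

    def test_midpoint_tie_breaks_to_lower_x(self):
        s = small_surface()
        # point exactly between centres x=150 and x=250 is (200, y)
        t, _ = lookup_concentration(s, (200.0, 50.0))
        assert t == s.total[0, 1]

    def test_out_of_domain_raises(self):
        s = small_surface()
        with pytest.raises(OutOfDomainError):
            lookup_concentration(s, (-60.0, 50.0))

    def test_matches_brute_force_nearest_neighbour(self):
        rng = np.random.default_rng(0)
        s = small_surface(nx=10, ny=7)
        pts_x = rng.uniform(0, 10 * 100.0, 200)
        pts_y = rng.uniform(0, 7 * 100.0, 200)
        t, n = lookup_concentration(s, (pts_x, pts_y))
        for k in range(200):
            d2 = (s.x[None, :] - pts_x[k]) ** 2 + (s.y[:, None] - pts_y[k]) ** 2
            best = np.unravel_index(np.argmin(d2), d2.shape)
            assert t[k] == s.total[best]


def stratum_frame(conc, weight, natural=None):
    """All strata share the same points (keeps every stratum non-empty)."""
    frames = []
    for band in AGE_BANDS:
        for sex in ("female", "male"):
            frames.append(pd.DataFrame({
                "concentration": conc,
                "natural": 0.0 if natural is None else natural,
                "weight": weight, "age_band": band, "sex": sex}))
    return pd.concat(frames, ignore_index=True)


class TestBuildDistributions:
    def test_single_value_stratum_gives_constant_tertiles(self):
        dist = build_distributions(stratum_frame([7.5], [10.0]), PM25)
        assert np.allclose(dist.q_total, 7.5)
        assert np.allclose(dist.weights, 1.0 / 3.0)

    def test_six_equal_points_split_into_pairs(self):
        dist = build_distributions(
            stratum_frame([1, 2, 3, 4, 5, 6], np.ones(6)), PM25)
        for t, (lo, hi) in enumerate([(1, 2), (3, 4), (5, 6)]):
            q = dist.q_total[0, 0, t]
            assert q.min() == lo and q.max() == hi

    def test_doubling_weights_leaves_distribution_unchanged(self):
        conc = [3.0, 9.0, 4.0, 8.0, 1.0]
        w = [1.0, 2.0, 0.5, 1.5, 3.0]
        a = build_distributions(stratum_frame(conc, w), PM25)
        b = build_distributions(stratum_frame(conc, [2 * x for x in w]), PM25)
        assert np.array_equal(a.q_total, b.q_total)
        assert np.array_equal(a.weights, b.weights)

    def test_empty_stratum_error_names_stratum(self):
        frame = stratum_frame([1.0], [1.0])
        frame = frame[~((frame.age_band == "40-44")
                        & (frame.sex == "male"))]
        with pytest.raises(EmptyStratumError, match="40-44.*male"):
            build_distributions(frame, PM25)

    def test_quantiles_monotone_within_and_across_tertiles(self):
        rng = np.random.default_rng(4)
        dist = build_distributions(
            stratum_frame(rng.lognormal(2, 0.4, 60), rng.uniform(1, 5, 60)),
            PM25)
        assert (np.diff(dist.q_total, axis=-1) >= 0).all()
        # matched percentiles are non-decreasing across tertiles
        assert (np.diff(dist.q_total, axis=2) >= -1e-12).all()
        assert np.allclose(dist.weights.sum(axis=2), 1.0)

    def test_natural_quantiles_below_total(self):
        rng = np.random.default_rng(5)
        conc = rng.lognormal(2.3, 0.3, 50)
        nat = np.minimum(rng.lognormal(0, 0.2, 50), conc)
        dist = build_distributions(stratum_frame(conc, np.ones(50), nat), PM25)
        assert (dist.q_natural <= dist.q_total + 1e-12).all()


class TestWeightedQuantile:
    def test_hand_computed_step_quantile(self):
        q = weighted_quantile([10.0, 20.0, 30.0], [1.0, 1.0, 2.0],
                              [0.0, 0.25, 0.5, 0.75, 1.0])
        assert list(q) == [10.0, 10.0, 20.0, 30.0, 30.0]


class TestTransforms:
    def test_cap_forty_truncates_above(self):
        dist = make_uniform_dist(NO2, [30.0, 35.0, 45.0])
        out = transform_for_scenario(dist, Transform("cap", limit=40.0))
        assert list(out.q_total[0, 0, 0]) == [30.0, 35.0, 40.0]

    def test_subtract_floors_at_natural(self):
        dist = make_uniform_dist(PM25, [10.8, 10.8], naturals=[2.0, 2.0])
        out = transform_for_scenario(dist, Transform("subtract", delta=1.0))
        assert np.allclose(out.q_total, max(10.8 - 1.0, 2.0))
        out2 = transform_for_scenario(dist, Transform("subtract", delta=10.0))
        assert np.allclose(out2.q_total, 2.0)

    def test_to_natural_is_idempotent(self):
        dist = make_uniform_dist(PM25, [5.0, 12.0], naturals=[1.0, 1.5])
        once = transform_for_scenario(dist, Transform("to_natural"))
        twice = transform_for_scenario(once, Transform("to_natural"))
        assert np.array_equal(once.q_total, twice.q_total)
        assert np.array_equal(once.q_total, dist.q_natural)

    def test_no2_natural_level_is_zero(self):
        dist = make_uniform_dist(NO2, [20.0, 40.0])
        out = transform_for_scenario(dist, Transform("to_natural"))
        assert np.all(out.q_total == 0.0)

    @given(delta=st.floats(0, 50), limit=st.floats(0.1, 100))
    @settings(max_examples=50, deadline=None)
    def test_transforms_monotone_non_increasing(self, delta, limit):
        dist = make_uniform_dist(PM25, [2.0, 11.0, 30.0],
                                 naturals=[0.5, 1.0, 1.0])
        for tr in (Transform("identity"), Transform("to_natural"),
                   Transform("subtract", delta=delta),
                   Transform("cap", limit=limit)):
            out = transform_for_scenario(dist, tr)
            assert (out.q_total <= dist.q_total + 1e-12).all()
            assert (np.diff(out.q_total, axis=-1) >= -1e-12).all()
            assert (out.q_total >= out.q_natural - 1e-12).all()

    def test_unknown_transform_rejected(self):
        with pytest.raises(ValueError):
            Transform("sqrt")
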