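"""Haversine distances, pair tables, regression and dispersion classes."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skbio import DistanceMatrix

from ribotax.geography import (
    EARTH_RADIUS_KM,
    GeoPairRecord,
    RegressionResult,
    build_pair_table,
    classify_dispersion,
    fit_regression,
    haversine_km,
)
from ribotax.records import Site

coords = st.tuples(
    st.floats(min_value=-89.0, max_value=89.0),
    st.floats(min_value=-179.0, max_value=180.0),
)


class TestHaversine:
    def test_identical_points_zero(self):
        assert haversine_km((12.3, 45.6), (12.3, 45.6)) == 0.0

    def test_half_circumference(self):
        assert haversine_km((0, 0), (0, 180)) == pytest.approx(
            math.pi * EARTH_RADIUS_KM, abs=1e-3
        )

    def test_quarter_circumference_pole(self):
        assert haversine_km((0, 0), (90, 0)) == pytest.approx(
            math.pi * EARTH_RADIUS_KM / 2, abs=1e-3
        )

    def test_waypoint_path_sums_legs(self):
        direct = haversine_km((0, 0), (0, 90))
        via = haversine_km((0, 0), (0, 90), waypoints=[(0, 45)])
        assert via == pytest.approx(direct)  # waypoint on the great circle

    def test_out_of_bounds_error(self):
        with pytest.raises(ValueError):
            haversine_km((95, 0), (0, 0))

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(a=coords, b=coords)
    def test_symmetric_and_nonnegative(self, a, b):
        d1, d2 = haversine_km(a, b), haversine_km(b, a)
        assert d1 == pytest.approx(d2, abs=1e-9)
        assert d1 >= 0

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(a=coords, b=coords, c=coords)
    def test_triangle_inequality(self, a, b, c):
        assert haversine_km(a, c) <= haversine_km(a, b) + haversine_km(b, c) + 1e-6


def _sites(n):
    return {
        f"s{i:02d}": Site(f"s{i:02d}", f"Site {i}", float(i), float(10 * i % 170))
        for i in range(n)
    }


def _patristic(tips):
    rng = np.random.default_rng(0)
    n = len(tips)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = rng.uniform(0.01, 0.2)
    return DistanceMatrix(m, tips)


class TestPairTable:
    def test_13_sites_give_78_pairs(self):
        sites = _sites(13)
        tips = [f"t{i}" for i in range(13)]
        site_tips = {s: {tips[i]} for i, s in enumerate(sorted(sites))}
        pairs = build_pair_table(sites, site_tips, _patristic(tips))
        assert len(pairs) == 78

    def test_two_sites_one_pair(self):
        sites = _sites(2)
        site_tips = {"s00": {"t0"}, "s01": {"t1"}}
        pairs = build_pair_table(sites, site_tips, _patristic(["t0", "t1"]))
        assert len(pairs) == 1

    def test_site_without_tips_excluded(self):
        sites = _sites(3)
        site_tips = {"s00": {"t0"}, "s01": {"t1"}, "s02": set()}
        pairs = build_pair_table(sites, site_tips, _patristic(["t0", "t1"]))
        assert len(pairs) == 1

    def test_waypoint_override_not_shorter(self):
        sites = {
            "a": Site("a", "A", 20.0, -158.0),
            "b": Site("b", "B", 37.0, 15.0),
        }
        site_tips = {"a": {"t0"}, "b": {"t1"}}
        override = {frozenset({"a", "b"}): [(0.0, -70.0)]}
        direct = build_pair_table(sites, site_tips, _patristic(["t0", "t1"]))
        routed = build_pair_table(
            sites, site_tips, _patristic(["t0", "t1"]), routing_overrides=override
        )
        assert routed[0].geographic_km >= direct[0].geographic_km

    def test_summaries_ordered(self):
        sites = _sites(4)
        tips = [f"t{i}" for i in range(8)]
        site_tips = {
            s: {tips[2 * i], tips[2 * i + 1]} for i, s in enumerate(sorted(sites))
        }
        for p in build_pair_table(sites, site_tips, _patristic(tips)):
            assert p.patristic_min <= p.patristic_mean <= p.patristic_max


class TestRegression:
    def _linear_pairs(self, slope=1e-5, intercept=0.01, n=10, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        out = []
        for i in range(n):
            x = 500.0 * (i + 1)
            y = intercept + slope * x + (rng.normal(0, noise) if noise else 0.0)
            out.append(
                GeoPairRecord(f"a{i}", f"b{i}", x, y, y - 0.002, y + 0.002)
            )
        return out

    def test_exact_line_r_squared_one(self):
        fit = fit_regression(self._linear_pairs())
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.slope == pytest.approx(1e-5)
        assert fit.intercept == pytest.approx(0.01)

    def test_zero_range_zero_halfwidth(self):
        pairs = [
            GeoPairRecord(f"a{i}", f"b{i}", 100.0 * (i + 1), 0.01 * i, 0.01 * i, 0.01 * i)
            for i in range(5)
        ]
        assert fit_regression(pairs).band_halfwidth == 0.0

    def test_parameter_recovery_with_noise(self):
        slopes = []
        for seed in range(10):
            fit = fit_regression(
                self._linear_pairs(n=40, noise=0.003, seed=seed)
            )
            slopes.append(fit.slope)
        assert np.mean(slopes) == pytest.approx(1e-5, rel=0.2)

    def test_zero_geographic_variance_error(self):
        pairs = [
            GeoPairRecord(f"a{i}", f"b{i}", 100.0, 0.01 * i, 0.0, 0.1)
            for i in range(5)
        ]
        with pytest.raises(ValueError):
            fit_regression(pairs)

    def test_too_few_pairs_error(self):
        with pytest.raises(ValueError):
            fit_regression(self._linear_pairs(n=2))


class TestDispersionClasses:
    FIT = RegressionResult(slope=0.0, intercept=0.05, r_squared=1.0,
                           p_value=0.0, band_halfwidth=0.01)

    def _pair(self, mean):
        return GeoPairRecord("a", "b", 1000.0, mean, mean, mean)

    def test_far_above_band_overdispersed(self):
        out = classify_dispersion([self._pair(0.05 + 5 * 0.01)], self.FIT)
        assert out[0].dispersion == "overdispersed"

    def test_far_below_band_underdispersed(self):
        out = classify_dispersion([self._pair(0.05 - 5 * 0.01)], self.FIT)
        assert out[0].dispersion == "underdispersed"

    def test_on_prediction_consistent(self):
        out = classify_dispersion([self._pair(0.05)], self.FIT)
        assert out[0].dispersion == "consistent"
        assert out[0].predicted == pytest.approx(0.05)
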