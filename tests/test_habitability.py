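import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coptdrake.habitability import (
    HabitabilityFractions,
    VariabilityRange,
    fi_product,
    foc_from_population,
    foc_ratio_bounds,
    fpt_estimate,
)
from coptdrake.population import PlanetPopulation
from coptdrake.water_budget import PlanetSpec, permitted_window


class TestFocRatioBounds:
    def test_headline_bracket(self):
        low, high = foc_ratio_bounds(0.009, 0.04, VariabilityRange(3.8, 55))
        assert low == pytest.approx(0.009 / 55)
        assert high == pytest.approx(0.04 / 3.8)
        # rounds to the published (0.00016, 0.011)
        assert round(low, 5) == 0.00016
        assert round(high, 3) == 0.011

    def test_window_equal_to_variability_gives_unity(self):
        w = 0.5
        # widths equal to the variability endpoints: certainty of being inside
        assert foc_ratio_bounds(w, w, VariabilityRange(w, w + 1e-12)) == pytest.approx((w / (w + 1e-12), 1.0))

    def test_earth_only_widths(self):
        low, high = foc_ratio_bounds(0.02, 0.02, VariabilityRange(3.8, 55))
        assert low == pytest.approx(0.02 / 55)
        assert high == pytest.approx(0.02 / 3.8)

    def test_rejects_window_wider_than_variability(self):
        with pytest.raises(ValueError):
            foc_ratio_bounds(0.5, 4.0, VariabilityRange(3.8, 55))

    def test_rejects_degenerate_variability(self):
        with pytest.raises(ValueError):
            VariabilityRange(0.0, 55)
        with pytest.raises(ValueError):
            VariabilityRange(5.0, 5.0)

    @settings(deadline=None, max_examples=50)
    @given(
        widths=st.tuples(
            st.floats(min_value=1e-4, max_value=0.1),
            st.floats(min_value=1e-4, max_value=0.1),
        ),
        scale=st.floats(min_value=0.01, max_value=100),
    )
    def test_dimensionless_and_ordered(self, widths, scale):
        wl, wh = sorted(widths)
        var = VariabilityRange(1.0, 10.0)
        low, high = foc_ratio_bounds(wl, wh, var)
        assert 0 < low <= high
        # scaling widths and variability together leaves the ratio unchanged
        scaled = foc_ratio_bounds(
            wl * scale, wh * scale, VariabilityRange(scale, 10 * scale)
        )
        assert scaled == pytest.approx((low, high))


class TestFptEstimate:
    def test_default_product(self):
        est = fpt_estimate()
        assert est.value == pytest.approx(0.165)
        assert est.is_upper_bound

    def test_stellar_cut_only(self):
        assert fpt_estimate(0.33, 1.0).value == pytest.approx(0.33)

    def test_extra_factors_multiply(self):
        assert fpt_estimate(0.33, 0.5, [0.5]).value == pytest.approx(0.0825)

    def test_rejects_factor_outside_unit_interval(self):
        with pytest.raises(ValueError):
            fpt_estimate(1.5, 0.5)
        with pytest.raises(ValueError):
            fpt_estimate(0.33, 0.5, [-0.1])


class TestFiProduct:
    def test_headline_product(self):
        low, high = fi_product((0.00016, 0.011), 0.17)
        assert low == pytest.approx(2.72e-5)
        assert high == pytest.approx(1.87e-3)

    @pytest.mark.parametrize(
        "bounds, fpt, expected",
        [(((0.0, 0.0)), 0.7, (0.0, 0.0)), ((1.0, 1.0), 1.0, (1.0, 1.0))],
    )
    def test_degenerate_cases(self, bounds, fpt, expected):
        assert fi_product(bounds, fpt) == pytest.approx(expected)

    @settings(deadline=None, max_examples=50)
    @given(
        a=st.floats(min_value=0, max_value=1),
        b=st.floats(min_value=0, max_value=1),
        f=st.floats(min_value=0, max_value=1),
    )
    def test_outputs_in_unit_interval_and_monotone(self, a, b, f):
        lo, hi = sorted((a, b))
        out = fi_product((lo, hi), f)
        assert 0 <= out[0] <= out[1] <= 1
        # monotone non-decreasing in fpt
        if f < 1:
            bigger = fi_product((lo, hi), min(1.0, f + 0.1))
            assert bigger[0] >= out[0] and bigger[1] >= out[1]

    def test_bundled_fractions_type(self):
        hf = HabitabilityFractions(0.00016, 0.011, 0.17)
        assert hf.fi_low == pytest.approx(0.00016 * 0.17)
        assert hf.fi_high == pytest.approx(0.011 * 0.17)


class TestFocFromPopulation:
    def test_counts_matching_membership(self):
        # 4 planets, exactly one inside its radius-dependent window
        pop = PlanetPopulation(
            radius=np.array([1.0, 1.0, 2.0, 0.5]),
            water_fraction=np.array([0.0224, 5.0, 0.0, 40.0]),
        )
        est = foc_from_population(pop)
        assert est.value == 0.25
        assert est.n_inside == 1
        assert est.std_error == pytest.approx(math.sqrt(0.25 * 0.75 / 4))

    def test_all_dry_population_is_zero(self):
        pop = PlanetPopulation(
            radius=np.ones(10), water_fraction=np.zeros(10)
        )
        assert foc_from_population(pop).value == 0.0

    def test_matches_bruteforce_membership(self):
        rng = np.random.default_rng(42)
        radius = rng.uniform(0.5, 2.35, size=100)
        water = rng.uniform(0, 0.06, size=100) * radius ** rng.choice([0, 1], 100)
        pop = PlanetPopulation(radius=radius, water_fraction=water)
        expected = sum(
            permitted_window(PlanetSpec(r)).contains(f)
            for r, f in zip(radius, water)
        ) / 100
        assert foc_from_population(pop).value == pytest.approx(expected)

    def test_boundary_planets_count_as_inside(self):
        pop = PlanetPopulation(
            radius=np.array([1.0, 1.0]), water_fraction=np.array([0.007, 0.027])
        )
        assert foc_from_population(pop).value == 1.0

    def test_korenaga_mode_admits_more(self):
        rng = np.random.default_rng(7)
        pop = PlanetPopulation(
            radius=rng.uniform(0.5, 2.35, 5000),
            water_fraction=rng.uniform(0, 0.08, 5000),
        )
        cons = foc_from_population(pop, "conservative").value
        kor = foc_from_population(pop, "korenaga").value
        assert kor >= cons

    def test_rejects_empty_and_invalid(self):
        with pytest.raises(ValueError):
            PlanetPopulation(radius=np.array([]), water_fraction=np.array([]))
        bad = PlanetPopulation(
            radius=np.array([1.0]), water_fraction=np.array([-1.0])
        )
        with pytest.raises(ValueError):
            foc_from_population(bad)
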