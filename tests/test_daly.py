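"""DALY engine: closed form vs quadrature, published factors, invariants."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from obcea.daly import (AgeProfile, DalyParameters, InvalidParameterError,
                        LifeTable, daly_per_maternal_death,
                        daly_per_stillbirth, discounted_weighted_years,
                        interpolate_life_expectancy, yld_maternal,
                        yll_maternal)


def quad_oracle(a, L, params):
    """Adaptive quadrature of the age-weighted discounted life-year integrand."""
    K, C = params.effective_K, params.age_weight_constant_C
    r, B = params.effective_r, params.age_weight_B

    def integrand(x):
        return (K * C * x * math.exp(-B * x) + (1 - K)) * math.exp(-r * (x - a))

    value, _ = quad(integrand, a, a + L, limit=200)
    return value


class TestDiscountedWeightedYears:
    def test_matches_quadrature_at_base_case(self, params):
        value = discounted_weighted_years(29.9, 43.4, params)
        assert value == pytest.approx(quad_oracle(29.9, 43.4, params), rel=1e-6)

    def test_matches_quadrature_over_random_parameters(self):
        rng = np.random.default_rng(20260923)
        for _ in range(100):
            a = rng.uniform(0, 80)
            L = rng.uniform(0.5, 90)
            p = DalyParameters(
                age_weight_K=rng.uniform(0, 1),
                age_weight_constant_C=rng.uniform(0.05, 0.3),
                discount_rate_r=rng.uniform(0, 0.1),
                age_weight_B=rng.uniform(0, 0.1),
            )
            value = discounted_weighted_years(a, L, p)
            assert value == pytest.approx(quad_oracle(a, L, p), rel=1e-6)

    @pytest.mark.parametrize("a, L, expected", [
        (29.9, 43.4, 28.6),   # maternal death, discounted + age-weighted
        (0.0, 61.2, 31.4),    # stillbirth from birth
    ])
    def test_reproduces_published_yll_factors(self, params, a, L, expected):
        assert discounted_weighted_years(a, L, params) == pytest.approx(
            expected, abs=0.05)

    def test_no_weighting_no_discounting_is_identity_on_duration(self):
        p = DalyParameters(age_weight_K=0.0, discount_rate_r=0.0)
        assert discounted_weighted_years(30.0, 40.0, p) == pytest.approx(
            40.0, abs=1e-12)

    def test_discounting_disabled_flag_gives_raw_duration(self, params):
        assert discounted_weighted_years(
            29.9, 43.4, params.undiscounted()) == pytest.approx(43.4, abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(L1=st.floats(0.5, 60), dL=st.floats(0.1, 30), a=st.floats(0, 60))
    def test_strictly_increasing_in_duration(self, L1, dL, a):
        p = DalyParameters()
        assert (discounted_weighted_years(a, L1 + dL, p)
                > discounted_weighted_years(a, L1, p))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(r1=st.floats(0.001, 0.15), dr=st.floats(0.001, 0.1))
    def test_unweighted_value_strictly_decreasing_in_discount_rate(self, r1, dr):
        lo = DalyParameters(age_weight_K=0.0, discount_rate_r=r1 + dr)
        hi = DalyParameters(age_weight_K=0.0, discount_rate_r=r1)
        assert (discounted_weighted_years(20, 40, lo)
                < discounted_weighted_years(20, 40, hi))

    def test_limit_small_r_small_k_approaches_duration(self):
        p = DalyParameters(age_weight_K=0.0, discount_rate_r=1e-15)
        assert discounted_weighted_years(10, 25, p) == pytest.approx(25, abs=1e-9)

    @pytest.mark.parametrize("a, L", [(-1, 10), (10, 0), (10, -5),
                                      (math.nan, 10), (10, math.inf)])
    def test_invalid_inputs_rejected(self, params, a, L):
        with pytest.raises(InvalidParameterError):
            discounted_weighted_years(a, L, params)

    def test_vanishing_duration_vanishes(self, params):
        assert discounted_weighted_years(0.0, 1e-9, params) == pytest.approx(
            0.0, abs=1e-9)


class TestParameterValidation:
    @pytest.mark.parametrize("kwargs", [
        {"age_weight_K": 1.5}, {"age_weight_K": -0.1},
        {"discount_rate_r": -0.01}, {"disability_weight_D": 1.2},
        {"disability_multiplier_M": -1.0}, {"age_weight_B": math.nan},
    ])
    def test_out_of_domain_constants_rejected(self, kwargs):
        with pytest.raises(InvalidParameterError):
            DalyParameters(**kwargs)

    def test_profile_proportions_must_sum_to_one(self):
        with pytest.raises(InvalidParameterError):
            AgeProfile(age_group_distribution=((22.0, 0.6, 50.0),
                                               (32.0, 0.5, 40.0)))

    def test_round_trips_through_dict(self, params, profile):
        assert DalyParameters.from_dict(params.to_dict()) == params
        assert AgeProfile.from_dict(profile.to_dict()) == profile


class TestMaternalAndStillbirthDalys:
    def test_yll_discounted_and_undiscounted(self, profile, params):
        assert yll_maternal(profile, params) == pytest.approx(28.6, abs=0.05)
        assert yll_maternal(profile, params.undiscounted()) == pytest.approx(
            43.4, abs=1e-9)

    def test_yld_discounted_and_undiscounted(self, profile, params):
        assert yld_maternal(profile, params) == pytest.approx(17.18, abs=0.05)
        # 2 disabled survivors x weight 0.3 x 43.4 remaining years
        assert yld_maternal(profile, params.undiscounted()) == pytest.approx(
            26.04, abs=1e-9)

    def test_yld_is_m_times_d_times_yll_exactly(self, profile, params):
        assert yld_maternal(profile, params) == (
            params.disability_multiplier_M * params.disability_weight_D
            * yll_maternal(profile, params))

    def test_zero_multiplier_kills_yld(self, profile, params):
        p = dataclasses.replace(params, disability_multiplier_M=0.0)
        assert yld_maternal(profile, p) == 0.0
        assert daly_per_maternal_death(profile, p.undiscounted()) == pytest.approx(
            43.4, abs=1e-9)

    def test_daly_per_maternal_death(self, profile, params):
        assert daly_per_maternal_death(profile, params) == pytest.approx(
            45.8, abs=0.1)
        assert daly_per_maternal_death(profile, params.undiscounted()) == \
            pytest.approx(69.4, abs=0.1)
        assert daly_per_maternal_death(profile, params) == (
            yll_maternal(profile, params) + yld_maternal(profile, params))

    def test_daly_per_stillbirth(self, profile, params):
        assert daly_per_stillbirth(profile, params) == pytest.approx(31.4, abs=0.05)
        assert daly_per_stillbirth(profile, params.undiscounted()) == \
            pytest.approx(61.2, abs=1e-9)

    def test_stillbirth_daly_independent_of_disability_assumptions(
            self, profile, params):
        alt = dataclasses.replace(params, disability_weight_D=0.9,
                                  disability_multiplier_M=17.0)
        assert daly_per_stillbirth(profile, alt) == daly_per_stillbirth(
            profile, params)

    def test_degenerate_age_distribution_equals_scalar_path(self, params):
        scalar = AgeProfile()
        grouped = AgeProfile(age_group_distribution=((29.9, 1.0, 43.4),))
        assert yll_maternal(grouped, params) == pytest.approx(
            yll_maternal(scalar, params), abs=1e-12)

    def test_grouped_profile_is_proportion_weighted_sum(self, params):
        groups = ((22.0, 0.4, 52.0), (37.0, 0.6, 36.0))
        grouped = AgeProfile(age_group_distribution=groups)
        expected = sum(
            w * discounted_weighted_years(a, L, params) for a, w, L in groups)
        assert yll_maternal(grouped, params) == pytest.approx(expected, abs=1e-12)


@pytest.fixture(scope="module")
def table():
    import pandas as pd
    rows = [(age, year, le)
            for year, les in [(2000, {0: 57.0, 25: 40.0, 50: 20.0}),
                              (2012, {0: 61.0, 25: 44.0, 50: 22.0})]
            for age, le in les.items()]
    return LifeTable(pd.DataFrame(
        rows, columns=["age", "year", "remaining_life_expectancy"]))


class TestLifeTable:

    def test_exact_at_nodes(self, table):
        assert interpolate_life_expectancy(table, 25, 2000) == pytest.approx(40.0)
        assert interpolate_life_expectancy(table, 50, 2012) == pytest.approx(22.0)

    def test_midpoint_year_is_mean_of_node_values(self, table):
        assert interpolate_life_expectancy(table, 0, 2006) == pytest.approx(
            (57.0 + 61.0) / 2)

    def test_interior_point_matches_hand_bilinear(self, table):
        # age 10 in 2003: age-interp within each year, then linear in year
        v2000 = 57.0 + (40.0 - 57.0) * 10 / 25
        v2012 = 61.0 + (44.0 - 61.0) * 10 / 25
        expected = v2000 + (v2012 - v2000) * 3 / 12
        assert interpolate_life_expectancy(table, 10, 2003) == pytest.approx(expected)

    def test_age_outside_range_raises(self, table):
        with pytest.raises(ValueError):
            interpolate_life_expectancy(table, 80, 2005)

    def test_year_clamped_to_reference_range(self, table):
        assert interpolate_life_expectancy(table, 25, 1990) == pytest.approx(40.0)

    def test_packaged_synthetic_table_loads(self):
        from obcea.datasets import load_life_table
        table = load_life_table()
        assert interpolate_life_expectancy(table, 30, 2012) == pytest.approx(38.3)
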