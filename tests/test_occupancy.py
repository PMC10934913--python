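"""Occupancy computations: generation, objective ACH, capacity inversion."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from ventbox import (
    ach_objective,
    capacity_table,
    exhalation_rate,
    generation_rate,
    max_occupancy_ach_constraint,
    max_occupancy_css_constraint,
    steady_state_concentration,
)
from ventbox.errors import DomainError, ValidationError
from ventbox.occupancy import CSS_BOUNDARY_TOL_PPM, LS_TO_M3H, OccupancyState


class TestExhalationRate:
    @pytest.mark.parametrize(
        "mix, rate",
        [
            ({"rest": 1.0}, 0.00390),
            ({"rest": 0.8, "walking": 0.2}, 0.00447),
            ({"physical": 1.0}, 0.01352),
            ({"walking": 1.0}, 0.00675),
        ],
    )
    def test_weighted_mixes(self, mix, rate):
        assert exhalation_rate(mix) == pytest.approx(rate, abs=1e-12)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValidationError):
            exhalation_rate({"rest": 0.6, "walking": 0.2})

    def test_occupancy_state_derives_rate_from_mix(self):
        occ = OccupancyState(n=9, activity_mix={"rest": 0.8, "walking": 0.2})
        assert occ.exh_rate == pytest.approx(0.00447)
        assert occ.generation == pytest.approx(0.144828)


class TestGenerationRate:
    @pytest.mark.parametrize(
        "n, exh, g",
        [(17, 0.00447, 0.273564), (6, 0.01352, 0.292032), (0, 0.0039, 0.0), (2, 0.0039, 0.02808)],
    )
    def test_printed_generation_rates(self, n, exh, g):
        assert generation_rate(n, exh) == pytest.approx(g, abs=1e-12)

    def test_negative_count_rejected(self):
        with pytest.raises(ValidationError):
            generation_rate(-1, 0.0039)


class TestAchObjective:
    @pytest.mark.parametrize(
        "fb, n, v, raw, ceiled",
        [
            (15, 9, 255.5, 1.90, 2),   # coffee shop, anti-contagion
            (10, 20, 2155.9, 0.33, 1),  # cinema
            (14, 2, 77.4, 1.30, 2),    # city study room
            (5, 2, 77.4, 0.47, 1),
        ],
    )
    def test_printed_objectives(self, fb, n, v, raw, ceiled):
        got_raw, got_ceiled = ach_objective(fb, n, v)
        assert got_raw == pytest.approx(raw, abs=0.0051)
        assert got_ceiled == ceiled

    def test_vacant_space_needs_nothing(self):
        assert ach_objective(15, 0, 100.0) == (0.0, 0)

    def test_exact_integer_raw_is_not_bumped(self):
        # Fb·n·3.6/V landing exactly on an integer must not ceil one higher.
        raw, ceiled = ach_objective(10, 5, 10 * 5 * 3.6 / 2.0)
        assert raw == pytest.approx(2.0)
        assert ceiled == 2

    def test_bad_volume_rejected(self):
        with pytest.raises(DomainError):
            ach_objective(15, 3, 0.0)


class TestAchConstraintCapacity:
    @pytest.mark.parametrize(
        "ach, fb, v, n_max",
        [
            (2.004, 14, 77.4, 3),     # city study room
            (2.149, 15, 509.2, 18),   # restaurant (binding constraint)
            (0.584, 10, 2155.9, 0),   # cinema: no occupancy complies
            (144.222, 14, 64.9, 185),  # office
        ],
    )
    def test_printed_capacities(self, ach, fb, v, n_max):
        assert max_occupancy_ach_constraint(ach, fb, v) == n_max

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        ach=st.floats(0, 30),
        fb=st.sampled_from([5.0, 10.0, 14.0, 15.0]),
        v=st.floats(20, 3000),
    )
    def test_bracketing_by_brute_force(self, ach, fb, v):
        """n_max complies and n_max + 1 does not, by direct enumeration."""
        n_max = max_occupancy_ach_constraint(ach, fb, v)
        for n in range(0, min(n_max, 30) + 1):
            _, ceiled = ach_objective(fb, n, v)
            assert n == 0 or ceiled <= ach + 1e-9
        _, ceiled_next = ach_objective(fb, n_max + 1, v)
        assert ceiled_next > ach + 1e-9

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(ach=st.floats(0, 20), fb=st.floats(5, 15), v=st.floats(20, 2000), dv=st.floats(0, 500))
    def test_monotone_in_available_ach_and_volume(self, ach, fb, v, dv):
        base = max_occupancy_ach_constraint(ach, fb, v)
        assert max_occupancy_ach_constraint(ach + 1.0, fb, v) >= base
        assert max_occupancy_ach_constraint(ach, fb, v + dv) >= base
        assert max_occupancy_ach_constraint(ach, fb + 1.0, v) <= base


class TestCssConstraintCapacity:
    @pytest.mark.parametrize(
        "ach, v, co, exh, limit, n_max",
        [
            (4.253, 2543.1, 475, 0.01352, 700, 50),    # gym: inclusive boundary
            (8.513, 742.2, 489, 0.0039, 1000, 229),    # university study room
            (2.004, 77.4, 447, 0.0039, 700, 2),        # city study room
        ],
    )
    def test_printed_capacities(self, ach, v, co, exh, limit, n_max):
        assert max_occupancy_css_constraint(ach, v, co, exh, limit) == n_max

    def test_gym_boundary_sits_on_the_ceiling(self):
        """At the gym's capacity the steady state is the 700-ppm ceiling itself."""
        n = max_occupancy_css_constraint(4.253, 2543.1, 475, 0.01352, 700)
        css = steady_state_concentration(475, generation_rate(n, 0.01352), 4.253 * 2543.1)
        assert round(css, 2) == 700.00

    def test_outdoor_at_ceiling_means_zero(self):
        assert max_occupancy_css_constraint(3.0, 100.0, 700, 0.0039, 700) == 0

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        ach=st.floats(0.1, 30),
        v=st.floats(20, 3000),
        co=st.floats(380, 600),
        exh=st.sampled_from([0.0039, 0.00447, 0.00675, 0.01352]),
        limit=st.sampled_from([700.0, 1000.0]),
    )
    def test_bracketing_by_brute_force(self, ach, v, co, exh, limit):
        n_max = max_occupancy_css_constraint(ach, v, co, exh, limit)
        fext = ach * v

        def css(n):
            return steady_state_concentration(co, generation_rate(n, exh), fext)

        assert css(n_max) <= limit + CSS_BOUNDARY_TOL_PPM
        assert css(n_max + 1) > limit + CSS_BOUNDARY_TOL_PPM

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        ach=st.floats(0.1, 30),
        v=st.floats(20, 3000),
        co=st.floats(380, 650),
        exh=st.floats(0.003, 0.015),
    )
    def test_closed_form_agreement(self, ach, v, co, exh):
        """Away from exact boundaries the solver equals the analytic floor."""
        limit = 700.0
        n_max = max_occupancy_css_constraint(ach, v, co, exh, limit)
        exact = (limit - co) * ach * v / (1e6 * exh * LS_TO_M3H)
        if min(abs(exact - math.floor(exact)), abs(math.ceil(exact) - exact)) > 1e-6:
            assert n_max == math.floor(exact)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(ach=st.floats(0.5, 20), v=st.floats(50, 2000), co=st.floats(380, 600))
    def test_monotone_in_limit_and_exhalation(self, ach, v, co):
        lo = max_occupancy_css_constraint(ach, v, co, 0.0039, 700)
        hi = max_occupancy_css_constraint(ach, v, co, 0.0039, 1000)
        assert hi >= lo
        heavy = max_occupancy_css_constraint(ach, v, co, 0.01352, 700)
        assert heavy <= lo


class TestCapacityTable:
    def test_city_study_room_at_measured_ach(self, cases, measured_ach):
        cap = capacity_table(
            v=77.4, co=447, exh_rate=0.0039, fb_ac=14, fb_mv=5,
            ach_available=measured_ach["city_study_room"],
        )
        ac, mv = cap.anti_covid, cap.minimum_ventilation
        assert (ac.ach_constraint.n_max, ac.css_constraint.n_max) == (3, 2)
        assert ac.n_max == 2 and ac.binding is ac.css_constraint
        assert (mv.ach_constraint.n_max, mv.css_constraint.n_max) == (8, 6)
        assert mv.n_max == 6

    def test_restaurant_binding_is_ach_side(self, measured_ach):
        cap = capacity_table(
            v=509.2, co=374, exh_rate=0.00447, fb_ac=15, fb_mv=5,
            ach_available=measured_ach["restaurant"],
        )
        assert cap.anti_covid.binding is cap.anti_covid.ach_constraint
        assert cap.anti_covid.n_max == 18

    def test_city_study_room_at_design_minimum(self):
        cap = capacity_table(v=77.4, co=447, exh_rate=0.0039, fb_ac=14, fb_mv=5, ach_available=4.0)
        ac = cap.anti_covid
        assert (ac.ach_constraint.n_max, ac.css_constraint.n_max) == (6, 5)
        assert ac.css_constraint.css_at_nmax == pytest.approx(673.74, abs=0.006)

    def test_cinema_at_design_maximum_air_quality_rule(self):
        cap = capacity_table(v=2155.9, co=474, exh_rate=0.0039, fb_ac=10, fb_mv=5, ach_available=8.0)
        css_side = cap.minimum_ventilation.css_constraint
        assert css_side.n_max == 646
        assert css_side.css_at_nmax == pytest.approx(999.87, abs=0.006)
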