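"""QALY engine: closed-form segments against numerical-integration oracles."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad

from waitcea.config import DiscountSettings, SubgroupParameters, Timeline, UtilityProfile
from waitcea.qaly import (
    discounted_exposure,
    qalys_lifesaving,
    qalys_missed_surgery,
    qalys_reduced_wait,
    subgroup_qalys,
)

from _oracles import draw_scenario_params, riemann_reduced_wait

D35 = DiscountSettings(annual_rate=0.035)
D0 = DiscountSettings(annual_rate=0.0)


def _u(**kw):
    return UtilityProfile(**kw)


def _tl(**kw):
    return Timeline(**kw)


class TestDiscountedExposure:
    def test_zero_rate_reduces_to_duration(self):
        assert discounted_exposure(0.0, 10.0, 0.0) == 10.0

    def test_empty_interval_is_zero(self):
        assert discounted_exposure(3.0, 3.0, 0.035) == 0.0

    def test_reversed_interval_raises(self):
        with pytest.raises(ValueError):
            discounted_exposure(5.0, 4.0, 0.035)

    @pytest.mark.parametrize("t0,t1,rate", [(0.0, 10.0, 0.035), (2.5, 17.3, 0.06), (0.0, 40.0, 0.01)])
    def test_matches_adaptive_quadrature(self, t0, t1, rate):
        expected, err = quad(lambda t: (1 + rate) ** (-t), t0, t1, epsrel=1e-12)
        got = discounted_exposure(t0, t1, rate)
        assert got == pytest.approx(expected, rel=1e-8)

    @given(
        t0=st.floats(0, 30), gap=st.floats(0, 30),
        rate=st.floats(0, 0.2, exclude_max=True),
    )
    def test_monotone_non_increasing_in_rate(self, t0, gap, rate):
        lo = discounted_exposure(t0, t0 + gap, rate)
        hi = discounted_exposure(t0, t0 + gap, rate + 0.05)
        assert hi <= lo + 1e-12


class TestReducedWait:
    def test_identical_arms_gain_nothing(self):
        u = _u(u_wait=0.7, u_post_early=0.7, u_post_delayed=0.7)
        tl = _tl(t_early=0.5, t_delayed=2.0, t_death_counterfactual=20, t_death_early=20)
        assert qalys_reduced_wait(u, tl, D35).total == pytest.approx(0.0, abs=1e-12)

    def test_no_waiting_gap_empties_segment_a(self):
        u = _u(u_wait=0.5, u_post_early=0.8, u_post_delayed=0.75)
        tl = _tl(t_early=1.0, t_delayed=1.0, t_death_counterfactual=20, t_death_early=21)
        assert qalys_reduced_wait(u, tl, D35).segments["A"] == pytest.approx(0.0, abs=1e-12)

    def test_worked_example_matches_fine_grid_riemann(self):
        """The three-segment closed form equals direct integration of the
        arm-difference utility curve (Δt = 1e−4 years)."""
        u = _u(u_wait=0.5, u_post_early=0.8, u_post_delayed=0.75)
        tl = _tl(t_early=0.0, t_delayed=1.0, t_death_counterfactual=20.0, t_death_early=22.0)
        expected = riemann_reduced_wait(0.5, 0.8, 0.75, 0.0, 1.0, 20.0, 22.0, 0.035, dt=1e-4)
        assert qalys_reduced_wait(u, tl, D35).total == pytest.approx(expected, rel=1e-5)

    def test_total_is_sum_of_segments(self):
        u = _u(u_wait=0.4, u_post_early=0.9, u_post_delayed=0.6)
        tl = _tl(t_early=0.3, t_delayed=2.1, t_death_counterfactual=17.0, t_death_early=19.5)
        b = qalys_reduced_wait(u, tl, D35)
        assert b.total == pytest.approx(sum(b.segments.values()), rel=1e-12)

    @given(split=st.floats(0.01, 0.99))
    def test_segment_additivity_under_interval_split(self, split):
        """Splitting a segment at an interior point and summing the halves
        leaves the total unchanged."""
        t0, t1, rate = 1.0, 8.0, 0.035
        ts = t0 + split * (t1 - t0)
        whole = discounted_exposure(t0, t1, rate)
        parts = discounted_exposure(t0, ts, rate) + discounted_exposure(ts, t1, rate)
        assert parts == pytest.approx(whole, rel=1e-12)

    @given(rate=st.floats(0, 0.15, exclude_max=True))
    def test_positive_gap_total_monotone_in_rate(self, rate):
        u = _u(u_wait=0.5, u_post_early=0.8, u_post_delayed=0.7)
        tl = _tl(t_early=0.2, t_delayed=1.5, t_death_counterfactual=18, t_death_early=20)
        lo = qalys_reduced_wait(u, tl, DiscountSettings(annual_rate=rate)).total
        hi = qalys_reduced_wait(u, tl, DiscountSettings(annual_rate=min(rate + 0.05, 0.99))).total
        assert hi <= lo + 1e-12


class TestMissedSurgery:
    def test_identical_outcomes_gain_nothing(self):
        u = _u(u_wait=0.6, u_post_early=0.8, u_post_delayed=0.8, u_missed=0.8)
        tl = _tl(t_early=0.5, t_delayed=0.5, t_death_counterfactual=15, t_death_early=15)
        assert qalys_missed_surgery(u, tl, D35).total == pytest.approx(0.0, abs=1e-12)

    def test_missing_u_missed_raises(self):
        u = _u(u_wait=0.6, u_post_early=0.8, u_post_delayed=0.8)
        tl = _tl(t_early=0.5, t_delayed=0.5, t_death_counterfactual=15, t_death_early=15)
        with pytest.raises(ValueError, match="u_missed"):
            qalys_missed_surgery(u, tl, D35)

    def test_survival_gap_segment_is_definitional(self):
        """With the living-unoperated gap zeroed, segment W alone remains."""
        u = _u(u_wait=0.6, u_post_early=0.8, u_post_delayed=0.8, u_missed=0.8)
        tl = _tl(t_early=0.5, t_delayed=0.5, t_death_counterfactual=10, t_death_early=18)
        b = qalys_missed_surgery(u, tl, D35)
        assert b.segments["V"] == pytest.approx(0.0, abs=1e-12)
        assert b.segments["W"] == pytest.approx(
            0.8 * discounted_exposure(10.0, 18.0, 0.035), rel=1e-12
        )

    def test_collapse_equivalence_with_general_model(self):
        """Missed surgery equals the general model with segment B's interval
        empty (delayed surgery pushed to the counterfactual death date) and
        the waiting utility replaced by the living-unoperated one."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            p = draw_scenario_params(rng)
            d = DiscountSettings(annual_rate=p["rate"])
            missed = qalys_missed_surgery(
                _u(u_wait=p["u_wait"], u_post_early=p["u_post_early"],
                   u_post_delayed=p["u_post_delayed"], u_missed=p["u_missed"]),
                _tl(t_early=p["t_early"], t_delayed=p["t_early"],
                    t_death_counterfactual=p["t_death_cf"], t_death_early=p["t_death_early"]),
                d,
            ).total
            collapsed = qalys_reduced_wait(
                _u(u_wait=p["u_missed"], u_post_early=p["u_post_early"],
                   u_post_delayed=p["u_post_delayed"]),
                _tl(t_early=p["t_early"], t_delayed=p["t_death_cf"],
                    t_death_counterfactual=p["t_death_cf"], t_death_early=p["t_death_early"]),
                d,
            ).total
            assert missed == pytest.approx(collapsed, rel=1e-10, abs=1e-12)


class TestLifesaving:
    def test_no_survival_gain_is_zero(self):
        u = _u(u_wait=0.6, u_post_early=0.8, u_post_delayed=0.8)
        tl = _tl(t_early=0.5, t_delayed=0.5, t_death_counterfactual=0.5, t_death_early=0.5)
        assert qalys_lifesaving(u, tl, D35).total == pytest.approx(0.0, abs=1e-12)

    def test_zero_rate_arithmetic(self):
        u = _u(u_wait=0.6, u_post_early=0.8, u_post_delayed=0.8)
        tl = _tl(t_early=0.0, t_delayed=0.0, t_death_counterfactual=0.0, t_death_early=30.0)
        assert qalys_lifesaving(u, tl, D0).total == pytest.approx(24.0, rel=1e-12)

    def test_generic_case_matches_quadrature(self):
        u = _u(u_wait=0.6, u_post_early=0.77, u_post_delayed=0.77)
        tl = _tl(t_early=0.4, t_delayed=0.4, t_death_counterfactual=0.4, t_death_early=23.7)
        expected, _ = quad(lambda t: 0.77 * 1.035 ** (-t), 0.4, 23.7, epsrel=1e-12)
        assert qalys_lifesaving(u, tl, D35).total == pytest.approx(expected, rel=1e-8)

    def test_unpinned_counterfactual_death_raises(self):
        u = _u(u_wait=0.6, u_post_early=0.8, u_post_delayed=0.8)
        tl = _tl(t_early=0.5, t_delayed=1.0, t_death_counterfactual=1.0, t_death_early=20.0)
        with pytest.raises(ValueError, match="early surgery date"):
            qalys_lifesaving(u, tl, D35)


class TestSubgroupDispatch:
    def _sp(self, n):
        return SubgroupParameters.model_validate(
            {
                "kind": "RWT",
                "n_patients": n,
                "utilities": {"u_wait": 0.5, "u_post_early": 0.8, "u_post_delayed": 0.7},
                "timeline": {"t_early": 0.2, "t_delayed": 1.2,
                             "t_death_counterfactual": 15, "t_death_early": 16},
                "costs": {"direct_early": 1000, "direct_delayed": 900},
            }
        )

    def test_zero_patients_zero_population_total(self):
        _, pop, _ = subgroup_qalys(self._sp(0), D35)
        assert pop == 0.0

    def test_population_total_linear_in_counts(self):
        _, pop1, _ = subgroup_qalys(self._sp(1), D35)
        _, pop2, _ = subgroup_qalys(self._sp(2), D35)
        assert pop2 == pytest.approx(2 * pop1, rel=1e-12)

    def test_dispatch_matches_scenario_engine(self):
        sp = self._sp(5)
        per_patient, _, _ = subgroup_qalys(sp, D35)
        direct = qalys_reduced_wait(sp.utilities, sp.timeline, D35).total
        assert per_patient == direct
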