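"""Screening-allocation rules: CA, CAIR, ISA, RA, and the sklearn wrappers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from riskscreen import (
    InvalidParameterError,
    StrategySpec,
    ThresholdScreeningPolicy,
    RandomScreeningPolicy,
    detection_summary,
    schedule_ca,
    schedule_cair,
    schedule_isa,
    schedule_ra,
)


class TestThresholdRules:
    def test_ca_all_or_nothing(self):
        risks = np.array([[0.02] * 5, [0.01] * 5])  # row sums 0.10 and 0.05
        sched = schedule_ca(risks, 0.08).screened
        assert sched[0].all() and not sched[1].any()

    def test_threshold_zero_is_full_schedule_for_every_rule(self, rng):
        risks = rng.uniform(0, 0.05, size=(10, 5))
        for rule in (schedule_ca, schedule_cair, schedule_isa):
            assert rule(risks, 0.0).screened.all()

    def test_cair_hand_trace_with_reset(self):
        risks = np.array([[0.01, 0.02, 0.03, 0.02, 0.02]])
        sched = schedule_cair(risks, 0.04).screened[0]
        assert sched.tolist() == [False, False, True, False, True]

    def test_cair_threshold_above_total_gives_no_exams(self):
        risks = np.array([[0.01, 0.02, 0.03, 0.02, 0.02]])
        assert not schedule_cair(risks, 0.2).screened.any()

    def test_cair_threshold_below_min_reduces_to_full(self):
        risks = np.array([[0.01, 0.02, 0.03, 0.02, 0.02]])
        assert schedule_cair(risks, 0.01).screened.all()

    def test_isa_selects_exceeding_years_only(self):
        risks = np.array([[0.01, 0.05, 0.02, 0.01, 0.01]])
        sched = schedule_isa(risks, 0.03).screened[0]
        assert sched.tolist() == [False, True, False, False, False]

    def test_isa_threshold_above_max_gives_empty(self, rng):
        risks = rng.uniform(0, 0.05, size=(10, 5))
        assert not schedule_isa(risks, risks.max() + 1e-9).screened.any()

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_lowering_threshold_nests_schedules_and_raises_tdr(self, seed):
        rng = np.random.default_rng(seed)
        risks = rng.uniform(0, 0.06, size=(12, 5))
        t_hi, t_lo = 0.06, 0.02
        for rule in (schedule_ca, schedule_isa):
            hi, lo = rule(risks, t_hi).screened, rule(risks, t_lo).screened
            assert np.all(lo >= hi)  # exact nesting
        # CAIR nesting is not structural; its achieved tdr is still monotone
        for dp in (0.3,):
            tdrs = [
                detection_summary(risks, schedule_cair(risks, t), dp).tdr_achieved
                for t in (t_lo, t_hi)
            ]
            assert tdrs[0] >= tdrs[1] - 1e-12

    def test_rules_are_deterministic(self, rng):
        risks = rng.uniform(0, 0.05, size=(30, 5))
        for rule in (schedule_ca, schedule_cair, schedule_isa):
            a, b = rule(risks, 0.03).screened, rule(risks, 0.03).screened
            assert np.array_equal(a, b)

    def test_negative_threshold_rejected(self):
        with pytest.raises(InvalidParameterError):
            schedule_ca(np.ones((2, 5)) * 0.01, -0.1)

    def test_unknown_strategy_spec_rejected(self):
        with pytest.raises(InvalidParameterError):
            StrategySpec(name="XYZ")


class TestRandomAllocation:
    def test_without_replacement_draws_equal_exams(self, rng):
        risks = rng.uniform(0, 0.05, size=(200, 5))
        res = schedule_ra(risks, dp=0.3, tdr_target=0.8,
                          ra_mode="without_replacement", rng=rng)
        assert res.draws == res.exams <= 200 * 5
        assert res.tdr_achieved >= 0.8

    def test_with_replacement_draws_at_least_exams(self, rng):
        risks = rng.uniform(0, 0.05, size=(200, 5))
        res = schedule_ra(risks, dp=0.3, tdr_target=0.8, rng=rng)
        assert res.draws >= res.exams
        assert res.tdr_achieved >= 0.8

    def test_stop_is_first_crossing(self, rng):
        # removing the last drawn slot must drop tdr below target
        risks = rng.uniform(0, 0.05, size=(100, 5))
        rng2 = np.random.default_rng(7)
        res = schedule_ra(risks, dp=0.3, tdr_target=0.85,
                          ra_mode="without_replacement", rng=rng2)
        seq = np.random.default_rng(7).permutation(500)[: res.draws - 1]
        flat = np.zeros(500, bool)
        flat[seq] = True
        below = detection_summary(risks, flat.reshape(100, 5), 0.3)
        assert below.tdr_achieved < 0.85 <= res.tdr_achieved

    def test_coverage_matches_coupon_collector_expectation(self):
        # distinct slots after D uniform draws with replacement:
        # M * (1 - (1 - 1/M)**D)
        M, D, runs = 25000, 30000, 50
        rng = np.random.default_rng(99)
        distinct = [
            np.unique(rng.integers(0, M, size=D)).size for _ in range(runs)
        ]
        expected = M * (1.0 - (1.0 - 1.0 / M) ** D)
        assert abs(np.mean(distinct) - expected) / expected < 0.02

    def test_near_full_target_approaches_full_schedule(self, rng):
        risks = rng.uniform(0.01, 0.05, size=(50, 5))
        res = schedule_ra(risks, dp=0.3, tdr_target=0.999,
                          ra_mode="without_replacement", rng=rng)
        assert res.exams >= 0.95 * 50 * 5


class TestEstimators:
    def test_policy_fit_transform_roundtrip(self, rng):
        risks = rng.uniform(0, 0.05, size=(300, 5))
        pol = ThresholdScreeningPolicy(rule="ISA", tdr_target=0.85, dp=0.3)
        sched = pol.fit(risks).transform(risks)
        assert pol.threshold_ >= 0
        assert sched.shape == risks.shape
        got = detection_summary(risks, sched.astype(bool), 0.3)
        assert got.tdr_achieved >= 0.85

    def test_policy_get_params_round_trip(self):
        pol = ThresholdScreeningPolicy(rule="CA", tdr_target=0.8)
        clone = ThresholdScreeningPolicy(**pol.get_params())
        assert clone.get_params() == pol.get_params()

    def test_random_policy_reproducible(self, rng):
        risks = rng.uniform(0, 0.05, size=(200, 5))
        a = RandomScreeningPolicy(tdr_target=0.8, dp=0.3, random_state=3).fit(risks)
        b = RandomScreeningPolicy(tdr_target=0.8, dp=0.3, random_state=3).fit(risks)
        assert a.draws_ == b.draws_
        assert np.array_equal(a.schedule_, b.schedule_)
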