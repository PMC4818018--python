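"""Pool-size and rate estimation against generator ground truth."""

import dataclasses
import warnings

import numpy as np
import pytest

import rrpkinetics as rk
from rrpkinetics.estimate import post_jump_excess, jump_onset_index

from conftest import mean_field_series, single_class_params


@pytest.fixture(scope="module")
def accel_params():
    """Single class, accelerating recruitment (the headline study condition)."""
    return single_class_params(rk.accelerating_schedule(4.3, 10.0))


@pytest.fixture(scope="module")
def twoclass_series_jump(jump500):
    return mean_field_series(rk.SynthParams(), jump500)


class TestSteadyStateStats:
    def test_constant_series_returns_the_constant(self, rest300):
        s = rk.SegmentSeries(1 / 300.0, np.full(45, 0.2),
                             rest300.segment_starts(), np.ones(45, int))
        st = rk.steady_state_stats(s, rest300)
        assert st.Rss == pytest.approx(0.2, rel=1e-6)
        assert st.steady_rate == pytest.approx(0.2 * 300, rel=1e-6)

    def test_mean_field_rss_matches_analytic_fixed_point(self, rest300):
        params = single_class_params(4.65, pv=0.12)
        series = mean_field_series(params, rest300)
        st = rk.steady_state_stats(series, rest300)
        # pre-release occupancy fixed point of the release-then-refill update
        g = 1 - np.exp(-4.65 / 300)
        occ_ss = 2553 * g / (0.12 + g - 0.12 * g)
        expect = occ_ss * 0.12 * params.quantal_charge_pC
        assert st.Rss == pytest.approx(expect, rel=0.01)

    def test_declining_tail_rejected(self, rest300):
        y = np.exp(-0.08 * np.arange(45))  # still decaying at train end
        s = rk.SegmentSeries(1 / 300.0, y, rest300.segment_starts(),
                             np.ones(45, int))
        with pytest.raises(rk.SteadyStateError):
            rk.steady_state_stats(s, rest300)


class TestEstimateAlphaFixed:
    def test_recovers_4p65_from_rest_train(self, rest300):
        series = mean_field_series(single_class_params(4.65), rest300)
        assert rk.estimate_alpha_fixed(series, rest300) == pytest.approx(4.65,
                                                                         rel=0.02)

    def test_recovers_4p70_from_frequency_jump(self, jump500):
        series = mean_field_series(single_class_params(4.70), jump500)
        assert rk.estimate_alpha_fixed(series, jump500) == pytest.approx(4.70,
                                                                         rel=0.02)

    def test_pure_depletion_returns_bracket_edge_with_warning(self,
                                                              geometric_series):
        series, _ = geometric_series
        with pytest.warns(UserWarning, match="no sign change"):
            a = rk.estimate_alpha_fixed(series, rk.make_protocol("rest300"))
        assert a == 0.05

    def test_self_consistency_condition_holds_at_root(self, rest300):
        series = mean_field_series(single_class_params(4.65), rest300)
        st = rk.steady_state_stats(series, rest300)
        a = rk.estimate_alpha_fixed(series, rest300, stats=st)
        est = rk.estimate_rrp0(series, rest300, "fixed_alpha", alpha=a, stats=st)
        assert est.rrp0_pC == pytest.approx(st.steady_rate / a, rel=1e-3)


class TestEstimateRRP0:
    def test_no_recruitment_all_methods_agree_with_truth(self, geometric_series,
                                                         rest300):
        series, params = geometric_series
        truth = 2553 * params.quantal_charge_pC
        for m in ("fixed_alpha", "back_extrapolation", "none_until_ss"):
            est = rk.estimate_rrp0(series, rest300, m)
            assert est.rrp0_pC == pytest.approx(truth, rel=0.02)

    def test_method_ordering_on_depressing_train(self, accel_params, rest300):
        series = mean_field_series(accel_params, rest300)
        back = rk.estimate_rrp0(series, rest300, "back_extrapolation").rrp0_pC
        fixed = rk.estimate_rrp0(series, rest300, "fixed_alpha").rrp0_pC
        none = rk.estimate_rrp0(series, rest300, "none_until_ss").rrp0_pC
        assert back <= fixed <= none

    def test_accelerating_analysis_reconciles_jump_and_rest(self, accel_params,
                                                            rest300, jump500):
        s_rest = mean_field_series(accel_params, rest300)
        s_jump = mean_field_series(accel_params, jump500)
        fixed_rest = rk.estimate_rrp0(s_rest, rest300, "fixed_alpha").rrp0_pC
        fixed_jump = rk.estimate_rrp0(s_jump, jump500, "fixed_alpha").rrp0_pC
        assert fixed_jump < fixed_rest  # jump underestimates under constant alpha
        sched = rk.accelerating_schedule(alpha_max=None, tau_ap=10.0)
        acc_rest = rk.estimate_rrp0(s_rest, rest300, "accelerating",
                                    schedule=sched).rrp0_pC
        acc_jump = rk.estimate_rrp0(s_jump, jump500, "accelerating",
                                    schedule=sched).rrp0_pC
        assert abs(acc_jump - acc_rest) / acc_rest < 0.03

    def test_accelerating_needs_schedule(self, rest300, accel_params):
        series = mean_field_series(accel_params, rest300)
        with pytest.raises(rk.EstimationError):
            rk.estimate_rrp0(series, rest300, "accelerating")

    def test_capacity_estimate_restores_standing_pool(self, rest300):
        params = single_class_params(4.65, pv=0.12)
        series = mean_field_series(params, rest300)
        est = rk.estimate_rrp0(series, rest300, "fixed_alpha")
        truth = 2553 * params.quantal_charge_pC
        assert est.rrp0_pC < truth  # released content only
        assert est.rrp0_capacity_pC == pytest.approx(truth, rel=0.02)


class TestPvBounds:
    def test_bounds_collapse_without_recruitment(self, geometric_series, rest300):
        series, _ = geometric_series
        lo, hi = rk.pv_bounds(series, rest300)
        assert lo == pytest.approx(0.2, rel=0.02)
        assert hi == pytest.approx(0.2, rel=0.02)

    def test_bounds_ordered_and_bracket_truth(self, rest300, jump500,
                                              twoclass_series_jump):
        series = mean_field_series(rk.SynthParams(), rest300)
        lo, hi = rk.pv_bounds(series, rest300)
        assert lo <= hi
        pv_total = 0.49 * 0.047 + 0.51 * 0.20
        assert lo <= pv_total * 1.05
        s_lo, s_hi = rk.pv_bounds(twoclass_series_jump, jump500, "steady_supply")
        assert s_lo <= s_hi
        # true standing-supply mean p_v from the generator occupancy
        rec = rk.mean_field(rk.SynthParams(), jump500)
        occ = rec.occupancy[50]
        pv_true = (occ * np.array([0.047, 0.20])).sum() / occ.sum()
        assert s_lo <= pv_true <= s_hi

    def test_standing_supply_bound_below_full_pool_bound(self, jump500, rest300):
        # the standing-supply upper bound drops below the full-pool lower bound
        # when the flow-through pool is dominated by the low-p_v class
        classes = (rk.SiteClassSpec(0.55, 0.03), rk.SiteClassSpec(0.45, 0.30))
        params = rk.SynthParams(site_classes=classes,
                                alpha_schedule=rk.fixed_schedule(3.6))
        s_jump = mean_field_series(params, jump500)
        s_rest = mean_field_series(params, rest300)
        full_lo, _ = rk.pv_bounds(s_rest, rest300)
        _, steady_hi = rk.pv_bounds(s_jump, jump500, "steady_supply")
        assert steady_hi < full_lo

    def test_zero_first_response_rejected(self, rest300):
        s = rk.SegmentSeries(1 / 300.0, np.zeros(45), rest300.segment_starts(),
                             np.ones(45, int))
        with pytest.raises((rk.EstimationError, rk.SteadyStateError)):
            rk.pv_bounds(s, rest300)


class TestQuantalContent:
    def test_unit_conversion(self):
        assert rk.quantal_content(1.0, 1.0, 1.0) == 1000

    def test_kyn_scale_invariance(self, rest300):
        # appropriately scaled traces give identical quanta at 1 and 2 mM KYN
        for scale in (0.13, 0.06):
            params = single_class_params(4.3, kyn_scale=scale)
            series = mean_field_series(params, rest300)
            est = rk.estimate_rrp0(series, rest300, "fixed_alpha")
            q = rk.quantal_content(est.rrp0_capacity_pC, 31.4, scale)
            assert q == pytest.approx(2553, rel=0.03)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(rk.EstimationError):
            rk.quantal_content(1.0, 0.0, 0.13)


class TestJumpIncreaseIndex:
    def setup_series(self, params, jump500, rest300, hz100):
        return (mean_field_series(params, jump500),
                mean_field_series(params, rest300),
                mean_field_series(params, hz100))

    def test_no_jump_equals_baseline(self, jump500, rest300, hz100):
        params = rk.SynthParams()
        _, s_rest, s_100 = self.setup_series(params, jump500, rest300, hz100)
        # "jump" series identical to the maintained-100 Hz series
        idx, base = rk.jump_increase_index(s_100, s_rest, s_100, jump_time=0.65)
        assert idx == pytest.approx(base, rel=1e-9)

    def test_jump_releases_extra_transmitter(self, jump500, rest300, hz100):
        params = rk.SynthParams()
        s_jump, s_rest, s_100 = self.setup_series(params, jump500, rest300, hz100)
        idx, base = rk.jump_increase_index(s_jump, s_rest, s_100)
        assert idx > base

    def test_high_ca_like_pv_reduces_the_increase(self, jump500, rest300, hz100):
        lo = rk.SynthParams()                      # 2 mM-like
        hi = rk.SynthParams(site_classes=(         # 4 mM-like: ~2x first response
            rk.SiteClassSpec(0.49, 0.094), rk.SiteClassSpec(0.51, 0.40)))
        j_lo, r_lo, m_lo = self.setup_series(lo, jump500, rest300, hz100)
        j_hi, r_hi, m_hi = self.setup_series(hi, jump500, rest300, hz100)
        idx_lo, base_lo = rk.jump_increase_index(j_lo, r_lo, m_lo)
        idx_hi, base_hi = rk.jump_increase_index(j_hi, r_hi, m_hi)
        assert base_hi < idx_hi < idx_lo


class TestRecoveryIndex:
    @staticmethod
    def pair_totals(params, delta):
        proto = rk.make_protocol("pairs", delta=delta)
        ch = rk.mean_field(params, proto).segment_charges(params)
        split = proto.segment_index(proto.ap_times[45])
        return float(ch[:split].sum()), float(ch[split:].sum())

    def test_zero_interval_recovers_zero_by_construction(self):
        params = single_class_params(4.3)
        zero = self.pair_totals(params, 1 / 300.0)
        out = rk.recovery_index([(1 / 300.0, *zero)], zero)
        assert out[0][1] == 0.0

    def test_long_rest_recovers_fully_with_constant_alpha(self):
        params = single_class_params(4.3)
        zero = self.pair_totals(params, 1 / 300.0)
        long = self.pair_totals(params, 3.0)  # 1 - e^-12.9 refill
        out = rk.recovery_index([(3.0, *long)], zero)
        assert out[0][1] == pytest.approx(1.0, abs=0.02)

    def test_rest_decay_schedule_leaves_under_40pct_at_1s(self):
        params = single_class_params(rk.rest_decay_schedule())
        zero = self.pair_totals(params, 1 / 300.0)
        one = self.pair_totals(params, 1.0)
        out = rk.recovery_index([(1.0, *one)], zero)
        assert 0.0 < out[0][1] < 0.40
        # engine closed form agrees with the simulated pool refill
        closed = rk.replenishment_fraction(1.0, params.alpha_schedule)
        assert out[0][1] == pytest.approx(closed, abs=0.05)

    def test_constant_alpha_model_grossly_mispredicts_rest_decay_recovery(self):
        # the acceleration-detection contrast: >98% predicted vs <40% observed
        sched = rk.rest_decay_schedule()
        observed = rk.replenishment_fraction(1.0, sched)
        constant = rk.replenishment_fraction(1.0, rk.fixed_schedule(sched.alpha_max))
        assert constant - observed > 0.50

    def test_unexhausted_pools_rejected(self):
        with pytest.raises(rk.EstimationError):
            rk.recovery_index([(1.0, 1.0, 0.9)], (1.0, 1.1))


class TestDepletionFraction:
    def test_exhaustion_without_recruitment(self, jump500):
        params = single_class_params(0.0, pv=0.12)
        series = mean_field_series(params, jump500)
        dep = rk.depletion_fraction(series, jump500, rk.fixed_schedule(0.0))
        assert dep == pytest.approx(1.0, abs=0.01)

    def test_two_class_2mM_like_band(self, jump500, twoclass_series_jump):
        sched = rk.accelerating_schedule(alpha_max=None, tau_ap=10.0)
        dep = rk.depletion_fraction(twoclass_series_jump, jump500, sched)
        assert 0.6 < dep < 0.9

    def test_strictly_increases_with_pv(self, jump500):
        deps = []
        for scale in (1.0, 2.0):
            classes = (rk.SiteClassSpec(0.49, 0.047 * scale),
                       rk.SiteClassSpec(0.51, 0.20 * scale))
            params = rk.SynthParams(site_classes=classes)
            series = mean_field_series(params, jump500)
            deps.append(rk.depletion_fraction(
                series, jump500, rk.accelerating_schedule(alpha_max=None)))
        assert deps[1] > deps[0]


def test_jump_onset_detection(jump500, twoclass_series_jump):
    j = jump_onset_index(twoclass_series_jump)
    assert twoclass_series_jump.t_start[j] == pytest.approx(0.65, abs=1e-3)


def test_parameter_recovery_median_under_5pct(rest300):
    """Stochastic recovery across the alpha x p_v grid (scaled-down ensemble)."""
    rng_alphas = [(2.0, 0.12), (4.65, 0.05), (4.65, 0.2), (8.0, 0.12)]
    errs = []
    from rrpkinetics.cli import process_trace, simulate_replicates
    for i, (alpha, pv) in enumerate(rng_alphas):
        for seed in range(5):
            params = single_class_params(alpha, pv=pv)
            tr = simulate_replicates(params, rest300, seed=seed, replicates=9)
            series = process_trace(tr, rest300)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                a = rk.estimate_alpha_fixed(series, rest300)
            errs.append(abs(a - alpha) / alpha)
    assert np.median(errs) <= 0.05
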