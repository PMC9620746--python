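"""STDP windows, eligibility traces and the SWC/CWC update rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from valencenav.fixtures import brute_force_pair_sum, make_cwc_integration_cases
from valencenav.plasticity import (
    DA_WINDOW_SWC,
    HT_WINDOW_SWC,
    EligibilityTrace,
    NeuromodulatorSignal,
    PlasticityParams,
    RateRuleParams,
    STDPWindow,
    clip_weights,
    cwc_sign_condition,
    cwc_step,
    make_cwc_signals,
    pairwise_stdp_sum,
    rate_based_update,
    swc_apply,
    swc_online_apply,
    update_trace,
    window_value,
)

P_SWC = PlasticityParams()


class TestWindows:
    def test_da_symmetric_values(self):
        assert window_value(0.0, DA_WINDOW_SWC) == pytest.approx(1.0)
        for s in (10.0, -10.0):
            assert window_value(s, DA_WINDOW_SWC) == pytest.approx(np.exp(-1), rel=1e-12)
        assert window_value(5.0, DA_WINDOW_SWC) == window_value(-5.0, DA_WINDOW_SWC)

    def test_5ht_causal_depressive_shape(self):
        assert window_value(-5.0, HT_WINDOW_SWC) == 0.0
        assert window_value(0.0, HT_WINDOW_SWC) == pytest.approx(0.5)
        assert window_value(10.0, HT_WINDOW_SWC) == pytest.approx(np.exp(-1), rel=1e-12)

    def test_window_magnitudes_non_negative(self):
        s = np.linspace(-50, 50, 101)
        for w in (DA_WINDOW_SWC, HT_WINDOW_SWC):
            assert np.all(window_value(s, w) >= 0)


class TestPairwiseSum:
    def test_empty_trains(self):
        assert pairwise_stdp_sum([], [], DA_WINDOW_SWC) == 0.0

    def test_single_pairs(self):
        assert pairwise_stdp_sum([0.0], [10.0], DA_WINDOW_SWC) == pytest.approx(
            np.exp(-1), rel=1e-12)
        assert pairwise_stdp_sum([0.0], [-10.0], HT_WINDOW_SWC) == 0.0

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 10**6))
    def test_matches_brute_force_and_additivity(self, seed):
        rng = np.random.default_rng(seed)
        pre = np.sort(rng.uniform(0, 500, rng.integers(0, 12)))
        post = np.sort(rng.uniform(0, 500, rng.integers(0, 12)))
        for w in (DA_WINDOW_SWC, HT_WINDOW_SWC):
            total = pairwise_stdp_sum(pre, post, w)
            assert total == pytest.approx(brute_force_pair_sum(pre, post, w), rel=1e-12)
            # additive over disjoint presynaptic subsets
            half = len(pre) // 2
            split = pairwise_stdp_sum(pre[:half], post, w) + pairwise_stdp_sum(
                pre[half:], post, w)
            assert total == pytest.approx(split, rel=1e-12)


class TestEligibilityTrace:
    def test_decay_over_one_time_constant(self):
        tr = EligibilityTrace(2.0, 1.0)
        tr = update_trace(tr, 0.0, 2000.0)
        assert tr.value == pytest.approx(np.exp(-1), rel=1e-12)

    def test_zero_stays_zero(self):
        tr = EligibilityTrace(5.0, 0.0)
        for _ in range(10):
            tr = update_trace(tr, 0.0, 100.0)
        assert tr.value == 0.0

    def test_superposition_of_two_events(self):
        tr = EligibilityTrace(2.0, 0.0)
        tr = update_trace(tr, 1.0, 1.0)  # event at t=0
        tr = update_trace(tr, 1.0, 2000.0)  # second event one tau_e later
        assert tr.value == pytest.approx(np.exp(-1) + 1.0, rel=1e-9)


class TestSWC:
    def test_reward_potentiates_everything(self):
        g = np.abs(np.random.default_rng(0).normal(size=(4, 6)))
        dw = swc_apply(g, g, "reward", P_SWC)
        assert np.all(dw >= 0)
        assert dw == pytest.approx(P_SWC.eta_da * g)

    def test_failure_depresses_everything(self):
        g = np.abs(np.random.default_rng(1).normal(size=(4, 6)))
        dw = swc_apply(g, g, "none", P_SWC)
        assert np.all(dw <= 0)

    def test_silent_episode_no_change(self):
        z = np.zeros((4, 6))
        assert np.all(swc_apply(z, z, "reward", P_SWC) == 0)
        assert np.all(swc_apply(z, z, "none", P_SWC) == 0)

    def test_online_rate_scaling(self):
        integral = np.ones((2, 2)) * 15.0  # constant unit trace over Tmax=15 s
        dw = swc_online_apply(integral, 15.0, P_SWC)
        # equivalent on average to the end-of-episode readout of a unit trace
        assert dw == pytest.approx(-P_SWC.eta_5ht * np.ones((2, 2)))

    def test_optogenetic_factor_scales_depression(self):
        g = np.ones((2, 2))
        base = swc_apply(g, g, "none", P_SWC)
        assert swc_apply(g, g, "none", P_SWC, a5ht_factor=2.0) == pytest.approx(2 * base)
        assert np.all(swc_apply(g, g, "none", P_SWC, a5ht_factor=0.0) == 0)


class TestCWC:
    def test_step_signs_follow_active_signal(self):
        p = PlasticityParams(eta_da=1e-4, eta_5ht=1e-4)
        rda, r5 = make_cwc_signals(t_rew_s=10.0, p=p, rewarded=True)
        g = np.ones((2, 2))
        before = cwc_step(g, g, 5.0, rda, r5, 1e-4, 0.01)
        assert np.all(before < 0)  # only tonic 5-HT active before the reward
        after = cwc_step(g, g, 10.5, rda, r5, 1e-4, 0.01)
        assert np.all(after > 0)  # only phasic DA active after
        late = cwc_step(g, g, 11.5, rda, r5, 1e-4, 0.01)
        assert np.all(late == 0)  # DA phase over (T_DA = 1 s)

    def test_no_5ht_means_pure_ltp(self):
        p = PlasticityParams(eta_da=1e-4, eta_5ht=1e-4, r5ht_amp=0.0)
        rda, r5 = make_cwc_signals(t_rew_s=5.0, p=p, rewarded=True)
        t = np.linspace(0, 6, 200)
        g = np.abs(np.sin(t))[:, None] * np.ones((1, 3))
        for ts in t:
            assert np.all(cwc_step(g[0], g[0], ts, rda, r5, 1e-4, 0.01) >= 0)

    def test_sign_condition_agrees_with_quadrature(self):
        cases = make_cwc_integration_cases(seed=42, n=100)
        for case in cases:
            rda = NeuromodulatorSignal("DA", 1.0, case["t_rew_s"],
                                       case["t_rew_s"] + case["t_da_s"])
            r5 = NeuromodulatorSignal("5HT", 1.0, 0.0, case["t_rew_s"])
            sign = cwc_sign_condition(
                case["t_s"], case["gamma_da"][:, None], case["gamma_5ht"][:, None],
                rda, r5)[0]
            expected = {"LTP": 1, "LTD": -1, "none": 0}[case["label"]]
            assert sign == expected

    def test_sign_condition_matches_integrated_steps(self):
        cases = make_cwc_integration_cases(seed=7, n=10)
        for case in cases:
            t = case["t_s"]
            rda = NeuromodulatorSignal("DA", 1.0, case["t_rew_s"],
                                       case["t_rew_s"] + case["t_da_s"])
            r5 = NeuromodulatorSignal("5HT", 1.0, 0.0, case["t_rew_s"])
            dt = t[1] - t[0]
            total = sum(
                cwc_step(case["gamma_da"][i], case["gamma_5ht"][i], ti, rda, r5,
                         1.0, dt)
                for i, ti in enumerate(t)
            )
            sign = cwc_sign_condition(
                t, case["gamma_da"][:, None], case["gamma_5ht"][:, None], rda, r5)[0]
            scale = case["integral_da"] + case["integral_5ht"] + 1e-12
            # Riemann and trapezoid sums only resolve sign away from balance
            if abs(case["integral_da"] - case["integral_5ht"]) > 0.01 * scale:
                assert np.sign(total) == sign


class TestClipping:
    @pytest.mark.parametrize("w_in,w_out", [(3.7, 3.0), (2.0, 2.0), (0.2, 1.0)])
    def test_table_bounds(self, w_in, w_out):
        assert clip_weights(np.array([w_in]), P_SWC)[0] == w_out

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            PlasticityParams(w_min=3.0, w_max=1.0)


class TestRateRule:
    def test_zero_rate_no_drift(self):
        tr = EligibilityTrace(2.0, 0.0)
        dw, _ = rate_based_update(0.0, 50.0, tr, 1, RateRuleParams(), P_SWC)
        assert dw == 0.0

    def test_antihebbian_sign(self):
        tr = EligibilityTrace(5.0, 0.0)
        dw = 0.0
        for _ in range(100):
            step, tr = rate_based_update(400.0, 30.0, tr, -1,
                                         RateRuleParams(mode="antihebbian_5ht"), P_SWC)
            dw += step
        assert dw < 0

    def test_linear_in_window_amplitude(self):
        tr1 = EligibilityTrace(2.0, 0.0)
        tr2 = EligibilityTrace(2.0, 0.0)
        dw1, _ = rate_based_update(400.0, 30.0, tr1, 1, RateRuleParams(amplitude=1.0), P_SWC)
        dw2, _ = rate_based_update(400.0, 30.0, tr2, 1, RateRuleParams(amplitude=2.0), P_SWC)
        assert dw2 == pytest.approx(2 * dw1, rel=1e-12)


class TestWindowValidation:
    def test_unknown_shape_rejected(self):
        with pytest.raises(ValueError):
            STDPWindow(1.0, 10.0, "triangular")
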