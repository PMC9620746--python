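"""Episode orchestration, batching, seeding and the search harness."""

from dataclasses import replace

import numpy as np
import pytest

import valencenav as vn
from valencenav.metrics import distance_stats
from valencenav.simulation import (
    OptoWindow,
    _episode_seed,
    finalize_update,
    run_batch,
    run_episode,
    run_probe,
    run_simulation,
    summarize,
)


def _short_cfg(**kw):
    defaults = dict(
        protocol=vn.make_protocol("mwm", t_max=1.0, episodes_per_trial=2),
        rule="swc", seed=9, n_simulations=1,
    )
    defaults.update(kw)
    return vn.RunConfig(**defaults)


class TestRunEpisode:
    def test_zero_learning_rate_leaves_weights(self):
        cfg = _short_cfg(plasticity=vn.PlasticityParams(eta_da=0.0, eta_5ht=0.0))
        w = np.full((40, 121), 2.0)
        _, w2 = run_episode(cfg, w, 1, seed=1)
        np.testing.assert_array_equal(w, w2)

    def test_platform_at_start_immediate_reward(self):
        proto = vn.make_protocol("mwm", start_position=(1.5, 1.5))
        cfg = vn.RunConfig(protocol=proto, rule="swc", seed=9)
        w = np.full((40, 121), 2.0)
        rec, w2 = run_episode(cfg, w, 1, seed=1)
        assert rec.outcome == "reward"
        assert rec.latency_s == pytest.approx(0.01)  # first movement check
        assert np.all(w2 >= w)  # dopamine-only potentiation

    def test_fixed_seed_reproducible(self):
        cfg = _short_cfg(record_trajectories=True)
        w = np.full((40, 121), 2.0)
        r1, w1 = run_episode(cfg, w, 1, seed=33)
        r2, w2 = run_episode(cfg, w, 1, seed=33)
        assert r1.outcome == r2.outcome and r1.latency_s == r2.latency_s
        np.testing.assert_array_equal(w1, w2)
        np.testing.assert_array_equal(r1.trajectory, r2.trajectory)

    def test_weights_respect_bounds_after_update(self):
        cfg = _short_cfg()
        w = np.full((40, 121), 1.05)  # near the floor; failure would depress
        _, w2 = run_episode(cfg, w, 1, seed=2)
        assert w2.min() >= cfg.plasticity.w_min
        assert w2.max() <= cfg.plasticity.w_max


class TestFinalizeUpdate:
    CFG = _short_cfg()

    def test_swc_dichotomy_by_outcome(self):
        g = np.abs(np.random.default_rng(0).normal(size=(40, 121)))
        up = finalize_update(self.CFG, "reward", g, g, g, 1.0)
        down = finalize_update(self.CFG, "none", g, g, g, 1.0)
        assert np.all(up >= 0) and np.all(down <= 0)

    def test_cwc_mixed_signs_possible(self):
        cfg = _short_cfg(rule="cwc")
        rng = np.random.default_rng(1)
        g_da = np.abs(rng.normal(size=(40, 121)))
        int5 = np.abs(rng.normal(size=(40, 121))) * 2.0
        dw = finalize_update(cfg, "reward", g_da, g_da, int5, 1.0)
        assert np.any(dw > 0) and np.any(dw < 0)

    def test_reversal_neutral_episode_no_update(self):
        cfg = _short_cfg(protocol=vn.make_protocol("reversal"))
        g = np.ones((40, 121))
        for rule in ("swc", "cwc"):
            dw = finalize_update(replace(cfg, rule=rule), "none", g, g, g, 1.0)
            assert np.all(dw == 0)

    def test_serotonin_factor_silences_and_doubles(self):
        g = np.ones((40, 121))
        base = finalize_update(self.CFG, "none", g, g, g, 1.0)
        assert np.all(finalize_update(self.CFG, "none", g, g, g, 0.0) == 0)
        np.testing.assert_allclose(
            finalize_update(self.CFG, "none", g, g, g, 2.0), 2 * base)

    def test_online_variant_matches_expected_scale(self):
        cfg = _short_cfg(rule="swc-online")
        int5 = np.ones((40, 121)) * cfg.protocol.t_max  # unit trace for Tmax
        dw = finalize_update(cfg, "none", int5, int5, int5, 1.0)
        assert dw == pytest.approx(-cfg.plasticity.eta_5ht * np.ones((40, 121)))


class TestRunSimulationAndBatch:
    def test_episode_count_and_persistent_weights(self):
        cfg = _short_cfg()
        recs = run_simulation(cfg, 0)
        assert len(recs) == 2
        assert recs[-1].weights_after is not None
        assert all(r.latency_s <= cfg.protocol.t_max + 1e-9 for r in recs)

    def test_batch_of_one_equals_single_simulation(self):
        cfg = _short_cfg()
        s = run_batch(cfg)
        recs = run_simulation(cfg, 0)
        assert [r.outcome for r in s.records[0]] == [r.outcome for r in recs]
        assert s.first_reward_episode.shape == (1,)

    def test_same_master_seed_identical_summary(self):
        cfg = _short_cfg(n_simulations=2)
        s1, s2 = run_batch(cfg), run_batch(cfg)
        np.testing.assert_array_equal(s1.success_fraction, s2.success_fraction)
        np.testing.assert_array_equal(s1.final_weights, s2.final_weights)

    def test_derived_seeds_distinct(self):
        seeds = {_episode_seed(7, s, e) for s in range(20) for e in range(1, 5)}
        assert len(seeds) == 80

    def test_success_fraction_is_share_of_simulations(self):
        cfg = _short_cfg(n_simulations=3)
        s = run_batch(cfg)
        for e in range(2):
            expected = np.mean(
                [recs[e].outcome == "reward" for recs in s.records])
            assert s.success_fraction[e] == pytest.approx(expected)

    def test_stop_after_first_reward_truncates(self):
        proto = vn.make_protocol("mwm", start_position=(1.5, 1.5))
        cfg = vn.RunConfig(protocol=proto, rule="swc", seed=9,
                           stop_after_first_reward=True)
        recs = run_simulation(cfg, 0)
        assert len(recs) == 1 and recs[0].outcome == "reward"

    def test_summarize_consistency(self):
        cfg = _short_cfg(n_simulations=2)
        s = run_batch(cfg)
        s2 = summarize(cfg, s.records)
        np.testing.assert_array_equal(s.success_fraction, s2.success_fraction)


class TestRuleVariants:
    @pytest.mark.parametrize("rule", ["swc-online", "rate-swc", "rate-cwc"])
    def test_variant_episodes_respect_bounds_and_signs(self, rule):
        cfg = _short_cfg(rule=rule)
        w = np.full((40, 121), 2.0)
        rec, w2, dbg = run_episode(cfg, w, 1, seed=8, record_debug=True)
        assert w2.min() >= 1.0 and w2.max() <= 3.0
        dw = dbg["dw"]
        if rec.outcome == "reward":
            assert np.all(dw >= 0) if rule != "rate-cwc" else True
        else:
            # aversive MWM episode: serotonin-driven depression only
            if rule in ("swc-online", "rate-swc"):
                assert np.all(dw <= 0) and np.any(dw < 0)

    def test_rate_drive_accumulates_on_visited_fields(self):
        cfg = _short_cfg(rule="rate-swc")
        w = np.full((40, 121), 2.0)
        _, _, dbg = run_episode(cfg, w, 1, seed=8, record_debug=True)
        g = dbg["gamma_5ht"]
        assert g.max() > 0
        # fields far from the trajectory stay silent
        traj_cells = g.max(axis=0)
        assert (traj_cells == 0).sum() > 0 or traj_cells.min() < 1e-6 * traj_cells.max()


class TestSpatialMemoryProbe:
    def test_probe_runs_full_duration_without_learning(self):
        cfg = _short_cfg()
        w = np.full((40, 121), 2.0)
        traj = run_probe(cfg, w, seed=11)
        # no outcome can terminate the probe early
        assert len(traj) == int(cfg.protocol.t_max * 1000 / cfg.dt_move) + 1

    def test_goal_biased_weights_probe_closer_to_platform(self):
        """Boosting the neurons that point toward the platform shrinks the
        probe's median distance to it."""
        cfg = vn.RunConfig(protocol=vn.make_protocol("mwm"), rule="swc", seed=1)
        uniform = np.full((40, 121), 1.5)
        biased = uniform.copy()
        # theta_k = 2*pi*k/40 with k starting at 1: rows 3-6 point northeast
        biased[3:7, :] = 3.0
        d_uniform = np.mean([
            distance_stats(run_probe(cfg, uniform, seed=s), (1.5, 1.5))
            for s in range(3)])
        d_biased = np.mean([
            distance_stats(run_probe(cfg, biased, seed=s), (1.5, 1.5))
            for s in range(3)])
        assert d_biased < d_uniform


class TestOptoSchedule:
    def test_factor_by_episode(self):
        cfg = _short_cfg(opto=(OptoWindow(2, 3, "inhibit"), OptoWindow(5, 5, "activate")))
        assert cfg.fivehT_factor(1) == 1.0
        assert cfg.fivehT_factor(2) == 0.0
        assert cfg.fivehT_factor(3) == 0.0
        assert cfg.fivehT_factor(5) == 2.0

    def test_no_5ht_overrides_everything(self):
        cfg = _short_cfg(no_5ht=True, opto=(OptoWindow(1, 9, "activate"),))
        assert cfg.fivehT_factor(1) == 0.0

    def test_invalid_mode_rejected(self):
        with pytest.raises(ValueError):
            OptoWindow(1, 2, "ablate")


class TestGridSearch:
    def test_single_point_grid(self):
        cfg = _short_cfg()
        ranked = vn.grid_search(cfg, {"eta_5ht": [0.01]}, m_small=1)
        assert len(ranked) == 1
        assert ranked[0]["params"] == {"eta_5ht": 0.01}

    def test_tie_break_lexicographic(self):
        cfg = _short_cfg(protocol=vn.make_protocol("mwm", t_max=0.2, episodes_per_trial=1))
        ranked = vn.grid_search(cfg, {"eta_5ht": [0.02, 0.01]}, m_small=1)
        scores = [r["final_success"] for r in ranked]
        if scores[0] == scores[1]:
            assert ranked[0]["params"]["eta_5ht"] == 0.01

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            vn.grid_search(_short_cfg(), {})


class TestConfigValidation:
    def test_unknown_rule(self):
        with pytest.raises(ValueError):
            _short_cfg(rule="hebbian")

    def test_bad_timing(self):
        with pytest.raises(ValueError):
            _short_cfg(dt=2.0, dt_move=1.0)

    def test_config_serializes_to_json(self):
        cfg = _short_cfg(opto=(OptoWindow(1, 2, "inhibit"),))
        doc = cfg.to_json()
        assert "inhibit" in doc and "swc" in doc
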