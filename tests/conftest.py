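"""Shared fixtures.

The session-scoped batch fixtures run the scaled-down study conditions once
and are shared by the acceptance tests and the statistical invariants; they
are only built when a test requests them.
"""

from __future__ import annotations

import numpy as np
import pytest

import valencenav as vn
from valencenav.simulation import OptoWindow

# three optogenetic intervals spread over the run, the last covering the
# final episodes (the perturbation windows are experiment configuration)
OPTO_WINDOWS = (
    OptoWindow(6, 10, "inhibit"),
    OptoWindow(21, 25, "inhibit"),
    OptoWindow(36, 40, "inhibit"),
)

M_LEARNING = 150   # batch size for the learning-curve comparisons
M_OPTO = 120       # batch size for the perturbation arms
M_JSD = 500        # per-condition size for the first-reward divergence
M_REVERSAL = 80    # per-learning-rate size for the reversal sweep
REVERSAL_ETAS = (0.005, 0.01, 0.02)


def _mwm_config(rule: str, seed: int, **kw) -> vn.RunConfig:
    return vn.RunConfig(protocol=vn.make_protocol("mwm"), rule=rule, seed=seed, **kw)


@pytest.fixture(scope="session")
def mwm_batches():
    """Morris-water-maze batches: control and DA-only arms for both rules."""
    out = {}
    for rule in ("swc", "cwc"):
        out[rule, "control"] = vn.run_batch(
            _mwm_config(rule, seed=101, n_simulations=M_LEARNING))
        out[rule, "no5ht"] = vn.run_batch(
            _mwm_config(rule, seed=101, n_simulations=M_LEARNING, no_5ht=True))
    return out


@pytest.fixture(scope="session")
def opto_batches():
    """Optogenetic serotonin inhibition/activation arms for both rules."""
    out = {}
    for rule in ("swc", "cwc"):
        for mode in ("inhibit", "activate"):
            windows = tuple(
                OptoWindow(w.first_episode, w.last_episode, mode) for w in OPTO_WINDOWS
            )
            out[rule, mode] = vn.run_batch(
                _mwm_config(rule, seed=101, n_simulations=M_OPTO, opto=windows))
    return out


@pytest.fixture(scope="session")
def first_reward_runs():
    """First-reward episode indices per rule and serotonin condition."""
    out = {}
    for rule in ("swc", "cwc"):
        for no5 in (False, True):
            cfg = _mwm_config(
                rule, seed=3, n_simulations=M_JSD, no_5ht=no5,
                stop_after_first_reward=True)
            out[rule, no5] = vn.run_batch(cfg).first_reward_episode
    return out


@pytest.fixture(scope="session")
def reversal_sweep():
    """Reversal-learning batches across serotonin learning rates."""
    from dataclasses import replace

    out = {}
    for eta in REVERSAL_ETAS:
        cfg = vn.RunConfig(
            protocol=vn.make_protocol("reversal"), rule="swc", seed=55,
            n_simulations=M_REVERSAL)
        cfg = replace(cfg, plasticity=replace(cfg.plasticity, eta_5ht=eta))
        out[eta] = vn.run_batch(cfg)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
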