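"""Deterministic synthetic instances with oracle-computed expectations.

The generators here produce small, exactly reproducible test cases — spike
train scenarios with brute-force STDP/trace sums, distribution pairs with
directly summed divergences, and episode-shaped proto-weight histories with
quadrature-integrated LTP/LTD labels.  The oracles are intentionally naive
(double loops, dense trapezoids) and independent of the production code
paths; each fixture stores its expectation so tests can regenerate and
compare.  Everything serializes to JSON for cross-language reuse.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .plasticity import (
    NeuromodulatorSignal,
    STDPWindow,
)

__all__ = [
    "SpikeScenario",
    "make_spike_scenarios",
    "make_distribution_pairs",
    "make_cwc_integration_cases",
    "brute_force_pair_sum",
    "brute_force_trace",
    "direct_kl",
    "direct_jsd",
]


# ---------------------------------------------------------------------------
# independent oracles


def _window_scalar(s: float, w: STDPWindow) -> float:
    if w.shape == "symmetric_da":
        return w.amplitude * float(np.exp(-abs(s) / w.tau))
    if s > 0:
        return w.amplitude * float(np.exp(-s / w.tau))
    if s == 0:
        return 0.5 * w.amplitude
    return 0.0


def brute_force_pair_sum(pre, post, w: STDPWindow) -> float:
    """Direct double loop over all (pre, post) spike pairs."""
    total = 0.0
    for tp in pre:
        for ta in post:
            total += _window_scalar(ta - tp, w)
    return total


def brute_force_trace(
    event_times_ms, event_values, t_ms: float, tau_e_s: float
) -> float:
    """Direct convolution of point events with the eligibility kernel at t."""
    total = 0.0
    for te, v in zip(event_times_ms, event_values):
        if te <= t_ms:
            total += v * float(np.exp(-(t_ms - te) / (tau_e_s * 1e3)))
    return total


def direct_kl(p, q) -> float:
    total = 0.0
    for pi, qi in zip(p, q):
        if pi > 0:
            total += pi * float(np.log2(pi / qi))
    return total


def direct_jsd(p, q) -> float:
    m = [(pi + qi) / 2.0 for pi, qi in zip(p, q)]
    return 0.5 * direct_kl(p, m) + 0.5 * direct_kl(q, m)


# ---------------------------------------------------------------------------
# fixture generators


@dataclass
class SpikeScenario:
    """Named pre/post spike trains with oracle-computed expectations."""

    name: str
    pre_ms: list[float]
    post_ms: list[float]
    expected: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self))


_DA = STDPWindow(1.0, 10.0, "symmetric_da")
_5HT = STDPWindow(1.0, 10.0, "causal_depressive_5ht")


def _with_expectations(name: str, pre, post) -> SpikeScenario:
    sc = SpikeScenario(name=name, pre_ms=list(map(float, pre)), post_ms=list(map(float, post)))
    sc.expected["pair_sum_da"] = brute_force_pair_sum(sc.pre_ms, sc.post_ms, _DA)
    sc.expected["pair_sum_5ht"] = brute_force_pair_sum(sc.pre_ms, sc.post_ms, _5HT)
    # trace at 1 s past the last event: one pairing event per post spike,
    # valued at its pairwise sum against all pre spikes
    events = [(ta, brute_force_pair_sum(sc.pre_ms, [ta], _DA)) for ta in sc.post_ms]
    t_read = (max(sc.post_ms) if sc.post_ms else 0.0) + 1000.0
    sc.expected["trace_da_at_1s"] = brute_force_trace(
        [e[0] for e in events], [e[1] for e in events], t_read, 2.0
    )
    return sc


def make_spike_scenarios(seed: int = 0) -> list[SpikeScenario]:
    """Deterministic scenario library: empties, single pairs, bursts, long trains."""
    rng = np.random.default_rng(seed)
    scenarios = [
        _with_expectations("empty", [], []),
        _with_expectations("pre_only", [0.0, 5.0, 12.0], []),
        _with_expectations("post_only", [], [3.0, 9.0]),
    ]
    for lag in (-20.0, -10.0, 0.0, 10.0, 20.0):
        scenarios.append(_with_expectations(f"pair_lag_{lag:+.0f}ms", [100.0], [100.0 + lag]))
    burst_pre = sorted(rng.uniform(0, 50, size=8))
    burst_post = sorted(rng.uniform(0, 50, size=5))
    scenarios.append(_with_expectations("burst", burst_pre, burst_post))
    long_pre = sorted(rng.uniform(0, 12_000, size=60))
    long_post = sorted(rng.uniform(0, 12_000, size=25))
    scenarios.append(_with_expectations("long_multi_tau_e", long_pre, long_post))
    return scenarios


def make_distribution_pairs(seed: int = 0) -> list[tuple[list, list, float]]:
    """(P, Q, expected JSD) triples: identical, disjoint, and random pairs."""
    rng = np.random.default_rng(seed)
    pairs = [
        ([0.25, 0.25, 0.5], [0.25, 0.25, 0.5], 0.0),
        ([1.0, 0.0], [0.0, 1.0], 1.0),
        ([0.5, 0.5, 0.0, 0.0], [0.0, 0.0, 0.5, 0.5], 1.0),
        ([1.0, 0.0], [0.5, 0.5], direct_jsd([1.0, 0.0], [0.5, 0.5])),
    ]
    for _ in range(6):
        k = int(rng.integers(2, 8))
        p = rng.dirichlet(np.ones(k))
        q = rng.dirichlet(np.ones(k))
        pairs.append((p.tolist(), q.tolist(), direct_jsd(p.tolist(), q.tolist())))
    return pairs


def make_cwc_integration_cases(seed: int = 0, n: int = 100) -> list[dict]:
    """Episode-shaped proto-weight histories with quadrature-derived net sign.

    Each case holds time grids and Gamma histories for DA and 5-HT, the step
    response signals, the trapezoidal integrals of R*Gamma, and the implied
    label: "LTP", "LTD" or "none".
    """
    rng = np.random.default_rng(seed)
    cases = []
    for idx in range(n):
        t_rew = float(rng.uniform(2.0, 14.0))
        t_da = 1.0
        t = np.linspace(0.0, t_rew + t_da, 400)
        kind = idx % 4
        # piecewise step/decay histories emulating pairing bursts
        def history(rate_scale, tau):
            burst_times = np.sort(rng.uniform(0, t_rew, size=rng.integers(1, 6)))
            amps = rng.uniform(0.1, 1.0, size=len(burst_times)) * rate_scale
            g = np.zeros_like(t)
            for bt, a in zip(burst_times, amps):
                g += np.where(t >= bt, a * np.exp(-(t - bt) / tau), 0.0)
            return g

        if kind == 0:  # DA-only
            g_da, g_5 = history(1.0, 2.0), np.zeros_like(t)
        elif kind == 1:  # 5-HT-only
            g_da, g_5 = np.zeros_like(t), history(1.0, 5.0)
        elif kind == 2:  # mixed
            g_da, g_5 = history(1.0, 2.0), history(1.0, 5.0)
        else:  # balanced: scale 5-HT to cancel the DA integral exactly
            g_da, g_5 = history(1.0, 2.0), history(1.0, 5.0)
        rda = NeuromodulatorSignal("DA", 1.0, t_rew, t_rew + t_da)
        r5 = NeuromodulatorSignal("5HT", 1.0, 0.0, t_rew)
        i_da = float(np.trapezoid(rda(t) * g_da, t))
        i_5 = float(np.trapezoid(r5(t) * g_5, t))
        if kind == 3 and i_5 > 0:
            g_5 = g_5 * (i_da / i_5)
            i_5 = float(np.trapezoid(r5(t) * g_5, t))
        diff = i_da - i_5
        label = "none" if abs(diff) < 1e-12 else ("LTP" if diff > 0 else "LTD")
        cases.append(
            {
                "t_s": t,
                "gamma_da": g_da,
                "gamma_5ht": g_5,
                "t_rew_s": t_rew,
                "t_da_s": t_da,
                "integral_da": i_da,
                "integral_5ht": i_5,
                "label": label,
            }
        )
    return cases
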