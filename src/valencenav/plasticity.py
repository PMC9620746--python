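"""Reward-modulated STDP rules for dopamine/serotonin valence learning.

Two three-factor rules update the feed-forward place-cell -> action-neuron
weights.  Both first convert pre/post spike coincidences into per-synapse
*proto-weights* Gamma: the pairwise STDP window value W(t_post - t_pre) is
accumulated and then low-pass filtered by an exponential eligibility trace
(tau_e = 2 s for dopamine, 5 s for serotonin).  They differ in how the
neuromodulators convert Gamma into actual weight change:

* **SWC** (sequential weight change): exactly one modulator resolves each
  episode.  Reaching the reward releases dopamine, which reads the DA trace
  300 ms after the reward and potentiates (R = +1); failure (or punishment)
  leaves serotonin dominant, which reads the 5-HT trace at episode end and
  depresses (R = -1).  Every synapse therefore moves in the same direction
  within an episode.

* **CWC** (competitive weight change): both traces compete continuously,
  dw/dt = eta * (R_DA(t)*Gamma_DA - R_5HT(t)*Gamma_5HT), where the serotonin
  response is a tonic step active until the outcome and the dopamine
  response a phasic step of duration T_DA = 1 s after the reward.  The net
  per-synapse sign is decided by which integral wins, so a rewarded episode
  can still depress some synapses.

STDP windows: dopamine's is symmetric, W_DA(s) = A_DA * exp(-|s|/tau); the
serotonin window is causal-only and depressive, W_5HT(s) = A_5HT*exp(-s/tau)
for s > 0, A_5HT/2 at s = 0, 0 for s < 0.  Windows are stored as magnitudes;
the depressive sign is carried by the outcome signal R.

Weights are clipped to [w_min, w_max] = [1, 3] at the end of every episode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "STDPWindow",
    "EligibilityTrace",
    "NeuromodulatorSignal",
    "PlasticityParams",
    "ProtoWeight",
    "RateRuleParams",
    "DA_WINDOW_SWC",
    "HT_WINDOW_SWC",
    "DA_WINDOW_CWC",
    "HT_WINDOW_CWC",
    "window_value",
    "pairwise_stdp_sum",
    "update_trace",
    "swc_apply",
    "swc_online_apply",
    "cwc_step",
    "cwc_sign_condition",
    "clip_weights",
    "rate_based_update",
]

TAU_E_DA_S = 2.0
TAU_E_5HT_S = 5.0
T_DA_S = 1.0  # phasic dopamine duration after the reward (CWC)
SWC_READOUT_DELAY_S = 0.3  # consummatory delay before the DA readout (SWC)


@dataclass(frozen=True)
class STDPWindow:
    """STDP coincidence window (magnitude; sign carried by the outcome R).

    ``symmetric_da``: W(s) = A*exp(-|s|/tau).
    ``causal_depressive_5ht``: W(s) = A*exp(-s/tau) for s > 0, A/2 at s = 0,
    0 for s < 0 (anti-causal pairs are ignored).
    """

    amplitude: float
    tau: float = 10.0  # ms
    shape: str = "symmetric_da"

    def __post_init__(self) -> None:
        if self.shape not in ("symmetric_da", "causal_depressive_5ht"):
            raise ValueError(f"unknown window shape {self.shape!r}")
        if self.tau <= 0:
            raise ValueError("tau must be positive")


DA_WINDOW_SWC = STDPWindow(amplitude=1.0, shape="symmetric_da")
HT_WINDOW_SWC = STDPWindow(amplitude=1.0, shape="causal_depressive_5ht")
DA_WINDOW_CWC = STDPWindow(amplitude=1.0, shape="symmetric_da")
HT_WINDOW_CWC = STDPWindow(amplitude=0.01, shape="causal_depressive_5ht")


@dataclass
class EligibilityTrace:
    """Exponentially decaying synaptic eligibility, kernel e^(-t/tau_e)."""

    tau_e_s: float
    value: float | np.ndarray = 0.0


@dataclass(frozen=True)
class NeuromodulatorSignal:
    """Step-function neuromodulator response R(t).

    Serotonin is tonic on [0, Trew]; dopamine is phasic on
    [Trew, Trew + t_da].
    """

    kind: str  # "DA" | "5HT"
    amplitude: float
    t_on: float
    t_off: float

    def __post_init__(self) -> None:
        if self.kind not in ("DA", "5HT"):
            raise ValueError(f"unknown modulator {self.kind!r}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")

    def __call__(self, t: float | np.ndarray):
        t = np.asarray(t, dtype=float)
        out = np.where((t >= self.t_on) & (t <= self.t_off), self.amplitude, 0.0)
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class PlasticityParams:
    """Learning rates, clip bounds and modulator amplitudes (per rule)."""

    eta_da: float = 0.01
    eta_5ht: float = 0.01
    w_min: float = 1.0
    w_max: float = 3.0
    rda_amp: float = 1.0
    r5ht_amp: float = 1.0

    def __post_init__(self) -> None:
        if not self.w_min < self.w_max:
            raise ValueError("require w_min < w_max")
        if self.eta_da < 0 or self.eta_5ht < 0:
            raise ValueError("learning rates must be non-negative")


@dataclass
class ProtoWeight:
    """Per-synapse proto-weight matrix Gamma for one modulator (>= 0)."""

    values: np.ndarray
    tau_e_s: float


@dataclass(frozen=True)
class RateRuleParams:
    """Rate-based (BCM-style) variant: drift proportional to the window area.

    The drift is (A * tau) * nu_post * nu_pre filtered by the eligibility
    kernel; Hebbian for dopamine (R = +1), anti-Hebbian for serotonin
    (R = -1).
    """

    amplitude: float = 1.0
    tau_ms: float = 10.0
    mode: str = "hebbian_da"

    def __post_init__(self) -> None:
        if self.mode not in ("hebbian_da", "antihebbian_5ht"):
            raise ValueError(f"unknown rate-rule mode {self.mode!r}")

    @property
    def window_integral(self) -> float:
        return self.amplitude * self.tau_ms


def window_value(s_ms, w: STDPWindow):
    """Evaluate the STDP window at pre-to-post lag s = t_post - t_pre (ms)."""
    s = np.asarray(s_ms, dtype=float)
    if w.shape == "symmetric_da":
        out = w.amplitude * np.exp(-np.abs(s) / w.tau)
    else:
        out = np.where(
            s > 0,
            w.amplitude * np.exp(-np.clip(s, 0, None) / w.tau),
            np.where(s == 0, 0.5 * w.amplitude, 0.0),
        )
    return out if out.ndim else float(out)


def pairwise_stdp_sum(pre_spikes, post_spikes, w: STDPWindow) -> float:
    """Sum W(t_post - t_pre) over all pre/post spike pairs."""
    pre = np.asarray(pre_spikes, dtype=float)
    post = np.asarray(post_spikes, dtype=float)
    if pre.size == 0 or post.size == 0:
        return 0.0
    lags = post[:, None] - pre[None, :]
    return float(np.sum(window_value(lags, w)))


def update_trace(
    trace: EligibilityTrace, increment, dt_ms: float
) -> EligibilityTrace:
    """Decay the eligibility by e^(-dt/tau_e) and add the new STDP increment.

    Iterating this recursion over a train of increments reproduces the exact
    convolution of the STDP event train with the eligibility kernel.
    """
    if dt_ms <= 0:
        raise ValueError("dt must be positive")
    decay = np.exp(-dt_ms * 1e-3 / trace.tau_e_s)
    return EligibilityTrace(trace.tau_e_s, trace.value * decay + increment)


def swc_apply(
    gamma_da: np.ndarray,
    gamma_5ht: np.ndarray,
    outcome: str,
    p: PlasticityParams,
    a5ht_factor: float = 1.0,
) -> np.ndarray:
    """End-of-episode SWC update: exactly one modulator contributes.

    ``gamma_da`` must already be the DA proto-weight read at
    Trew + 300 ms, ``gamma_5ht`` the 5-HT proto-weight read at episode end.
    Reward -> +eta_da * Gamma_DA; otherwise -> -eta_5ht * Gamma_5HT.
    ``a5ht_factor`` rescales the serotonergic term (optogenetic perturbation).
    """
    if outcome == "reward":
        return p.eta_da * np.asarray(gamma_da, dtype=float)
    return -p.eta_5ht * a5ht_factor * np.asarray(gamma_5ht, dtype=float)


def swc_online_apply(
    gamma_5ht_integral: np.ndarray, t_max_s: float, p: PlasticityParams
) -> np.ndarray:
    """Online-serotonin SWC candidate: continuous LTD at rate eta_5ht/Tmax.

    ``gamma_5ht_integral`` is the time integral of the 5-HT proto-weight over
    the episode (in trace units * s).  The candidate is discarded in favour
    of the DA update if the episode ends in reward.
    """
    return -(p.eta_5ht / t_max_s) * np.asarray(gamma_5ht_integral, dtype=float)


def cwc_step(
    gamma_da: np.ndarray,
    gamma_5ht: np.ndarray,
    t_s: float,
    rda: NeuromodulatorSignal,
    r5ht: NeuromodulatorSignal,
    eta: float,
    dt_s: float,
) -> np.ndarray:
    """One Euler step of the competitive rule.

    dw = eta * (R_DA(t)*Gamma_DA - R_5HT(t)*Gamma_5HT) * dt.
    """
    return eta * (rda(t_s) * np.asarray(gamma_da) - r5ht(t_s) * np.asarray(gamma_5ht)) * dt_s


def cwc_sign_condition(
    t_s: np.ndarray,
    gamma_da_hist: np.ndarray,
    gamma_5ht_hist: np.ndarray,
    rda: NeuromodulatorSignal,
    r5ht: NeuromodulatorSignal,
) -> np.ndarray:
    """Predict the net LTP/LTD direction of the episode per synapse.

    Compares the trapezoidal integrals of R_DA*Gamma_DA and R_5HT*Gamma_5HT
    over the episode history; returns +1 (LTP), -1 (LTD) or 0 per synapse.
    The result matches the sign of the accumulated ``cwc_step`` increments.
    """
    t_s = np.asarray(t_s, dtype=float)
    da = np.trapezoid(rda(t_s)[..., None] * gamma_da_hist, t_s, axis=0)
    ht = np.trapezoid(r5ht(t_s)[..., None] * gamma_5ht_hist, t_s, axis=0)
    diff = da - ht
    # balanced integrals count as no net change (fp-tolerant zero)
    tol = 1e-12 * np.maximum(np.maximum(np.abs(da), np.abs(ht)), 1.0)
    return np.sign(np.where(np.abs(diff) <= tol, 0.0, diff))


def clip_weights(w: np.ndarray, p: PlasticityParams) -> np.ndarray:
    """Clamp weights elementwise to [w_min, w_max]."""
    return np.clip(w, p.w_min, p.w_max)


def rate_based_update(
    nu_pre_hz,
    nu_post_hz,
    trace: EligibilityTrace,
    r_sign: int,
    params: RateRuleParams,
    p: PlasticityParams,
    dt_ms: float = 1.0,
) -> tuple[np.ndarray, EligibilityTrace]:
    """One step of the rate-based (BCM-style) rule.

    The instantaneous drive (A*tau) * nu_pre * nu_post (rates in kHz, window
    area in ms) is pushed through the eligibility trace; the weight increment
    is eta * R * trace * dt with R = +1 (Hebbian, DA) or -1 (anti-Hebbian,
    5-HT).
    """
    if r_sign not in (1, -1):
        raise ValueError("R must be +1 or -1")
    drive = params.window_integral * (
        np.asarray(nu_pre_hz, dtype=float) * 1e-3
    ) * (np.asarray(nu_post_hz, dtype=float) * 1e-3)
    new_trace = update_trace(trace, drive * dt_ms * 1e-3, dt_ms)
    eta = p.eta_da if r_sign > 0 else p.eta_5ht
    dw = eta * r_sign * np.asarray(new_trace.value) * dt_ms * 1e-3
    return dw, new_trace


def make_cwc_signals(
    t_rew_s: float,
    p: PlasticityParams,
    rewarded: bool,
    t_da_s: float = T_DA_S,
    a5ht_factor: float = 1.0,
) -> tuple[NeuromodulatorSignal, NeuromodulatorSignal]:
    """Standard CWC response pair: tonic 5-HT until the outcome, phasic DA after.

    In an unrewarded episode the dopamine response never turns on.
    """
    rda = NeuromodulatorSignal(
        "DA",
        p.rda_amp if rewarded else 0.0,
        t_rew_s,
        t_rew_s + t_da_s,
    )
    r5ht = NeuromodulatorSignal("5HT", p.r5ht_amp * a5ht_factor, 0.0, t_rew_s)
    return rda, r5ht
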