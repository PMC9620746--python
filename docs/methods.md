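# Methods

## Model overview

`valencenav` simulates valence-based spatial learning in a minimal
hippocampal circuit: a feed-forward layer of **place cells** encodes the
agent's position and drives a ring of **action neurons** whose population
vector moves the agent; **reward-modulated STDP** on the feed-forward
weights, with dopamine (DA) acting as an LTP signal and serotonin (5-HT) as
an LTD signal, shapes navigation across episodes of a Morris water maze
(MWM) or a reversal-learning task.

### Positional input

121 place cells sit on an 11×11 grid with spacing σ = 0.4 a.u. covering the
square arena S = [−2, 2]² (boundary rows included). Cell *i* fires as an
inhomogeneous Poisson process with Gaussian tuning

    λ_i(x) = λ̄ · exp(−‖x − x_i‖² / σ²),   λ̄ = 400 Hz.

### Action layer (SRM0)

40 direction-tuned neurons follow a zero-order spike response model. The
membrane potential sums EPSP kernels

    ε(t) = ε0/(τm − τs) · (e^(−t/τm) − e^(−t/τs)),  ε0 = 20 mV·ms,
    τm = 20 ms, τs = 5 ms,

over feed-forward and lateral presynaptic spikes that arrived after the
neuron's own last spike, plus a refractory after-potential
χ·e^(−(t−t̂)/τm) with χ = −5 mV. Spikes are emitted stochastically at rate
λ(u) = λ0·exp((u − θ)/Δu), λ0 = 60 Hz, θ = 16 mV. Δu (the emission window)
has no established value; the default is 2 mV and it is configurable — larger
values make action selection noisier and exploration more diffuse.

Lateral connectivity is fixed ("N-winner-takes-all"): uniform inhibition
w−/N (w− = −300) plus excitation w+ = 100 distributed over similar
directions through f(k,k′) = (1 − δ_{kk′})·exp(ζ·cos(θk − θk′)), ζ = 20,
row-normalized. Excitation peaks at the neighbouring directions k′ = k ± 1;
self-excitation is zero.

### Movement

Each neuron's instantaneous rate ρ_k is its spike train filtered with the
normalized double exponential γ (τγ = 50 ms, νγ = 20 ms); the movement
command is the population vector a = (1/N)·Σ ρ_k a_k with
a_k = a0·(sin θk, cos θk), a0 = 0.08.

The time base of ρ is not dictated by the population-vector formula, so the
package fixes a convention: ρ is in spikes/ms and the agent moves once per
dt_move = 10 ms by Δx = a(t)·dt_move. Under the default parameters this
yields ~1.2 a.u./s of naive travel — latencies on the seconds scale for a
4×4 a.u. arena, which is the regime the task design assumes. Moves that
would leave S are replaced by a d0 = 0.01 a.u. displacement along the
inward boundary normal (the sum of normals at a corner), so the position is
always inside S.

### Tasks

*MWM*: hidden reward platform (disc of radius 0.3 at (1.5, 1.5)), start at
the origin, Tmax = 15 s per episode, 40 episodes by default (the episode
count is configurable; the reversal protocol fixes it at 40). Reaching the
platform ends the episode and deactivates the place cells. Failure to reach
it within Tmax is an aversive (water) episode.

*Reversal*: reward at (1.5, 1.5) and punisher at (−1.5, −1.5) for episodes
1–20; both centers swap for episodes 21–40 (radii unchanged). Zone
membership is the closed disc (with an fp-safe +1e−12 margin so
exact-boundary points count); overlapping zones are rejected at
configuration time. All activity state resets between episodes; weights
persist.

## Plasticity

Both rules convert spike coincidences into per-synapse **proto-weights**:
each (pre, post) pairing contributes the STDP window value
W(t_post − t_pre), and the pairing train is filtered by an exponential
eligibility trace with τe = 2 s (DA) or 5 s (5-HT). Windows (magnitudes;
the depressive sign is carried by the outcome factor R):

    W_DA(s)  = A_DA · e^(−|s|/τ)                      (symmetric)
    W_5HT(s) = A_5HT · e^(−s/τ) for s > 0, A_5HT/2 at s = 0, 0 for s < 0

with τ = 10 ms for both (the 5-HT window timing does not alter outcomes, so
it is set equal to DA's).

**SWC (sequential)** — exactly one modulator resolves each episode. Reward:
Δw = η_DA·Γ_DA read 300 ms after the reward (consummatory delay; the trace
decays through it and no new pairings accrue because spiking has stopped).
Failure (MWM) or punishment (reversal): Δw = −η_5HT·Γ_5HT read at episode
end. An *online* variant replaces the end-of-episode 5-HT readout with a
continuous candidate at rate η_5HT/Tmax (implemented as the trace's time
integral scaled by η_5HT/Tmax); the LTP/LTD orientation is still resolved
by the outcome, making it statistically equivalent to the end-of-episode
form.

**CWC (competitive)** — the traces compete continuously,
dw/dt = η·(R_DA(t)·Γ_DA − R_5HT(t)·Γ_5HT), with a tonic 5-HT step active on
[0, T_outcome] and a phasic DA step of duration T_DA = 1 s after the
reward. The episode update is the exact integral of this expression (the
decaying-trace tail over the DA phase is integrated analytically). The net
sign per synapse is decided by which integral wins, so a rewarded episode
may depress some synapses — unlike SWC, whose updates are always
sign-homogeneous within an episode.

Two integration conventions had to be fixed here:

* *Time base.* The competitive integral runs on the network's millisecond
  time base. This is what makes the standard CWC learning rate η = 1e−4
  effective: on a seconds base the per-episode drift would be ~1e−4 and the
  rule would never leave its initial condition, while on the ms base CWC
  reproduces the expected ordering (SWC > CWC > DA-only variants).
* *Feedback cadence.* CWC weight changes are accumulated during the episode
  and applied (then clipped) at episode end rather than fed back into the
  membrane potential step by step. With η = 1e−4 the within-episode drift
  is orders of magnitude below the weight scale, and end-of-episode
  application keeps the kernel's lazy trace bookkeeping exact.

Weights start uniform at 2.0 (midpoint of the clip range; initialization is a
free choice of this package) and are clipped to [w_min, w_max] = [1, 3] at the end of
every episode.

In the reversal task the outcomes are mutually exclusive, so both rules act
sequentially: reward → pure DA LTP, punishment → pure 5-HT LTD, neutral
episode → no update. CWC's phasic responses integrate the respective trace
over a 1 s window (the mirror of T_DA).

**Rate-based variants** (`rate-swc`, `rate-cwc`) replace spike pairing by
the drift (A·τ)·ν_pre·ν_post (BCM-flavoured; Hebbian for DA, anti-Hebbian
for 5-HT via R), filtered by the same eligibility traces and finalized by
the same SWC/CWC logic. The implementation keeps the window-integral scaling that motivates this
rule and omits any postsynaptic threshold term. The rate drive is
updated at the movement cadence (rates change only with position on that
timescale).

**Neuromodulator perturbations.** A DA-only control (`no_5ht`) and
per-episode optogenetic windows scale the serotonergic amplitude (inhibit →
×0, activate → ×2); because every update is linear in that amplitude, the
factor is applied at finalization. The perturbation episode intervals are a
config input; the packaged experiments use episodes 6–10, 21–25 and 36–40
(three evenly spread intervals, the last covering the final-episode
readout).

### Parameters that matter

| parameter | default | units | role |
|---|---|---|---|
| Δu | 2 | mV | emission noise; exploration breadth |
| dt | 1 | ms | neural integration step (resolves τs = 5 ms) |
| dt_move | 10 | ms | movement/outcome-check cadence |
| η_DA, η_5HT | 0.01 (SWC), 1e−4 (CWC) | — | learning rates |
| A_DA, A_5HT | 1, 1 (SWC); 1, 0.01 (CWC) | — | STDP window amplitudes |
| R_DA-Amp, R_5HT-Amp | 1, 1 | — | CWC response amplitudes |
| τe(DA), τe(5-HT) | 2, 5 | s | eligibility decay |
| w_init | 2.0 | — | initial feed-forward weight |

## Numerics

The episode kernel (numba) integrates at dt = 1 ms. EPSP sums, refractory
terms, rate-filter states and STDP pre/post traces are exact two-state
exponential recursions; per-synapse proto-weights and their time integrals
are updated lazily at pairing events with tabulated decay factors, making
the per-step cost independent of the 4840-synapse count. Place cells whose
spike probability falls below 1e−9/step and action neurons whose potential
implies the same are skipped (expected omitted spikes per episode ≪ 1e−2).
Action-neuron emission uses per-step Bernoulli probability min(λ(u)dt, 1);
the clamp binds only in pathological excursions far above threshold.
Same-step conventions: ε(0) = 0, so same-step EPSPs contribute nothing; a
same-step pre/post pair is credited once at W(0); a neuron that spikes in a
step does not receive that step's lateral spikes (its reset discards
arrivals at or before its own spike time). The compiled path is
cross-validated against the explicit spike-list formulations to 1e−9 in the
test suite.

Seeding: simulation *i*, episode *e* of a batch uses
`SeedSequence(master, i, e)`; runs are bit-identical across reruns and
independent of execution order.

## What the simulator emulates — and what it does not

All behavioral data are generated by the simulator itself under the
standard conditions (default parameters, fixed arena and zone geometry,
Tmax = 15 s, 40 episodes). It emulates the statistics that matter for the
claims: Poisson positional coding, winner-take-all action selection,
seconds-scale latencies, and outcome-gated neuromodulation. It does not
emulate receptor-level mechanisms, conduction delays, plastic lateral
connectivity, learned place fields, or non-stationary motivation — so
passing tests support the rules' computational behavior, not biological
mechanism. The spatial-memory probe (median distance to the platform
center with learning frozen and the reward disabled) is this package's own
protocol design.

## Problem sizes

The full study conditions use M = 1000 parallel simulations. The packaged
test suite and acceptance script run the same protocols at reduced sizes,
chosen as the smallest batches whose test statistics keep comfortable
margins: M = 150 for the learning-curve comparisons, M = 120 for the
optogenetic arms, M = 80 per rate for the reversal sweep (three 5-HT
rates), and M = 500 per condition for the first-reward divergences in the
suite. For the divergence runs, simulations stop after their first rewarded
episode — later episodes cannot change the first-reward statistic, so this
is exact; that saving also lets `scripts/acceptance.py` run the divergences
at the full batch size (M = 1000 per condition). Batch size
matters for this metric: the empirical JSD of two finite samples carries an
upward bias of roughly (K−1)/(4·ln 2)·(1/M_P + 1/M_Q)/2 bits over the
K-bin effective support (~0.02 at M = 500, ~0.01 at M = 1000), so
divergences are only comparable between runs of similar M.

## Known limitations

* The CWC time base and the movement-speed convention are calibration
  choices (documented above); other conventions rescale η or a0.
* The 5-HT LTD shortens time-to-first-reward noticeably in this
  implementation, so the two conditions' first-reward distributions differ
  measurably even though their divergence stays small.
* Stochastic assertions (learning improvements, perturbation effects) are
  seeded; at the reduced batch sizes their z-margins are ≥ 2.5 but a
  different convention choice upstream would require re-checking them.
* The rate-based variants are provided for completeness and sign/linearity
  properties are tested, but they are not tuned to reproduce the spiking
  rules' learning curves.
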