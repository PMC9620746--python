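# valencenav

Spiking-network simulator of **valence-based spatial learning**: how the
interplay of dopamine (DA, long-term potentiation) and serotonin (5-HT,
long-term depression) shapes navigation learning in a hippocampal
place-cell model. It is aimed at computational neuroscientists studying
neuromodulated, three-factor plasticity rules.

## The model

A feed-forward network of 121 Gaussian place cells
(λ_i(x) = λ̄·exp(−‖x−x_i‖²/σ²), λ̄ = 400 Hz, σ = 0.4 a.u.) drives 40
direction-tuned SRM0 action neurons arranged in a
winner-take-all ring. The population vector a(t) = (1/N)·Σ ρ_k(t)·a_k of
the filtered action-neuron rates moves an agent through a square arena
toward a hidden reward platform (Morris water maze) or between reward and
punishment zones that swap mid-run (reversal learning).

Feed-forward weights learn through reward-modulated STDP: pre/post
coincidences, weighted by an STDP window W(s) and filtered by an
eligibility trace e^(−t/τe) (τe = 2 s for DA, 5 s for 5-HT), form
per-synapse proto-weights Γ that neuromodulators convert into weight
change. Two rules are implemented:

* **SWC** (sequential weight change): one modulator resolves each episode —
  Δw = +η·Γ_DA after a rewarded episode (read 300 ms post-reward),
  Δw = −η·Γ_5HT after an aversive one. Updates are never mixed-sign.
* **CWC** (competitive weight change): dw/dt = η·(R_DA(t)·Γ_DA −
  R_5HT(t)·Γ_5HT) with tonic 5-HT until the outcome and a 1 s phasic DA
  response after the reward; the per-synapse sign is decided by the
  competition.

DA's window is symmetric (A·e^(−|s|/τ), τ = 10 ms); 5-HT's is causal-only
and depressive. Weights are clipped to [1, 3] per episode. Online-5-HT and
rate-based (BCM-style) variants of both rules are included, as are DA-only
controls and optogenetic-style 5-HT inhibition/activation schedules.

See `docs/methods.md` for the full model description, conventions and
numerical design.

## Worked example

```python
import numpy as np
import valencenav as vn

cfg = vn.RunConfig(protocol=vn.make_protocol("mwm"), rule="swc",
                   n_simulations=20, seed=7)
summary = vn.run_batch(cfg)
sf = summary.success_fraction
print(f"success fraction: episode 1 {sf[0]:.2f} -> episode 40 {sf[-1]:.2f}")
print(f"mean over last five episodes: {sf[-5:].mean():.2f}")
print(f"mean latency to reward in the final episode: "
      f"{np.mean(summary.latencies[-1]):.1f} s")
from valencenav.metrics import coefficient_of_variation
cv = coefficient_of_variation(summary.final_weights)
print(f"mean weight CV after training: {np.mean(cv.cv):.3f}")
```

prints

```
success fraction: episode 1 0.10 -> episode 40 0.75
mean over last five episodes: 0.70
mean latency to reward in the final episode: 3.3 s
mean weight CV after training: 0.231
```

i.e. with both neuromodulators active the agent goes from finding the
platform in 10% of naive episodes to 70–75% after 40 episodes, reaches it
in ~3 s once trained, and ends with polarized per-place-cell weight vectors
(CV ≈ 0.23). Passing `no_5ht=True` (DA-only control) slows and lowers the
curve; `rule="cwc"` learns, but less well than SWC.

## Command line

```bash
valencenav simulate --task mwm --rule swc --episodes 40 --sims 100 \
    --seed 1 --out runs/swc --trajectories
valencenav analyze --in runs/swc --metrics cv,latency,occupancy --out runs/swc/metrics
```

`simulate` writes a per-episode CSV, trajectories/weights (HDF5) and a JSON
run manifest; `analyze` produces tidy metric tables. A YAML config file
(`--config`) can replace the flags; unknown keys are rejected.

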