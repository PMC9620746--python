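"""Episode/trial orchestration and batch execution.

``run_episode`` wraps the compiled episode kernel: it simulates the spiking
network and the agent's movement until an outcome or Tmax, then finalizes the
configured plasticity rule's weight update and clips.  ``run_simulation``
chains episodes with persistent weights (activity resets between episodes);
``run_batch`` runs M independent simulations with derived seeds and
aggregates the learning curves.

Seeding contract: simulation i of a batch uses
``numpy.random.SeedSequence(master_seed, i)`` and episode e within it spawns
``SeedSequence(master_seed, i, e)``; results are therefore independent of
execution order and bit-identical across reruns.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace

import numpy as np

from . import _engine
from .arena import TaskProtocol, make_protocol
from .network import (
    LateralConnectivity,
    MembraneParams,
    RateFilter,
    build_place_grid,
    lateral_weights,
)
from .plasticity import (
    DA_WINDOW_CWC,
    DA_WINDOW_SWC,
    HT_WINDOW_CWC,
    HT_WINDOW_SWC,
    SWC_READOUT_DELAY_S,
    T_DA_S,
    TAU_E_5HT_S,
    TAU_E_DA_S,
    PlasticityParams,
    clip_weights,
)

__all__ = [
    "OptoWindow",
    "RunConfig",
    "EpisodeRecord",
    "RunSummary",
    "run_episode",
    "run_simulation",
    "run_batch",
    "grid_search",
]

RULES = ("swc", "cwc", "swc-online", "rate-swc", "rate-cwc")

_OUTCOME_NAME = {_engine.NONE: "none", _engine.REWARD: "reward", _engine.PUNISH: "punishment"}


@dataclass(frozen=True)
class OptoWindow:
    """Optogenetic serotonin perturbation over an inclusive episode range.

    ``inhibit`` silences the serotonergic signal (amplitude x0); ``activate``
    doubles it.
    """

    first_episode: int
    last_episode: int
    mode: str  # "inhibit" | "activate"

    def __post_init__(self) -> None:
        if self.mode not in ("inhibit", "activate"):
            raise ValueError(f"unknown opto mode {self.mode!r}")

    @property
    def factor(self) -> float:
        return 0.0 if self.mode == "inhibit" else 2.0


@dataclass(frozen=True)
class RunConfig:
    """Complete, serializable description of a run."""

    protocol: TaskProtocol = field(default_factory=lambda: make_protocol("mwm"))
    rule: str = "swc"
    plasticity: PlasticityParams | None = None
    membrane: MembraneParams = field(default_factory=MembraneParams)
    lateral: LateralConnectivity = field(default_factory=LateralConnectivity)
    rate_filter: RateFilter = field(default_factory=RateFilter)
    sigma: float = 0.4
    peak_rate: float = 400.0
    a_da: float | None = None
    a_5ht: float | None = None
    tau_stdp: float = 10.0
    tau_e_da_s: float = TAU_E_DA_S
    tau_e_5ht_s: float = TAU_E_5HT_S
    w_init: float = 2.0
    dt: float = 1.0
    dt_move: float = 10.0
    n_simulations: int = 1000
    seed: int = 0
    opto: tuple[OptoWindow, ...] = ()
    no_5ht: bool = False
    record_trajectories: bool = False
    stop_after_first_reward: bool = False
    snapshot_episodes: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.rule not in RULES:
            raise ValueError(f"unknown rule {self.rule!r}; choose from {RULES}")
        if self.plasticity is None:
            object.__setattr__(self, "plasticity", default_plasticity(self.rule))
        if self.a_da is None:
            object.__setattr__(self, "a_da", default_window_amplitudes(self.rule)[0])
        if self.a_5ht is None:
            object.__setattr__(self, "a_5ht", default_window_amplitudes(self.rule)[1])
        if self.dt <= 0 or self.dt_move < self.dt:
            raise ValueError("require 0 < dt <= dt_move")

    def fivehT_factor(self, episode: int) -> float:
        """Serotonin amplitude scale for a 1-based episode index."""
        if self.no_5ht:
            return 0.0
        for w in self.opto:
            if w.first_episode <= episode <= w.last_episode:
                return w.factor
        return 1.0

    def to_dict(self) -> dict:
        def enc(o):
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if isinstance(o, np.ndarray):
                return o.tolist()
            if hasattr(o, "__dataclass_fields__"):
                return {k: enc(getattr(o, k)) for k in o.__dataclass_fields__}
            if isinstance(o, (list, tuple)):
                return [enc(v) for v in o]
            if isinstance(o, dict):
                return {k: enc(v) for k, v in o.items()}
            return o

        return enc(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)


def default_plasticity(rule: str) -> PlasticityParams:
    """Grid-searched parameter rows for each rule family."""
    if rule in ("cwc", "rate-cwc"):
        return PlasticityParams(eta_da=1e-4, eta_5ht=1e-4, rda_amp=1.0, r5ht_amp=1.0)
    return PlasticityParams(eta_da=0.01, eta_5ht=0.01)


def default_window_amplitudes(rule: str) -> tuple[float, float]:
    if rule in ("cwc", "rate-cwc"):
        return DA_WINDOW_CWC.amplitude, HT_WINDOW_CWC.amplitude
    return DA_WINDOW_SWC.amplitude, HT_WINDOW_SWC.amplitude


@dataclass
class EpisodeRecord:
    """Outcome of one episode."""

    episode: int
    outcome: str  # "none" | "reward" | "punishment"
    latency_s: float
    final_position: tuple[float, float]
    trajectory: np.ndarray | None = None
    weights_after: np.ndarray | None = None


@dataclass
class RunSummary:
    """Aggregate of a batch of simulations."""

    config: RunConfig
    success_fraction: np.ndarray      # per episode, over simulations
    punishment_fraction: np.ndarray
    cumulative_success: np.ndarray    # mean cumulative successes per episode
    latencies: list[list[float]]      # latencies of rewarded sims per episode
    first_reward_episode: np.ndarray  # per simulation; 0 = never rewarded
    final_weights: np.ndarray         # (M, n_action, n_place)
    records: list[list[EpisodeRecord]] | None = None


class SimulationIntegrityError(RuntimeError):
    """Raised when the dynamics produce non-finite state."""


def _episode_seed(master: int, sim: int, episode: int) -> int:
    return int(np.random.SeedSequence([master, sim, episode]).generate_state(1)[0] & 0x7FFFFFFF)


def _eligibility_tables(config: RunConfig, max_steps: int):
    d = np.arange(max_steps + 1) * config.dt
    dec_da = np.exp(-d / (config.tau_e_da_s * 1e3))
    dec_5 = np.exp(-d / (config.tau_e_5ht_s * 1e3))
    int_5 = config.tau_e_5ht_s * (1.0 - dec_5)
    return dec_da, dec_5, int_5


def _zone_arrays(zones):
    zx = np.array([z.center[0] for z in zones], dtype=float)
    zy = np.array([z.center[1] for z in zones], dtype=float)
    zr2 = np.array([(z.radius + 1e-12) ** 2 for z in zones], dtype=float)  # closed disc
    zv = np.array(
        [_engine.REWARD if z.valence == "reward" else _engine.PUNISH for z in zones],
        dtype=np.int64,
    )
    return zx, zy, zr2, zv


def finalize_update(
    config: RunConfig,
    outcome: str,
    gamma_da: np.ndarray,
    gamma_5ht: np.ndarray,
    int_5ht: np.ndarray,
    fiveht_factor: float,
) -> np.ndarray:
    """Convert the episode's proto-weight statistics into a weight update.

    SWC family: the DA proto-weight is read 300 ms after the reward (decaying
    through the consummatory delay; no new pairings accrue because place
    cells are deactivated at the outcome); the 5-HT proto-weight is read at
    episode end with sign -1.  The online variant replaces the end-of-episode
    5-HT readout by the time integral scaled by eta_5ht/Tmax.

    CWC family: integral of dw/dt = eta*(R_DA*Gamma_DA - R_5HT*Gamma_5HT)
    with the tonic/phasic step responses; the post-outcome dopamine phase
    integrates the decaying trace analytically over T_DA = 1 s.

    In the reversal task the outcomes are mutually exclusive, so both rules
    act sequentially: reward -> pure DA LTP, punishment -> pure 5-HT LTD,
    neutral episode -> no update.
    """
    p = config.plasticity
    t_max_s = config.protocol.t_max
    in_water = config.protocol.task == "mwm"  # tonic aversion when unrewarded
    swc_like = config.rule in ("swc", "swc-online", "rate-swc")

    da_delay = np.exp(-SWC_READOUT_DELAY_S / config.tau_e_da_s)
    # CWC integrals run on the network's millisecond time base (the default
    # rates assume per-ms pacing): phase factors are int_0^T_DA e^(-t/tau_e) dt in ms.
    da_phase = 1e3 * config.tau_e_da_s * (1.0 - np.exp(-T_DA_S / config.tau_e_da_s))
    ht_phase = 1e3 * config.tau_e_5ht_s * (1.0 - np.exp(-T_DA_S / config.tau_e_5ht_s))

    if swc_like:
        if outcome == "reward":
            return p.eta_da * gamma_da * da_delay
        if outcome == "none" and not in_water:
            return np.zeros_like(gamma_da)
        # aversive episode: MWM failure or reversal punishment
        if config.rule == "swc-online":
            return -(p.eta_5ht / t_max_s) * fiveht_factor * int_5ht
        return -p.eta_5ht * fiveht_factor * gamma_5ht

    # CWC family
    if in_water:
        dw = -p.eta_da * p.r5ht_amp * fiveht_factor * int_5ht * 1e3
        if outcome == "reward":
            dw = dw + p.eta_da * p.rda_amp * gamma_da * da_phase
        return dw
    # open-field reversal: sequential degeneration of the competition
    if outcome == "reward":
        return p.eta_da * p.rda_amp * gamma_da * da_phase
    if outcome == "punishment":
        return -p.eta_da * p.r5ht_amp * fiveht_factor * gamma_5ht * ht_phase
    return np.zeros_like(gamma_da)


def run_episode(
    config: RunConfig,
    weights: np.ndarray,
    episode_index: int,
    seed: int,
    start: np.ndarray | None = None,
    record_debug: bool = False,
):
    """Run one episode; returns (EpisodeRecord, updated weights[, debug]).

    ``episode_index`` is 1-based and selects the protocol phase and the
    optogenetic factor.  Weights are updated by the configured rule and
    clipped to the configured bounds; all activity state is implicitly
    reset (each episode starts from silence).
    """
    proto = config.protocol
    grid = build_place_grid(proto.arena.side, config.sigma, config.peak_rate)
    w_lat = lateral_weights(config.lateral)
    mem = config.membrane
    rf = config.rate_filter
    max_steps = int(round(proto.t_max * 1000.0 / config.dt))
    dt_move_steps = int(round(config.dt_move / config.dt))
    dec_da, dec_5, int_5 = _eligibility_tables(config, max_steps)
    zones = proto.zones(episode_index)
    zx, zy, zr2, zv = _zone_arrays(zones)
    if start is None:
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 977, episode_index, seed])
        )
        start = proto.draw_start(rng, episode_index)

    out = _engine.run_episode_kernel(
        seed,
        config.dt,
        weights,
        w_lat,
        grid.centers,
        config.sigma,
        config.peak_rate * 1e-3,
        mem.tau_m, mem.tau_s, mem.chi, mem.eps0, mem.theta, mem.delta_u,
        mem.lambda0 * 1e-3,
        rf.tau_gamma, rf.nu_gamma,
        config.lateral.action_vectors,
        config.tau_stdp, config.a_da, config.a_5ht,
        dec_da, dec_5, int_5,
        max_steps,
        dt_move_steps,
        proto.arena.half_side, proto.arena.bounce_distance,
        zx, zy, zr2, zv,
        float(start[0]), float(start[1]),
        1 if config.rule.startswith("rate-") else 0,
        config.tau_e_da_s * 1e3, config.tau_e_5ht_s * 1e3,
        config.record_trajectories or record_debug,
        record_debug,
    )
    (code, t_end, g_da, g_5, acc5, traj, ok, dbg_p, dbg_a, dbg_u) = out
    if not ok:
        raise SimulationIntegrityError(
            f"non-finite state in episode {episode_index} (seed {seed}); "
            f"weights range [{weights.min()}, {weights.max()}]"
        )
    outcome = _OUTCOME_NAME[code]
    factor = config.fivehT_factor(episode_index)
    dw = finalize_update(config, outcome, g_da, g_5, acc5, factor)
    new_w = clip_weights(weights + dw, config.plasticity)
    rec = EpisodeRecord(
        episode=episode_index,
        outcome=outcome,
        latency_s=t_end * config.dt * 1e-3,
        final_position=(float(traj[-1, 0]), float(traj[-1, 1])),
        trajectory=traj if config.record_trajectories else None,
    )
    if record_debug:
        return rec, new_w, {"place": dbg_p, "action": dbg_a, "u": dbg_u, "dw": dw,
                            "gamma_da": g_da, "gamma_5ht": g_5, "int_5ht": acc5}
    return rec, new_w


def run_probe(
    config: RunConfig, weights: np.ndarray, seed: int
) -> np.ndarray:
    """Spatial-memory probe episode: zones disabled, learning frozen.

    Runs a full-Tmax episode from the protocol's start position with the
    current weights and returns the trajectory (samples at dt_move).  The
    median distance of these samples to the platform center is the probe's
    memory readout (see metrics.distance_stats).
    """
    proto = replace(
        config.protocol,
        zones_by_phase=(((1, 1_000_000_000), ()),),
    )
    cfg = replace(
        config,
        protocol=proto,
        plasticity=replace(config.plasticity, eta_da=0.0, eta_5ht=0.0),
        record_trajectories=True,
    )
    rec, _ = run_episode(cfg, weights, 1, seed)
    return rec.trajectory


def run_simulation(config: RunConfig, sim_index: int = 0) -> list[EpisodeRecord]:
    """Run all episodes of one simulation with persistent weights."""
    proto = config.protocol
    n_p = build_place_grid(proto.arena.side, config.sigma, config.peak_rate).n_cells
    w = np.full((config.lateral.n_action, n_p), config.w_init)
    records: list[EpisodeRecord] = []
    rewarded = False
    for ep in range(1, proto.n_episodes + 1):
        seed = _episode_seed(config.seed, sim_index, ep)
        rec, w = run_episode(config, w, ep, seed)
        if ep in config.snapshot_episodes:
            rec.weights_after = w.copy()
        records.append(rec)
        if rec.outcome == "reward":
            rewarded = True
        if config.stop_after_first_reward and rewarded:
            break
    records[-1].weights_after = w.copy()
    return records


def summarize(config: RunConfig, all_records: list[list[EpisodeRecord]]) -> RunSummary:
    """Aggregate per-simulation records into learning curves."""
    m = len(all_records)
    n_ep = config.protocol.n_episodes
    succ = np.zeros(n_ep)
    pun = np.zeros(n_ep)
    n_at = np.zeros(n_ep)
    lat: list[list[float]] = [[] for _ in range(n_ep)]
    first = np.zeros(m, dtype=int)
    final_w = np.stack([recs[-1].weights_after for recs in all_records])
    for s, recs in enumerate(all_records):
        for rec in recs:
            e = rec.episode - 1
            n_at[e] += 1
            if rec.outcome == "reward":
                succ[e] += 1
                lat[e].append(rec.latency_s)
                if first[s] == 0:
                    first[s] = rec.episode
            elif rec.outcome == "punishment":
                pun[e] += 1
    n_at = np.maximum(n_at, 1)
    succ_f = succ / n_at
    pun_f = pun / n_at
    return RunSummary(
        config=config,
        success_fraction=succ_f,
        punishment_fraction=pun_f,
        cumulative_success=np.cumsum(succ) / m,
        latencies=lat,
        first_reward_episode=first,
        final_weights=final_w,
        records=all_records,
    )


def run_batch(config: RunConfig, progress: bool = False) -> RunSummary:
    """Run M independent simulations (derived seeds) and aggregate."""
    if config.n_simulations < 1:
        raise ValueError("n_simulations must be >= 1")
    sims = range(config.n_simulations)
    if progress:
        from tqdm import tqdm

        sims = tqdm(sims, desc=f"{config.rule}/{config.protocol.task}")
    all_records = [run_simulation(config, s) for s in sims]
    return summarize(config, all_records)


def grid_search(
    base: RunConfig,
    param_grid: dict[str, list],
    m_small: int = 20,
    criterion: str = "final_success",
):
    """Rank configurations on a small batch by final-episode success fraction.

    ``param_grid`` maps RunConfig or PlasticityParams field names to value
    lists.  Ties break toward the lexicographically smaller parameter tuple.
    Deterministic given ``base.seed``.
    """
    if not param_grid or any(len(v) == 0 for v in param_grid.values()):
        raise ValueError("param_grid must be non-empty")
    if criterion != "final_success":
        raise ValueError(f"unknown criterion {criterion!r}")
    names = sorted(param_grid)
    results = []
    for values in itertools.product(*(param_grid[n] for n in names)):
        cfg = base
        pl = base.plasticity
        pl_updates = {n: v for n, v in zip(names, values) if hasattr(pl, n)}
        cfg_updates = {n: v for n, v in zip(names, values) if n in cfg.__dataclass_fields__}
        unknown = set(names) - set(pl_updates) - set(cfg_updates)
        if unknown:
            raise ValueError(f"unknown grid parameters: {sorted(unknown)}")
        if pl_updates:
            pl = replace(pl, **pl_updates)
        cfg = replace(cfg, **cfg_updates, plasticity=pl, n_simulations=m_small)
        summary = run_batch(cfg)
        results.append((values, float(summary.success_fraction[-1]), cfg))
    results.sort(key=lambda r: (-r[1], r[0]))
    return [
        {"params": dict(zip(names, vals)), "final_success": score, "config": cfg}
        for vals, score, cfg in results
    ]
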