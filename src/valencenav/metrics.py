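"""Behavioral and synaptic metrics.

Jensen-Shannon divergence between first-reward distributions, coefficient of
variation of per-place-cell weight vectors, occupancy histograms and
fold-change maps, quadrant dwell times, distance statistics, and the
two-sample comparison used for condition contrasts.  All divergences use
base-2 logarithms (bits).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .arena import Arena

__all__ = [
    "DiscreteDistribution",
    "OccupancyMap",
    "WeightDispersion",
    "kl_divergence",
    "jsd",
    "first_reward_distribution",
    "coefficient_of_variation",
    "occupancy_map",
    "fold_change_map",
    "quadrant_times",
    "distance_stats",
    "compare_conditions",
]


@dataclass(frozen=True)
class DiscreteDistribution:
    """Probability mass function over labelled bins."""

    labels: tuple
    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if np.any(p < 0):
            raise ValueError("probabilities must be non-negative")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {p.sum()}, not 1")
        object.__setattr__(self, "probs", p)


@dataclass(frozen=True)
class OccupancyMap:
    """Episode-normalized 2D visit-probability grid."""

    grid: np.ndarray  # (bins, bins), sums to 1
    bins_per_side: int
    arena: Arena


@dataclass(frozen=True)
class WeightDispersion:
    """Coefficient of variation of outgoing weights per place cell."""

    cv: np.ndarray  # per place cell
    episode: int | None = None


def _check_shared(p: DiscreteDistribution, q: DiscreteDistribution) -> None:
    if p.labels != q.labels:
        raise ValueError("distributions must share bin labels")


def kl_divergence(p: DiscreteDistribution, q: DiscreteDistribution) -> float:
    """Kullback-Leibler divergence D_KL(P || Q) in bits, with 0*log(0/.) = 0."""
    _check_shared(p, q)
    pv, qv = p.probs, q.probs
    mask = pv > 0
    if np.any(qv[mask] <= 0):
        raise ValueError("Q must be positive wherever P is")
    return float(np.sum(pv[mask] * np.log2(pv[mask] / qv[mask])))


def jsd(p: DiscreteDistribution, q: DiscreteDistribution) -> float:
    """Jensen-Shannon divergence in bits: symmetric, bounded in [0, 1]."""
    _check_shared(p, q)
    m = DiscreteDistribution(p.labels, 0.5 * (p.probs + q.probs))
    return 0.5 * kl_divergence(p, m) + 0.5 * kl_divergence(q, m)


def first_reward_distribution(
    first_reward_episodes: np.ndarray,
    n_episodes: int,
    include_never: bool = True,
) -> DiscreteDistribution:
    """Empirical distribution of each simulation's first rewarded episode.

    ``first_reward_episodes`` holds the 1-based episode index of the first
    reward per simulation, 0 for simulations never rewarded; support is one
    bin per episode plus (optionally) a terminal "never" bin so that two
    conditions always share labels.
    """
    fr = np.asarray(first_reward_episodes, dtype=int)
    if fr.size == 0:
        raise ValueError("need at least one simulation")
    if not include_never and np.all(fr == 0):
        raise ValueError("no simulation was ever rewarded")
    labels = list(range(1, n_episodes + 1))
    counts = [np.sum(fr == e) for e in labels]
    if include_never:
        labels.append("never")
        counts.append(np.sum(fr == 0))
    counts = np.asarray(counts, dtype=float)
    return DiscreteDistribution(tuple(labels), counts / counts.sum())


def coefficient_of_variation(weights: np.ndarray, episode: int | None = None) -> WeightDispersion:
    """Per-place-cell CV of outgoing weights, sample (n-1) convention.

    ``weights`` is (n_action, n_place) or (M, n_action, n_place); with a
    batch axis the CV is averaged across simulations.
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim == 2:
        w = w[None]
    mean = w.mean(axis=1)
    if np.any(mean <= 0):
        raise ValueError("mean weight must be positive")
    sd = w.std(axis=1, ddof=1)
    return WeightDispersion(cv=(sd / mean).mean(axis=0), episode=episode)


def occupancy_map(
    trajectories: list[np.ndarray],
    bins_per_side: int = 50,
    arena: Arena | None = None,
) -> OccupancyMap:
    """Average per-episode position histogram, normalized to sum 1.

    Each trajectory is binned on a ``bins_per_side``-square grid, normalized
    per episode, then averaged across episodes/simulations.
    """
    arena = arena or Arena()
    h = arena.half_side
    edges = np.linspace(-h, h, bins_per_side + 1)
    acc = np.zeros((bins_per_side, bins_per_side))
    n = 0
    for traj in trajectories:
        traj = np.asarray(traj, dtype=float)
        if len(traj) == 0:
            continue
        hist, _, _ = np.histogram2d(traj[:, 0], traj[:, 1], bins=[edges, edges])
        acc += hist / hist.sum()
        n += 1
    if n == 0:
        raise ValueError("no non-empty trajectories")
    return OccupancyMap(grid=acc / n, bins_per_side=bins_per_side, arena=arena)


def fold_change_map(
    map_a: OccupancyMap, map_b: OccupancyMap, pseudocount: float | None = None
) -> np.ndarray:
    """Elementwise occupancy ratio A/B with a pseudocount guard.

    The default pseudocount is one visit-equivalent per map (1/bins^2),
    added to every bin of both maps before the ratio.
    """
    if map_a.bins_per_side != map_b.bins_per_side:
        raise ValueError("occupancy maps must share the same grid")
    if pseudocount is None:
        pseudocount = 1.0 / map_a.bins_per_side**2
    return (map_a.grid + pseudocount) / (map_b.grid + pseudocount)


def quadrant_times(
    trajectories: list[np.ndarray],
    dt_sample_s: float,
    target_center: tuple[float, float],
) -> dict[str, float]:
    """Mean dwell time (s) per arena quadrant across episodes.

    Quadrants are the four equal squares around the origin, labelled by the
    half-open convention x >= 0 / y >= 0; ``target`` marks the quadrant
    containing the reward zone center.  The four times sum to the mean
    episode duration.
    """
    totals = np.zeros(4)
    n = 0
    for traj in trajectories:
        traj = np.asarray(traj, dtype=float)
        if len(traj) == 0:
            continue
        qx = (traj[:, 0] >= 0).astype(int)
        qy = (traj[:, 1] >= 0).astype(int)
        q = 2 * qy + qx  # 0:SW 1:SE 2:NW 3:NE
        totals += np.bincount(q, minlength=4) * dt_sample_s
        n += 1
    if n == 0:
        raise ValueError("no non-empty trajectories")
    totals /= n
    target_q = 2 * int(target_center[1] >= 0) + int(target_center[0] >= 0)
    names = ["SW", "SE", "NW", "NE"]
    out = {names[i]: float(totals[i]) for i in range(4)}
    out["target"] = float(totals[target_q])
    out["target_quadrant"] = names[target_q]
    return out


def distance_stats(trajectory: np.ndarray, reference: tuple[float, float]) -> float:
    """Median Euclidean distance of trajectory samples to a reference point."""
    traj = np.asarray(trajectory, dtype=float)
    if traj.size == 0:
        raise ValueError("empty trajectory")
    d = np.hypot(traj[:, 0] - reference[0], traj[:, 1] - reference[1])
    return float(np.median(d))


def compare_conditions(samples_a, samples_b) -> dict[str, float]:
    """Two-sample pooled-variance t test with the mean difference as effect.

    Returns mean difference (a - b), t statistic and two-tailed p value.
    """
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two samples per condition")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0 and a.mean() == b.mean():
        return {"mean_diff": 0.0, "t": 0.0, "p": 1.0}
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return {"mean_diff": float(a.mean() - b.mean()), "t": float(t), "p": float(p)}
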