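"""Arena geometry, agent kinematics and task protocols.

The agent moves in the square S = [-2,2] x [-2,2] (a.u.).  A move that would
leave S is replaced by a small "bounce": a displacement of d0 along the
inward boundary normal, which keeps the position inside S.  Task protocols
describe where reward/punishment zones sit per episode (Morris water maze,
or reversal learning in which the two zones swap at mid-run).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Arena",
    "Zone",
    "TaskProtocol",
    "step_position",
    "check_outcome",
    "make_protocol",
]


@dataclass(frozen=True)
class Arena:
    """Square arena with a bounce boundary condition."""

    half_side: float = 2.0
    bounce_distance: float = 0.01

    @property
    def side(self) -> float:
        return 2.0 * self.half_side


@dataclass(frozen=True)
class Zone:
    """Circular outcome zone (closed disc)."""

    center: tuple[float, float]
    radius: float
    valence: str  # "reward" | "punishment"

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("zone radius must be positive")
        if self.valence not in ("reward", "punishment"):
            raise ValueError(f"unknown valence {self.valence!r}")

    def contains(self, x: np.ndarray) -> bool:
        # closed disc, with an fp-safe margin so exact-boundary points count
        x = np.asarray(x, dtype=float)
        return float(np.hypot(*(x - np.asarray(self.center)))) <= self.radius + 1e-12


def _validate_zones(zones: list[Zone], arena: Arena) -> None:
    for z in zones:
        if np.max(np.abs(z.center)) + z.radius > arena.half_side + 1e-12:
            raise ValueError(f"zone {z} extends outside the arena")
    for i, a in enumerate(zones):
        for b in zones[i + 1 :]:
            d = np.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
            if d < a.radius + b.radius:
                raise ValueError("overlapping outcome zones are not allowed")


@dataclass(frozen=True)
class TaskProtocol:
    """Episode structure of a navigation task.

    zones_by_phase maps a (first_episode, last_episode) inclusive 1-based
    range to the zones active there.  For the reversal task, the second phase
    swaps the reward and punisher centers with radii unchanged.
    """

    task: str
    zones_by_phase: tuple[tuple[tuple[int, int], tuple[Zone, ...]], ...]
    t_max: float = 15.0  # s
    start_position: tuple[float, float] | str = (0.0, 0.0)
    episodes_per_trial: int = 40
    trials: int = 1
    arena: Arena = field(default_factory=Arena)

    def __post_init__(self) -> None:
        for _, zones in self.zones_by_phase:
            _validate_zones(list(zones), self.arena)

    @property
    def n_episodes(self) -> int:
        return self.episodes_per_trial * self.trials

    def zones(self, episode: int) -> tuple[Zone, ...]:
        """Active zones for a 1-based episode index."""
        for (lo, hi), zones in self.zones_by_phase:
            if lo <= episode <= hi:
                return zones
        raise ValueError(f"episode {episode} outside every protocol phase")

    def draw_start(self, rng: np.random.Generator, episode: int = 1) -> np.ndarray:
        if self.start_position == "random":
            zones = self.zones(episode)
            h = self.arena.half_side
            while True:
                x = rng.uniform(-h, h, size=2)
                if not any(z.contains(x) for z in zones):
                    return x
        return np.asarray(self.start_position, dtype=float)


def step_position(x: np.ndarray, a: np.ndarray, arena: Arena) -> np.ndarray:
    """Apply one movement step with the bounce boundary condition.

    If x + a stays inside S the move is taken; otherwise the agent is
    displaced by d0 along the inward normal of every violated wall (their sum
    at a corner).
    """
    x = np.asarray(x, dtype=float)
    a = np.asarray(a, dtype=float)
    cand = x + a
    h = arena.half_side
    if np.all(np.abs(cand) <= h):
        return cand
    normal = np.zeros(2)
    for d in range(2):
        if cand[d] > h:
            normal[d] = -1.0
        elif cand[d] < -h:
            normal[d] = 1.0
    out = x + arena.bounce_distance * normal
    return np.clip(out, -h, h)


def check_outcome(x: np.ndarray, zones: tuple[Zone, ...]) -> str:
    """Return 'reward'/'punishment' if x lies in a zone's closed disc, else 'none'."""
    for z in zones:
        if z.contains(x):
            return z.valence
    return "none"


_REWARD_MWM = (1.5, 1.5)
_PUNISH_REV = (-1.5, -1.5)
_ZONE_RADIUS = 0.3


def make_protocol(task: str, **overrides) -> TaskProtocol:
    """Build a standard task protocol.

    ``mwm``: one hidden reward platform at (1.5, 1.5), radius 0.3, start at
    the center, Tmax = 15 s, 40 episodes.
    ``reversal``: reward at (1.5, 1.5) and punisher at (-1.5, -1.5) for
    episodes 1-20, centers swapped for 21-40.
    """
    if task == "mwm":
        episodes = int(overrides.pop("episodes_per_trial", 40))
        trials = int(overrides.pop("trials", 1))
        n = episodes * trials
        phases = (
            (
                (1, n),
                (Zone(_REWARD_MWM, _ZONE_RADIUS, "reward"),),
            ),
        )
        proto = TaskProtocol(
            task="mwm",
            zones_by_phase=phases,
            episodes_per_trial=episodes,
            trials=trials,
        )
    elif task == "reversal":
        episodes = int(overrides.pop("episodes_per_trial", 40))
        trials = int(overrides.pop("trials", 1))
        if episodes % 2:
            raise ValueError("reversal task needs an even episode count")
        half = episodes // 2
        phases = (
            (
                (1, half),
                (
                    Zone(_REWARD_MWM, _ZONE_RADIUS, "reward"),
                    Zone(_PUNISH_REV, _ZONE_RADIUS, "punishment"),
                ),
            ),
            (
                (half + 1, episodes * trials),
                (
                    Zone(_PUNISH_REV, _ZONE_RADIUS, "reward"),
                    Zone(_REWARD_MWM, _ZONE_RADIUS, "punishment"),
                ),
            ),
        )
        proto = TaskProtocol(
            task="reversal",
            zones_by_phase=phases,
            episodes_per_trial=episodes,
            trials=trials,
        )
    else:
        raise ValueError(f"unknown task {task!r}")
    if overrides:
        proto = replace(proto, **overrides)
    return proto
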