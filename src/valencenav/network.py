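"""Place-cell input code and SRM0 action-neuron layer.

The network is a single feed-forward layer: a square grid of Gaussian place
cells encodes the agent's position through inhomogeneous Poisson spiking, and
a ring of direction-tuned action neurons (zero-order spike response model,
SRM0) reads that code out.  A fixed "N-winner-takes-all" lateral connectivity
among the action neurons sharpens a single activity bump whose population
vector is the movement command.

Only feed-forward weights are plastic; everything in this module is fixed
structure and per-step dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PlaceCellGrid",
    "MembraneParams",
    "LateralConnectivity",
    "SpikeState",
    "RateFilter",
    "build_place_grid",
    "place_cell_rates",
    "sample_poisson",
    "epsp_kernel",
    "membrane_potential",
    "action_rate",
    "lateral_weights",
    "filtered_rate",
    "population_action",
]

NEVER = -np.inf  # sentinel for "no postsynaptic spike yet"


@dataclass(frozen=True)
class PlaceCellGrid:
    """Regular square grid of Gaussian place fields.

    Attributes
    ----------
    centers : (n, 2) array of field centers (a.u.).
    sigma : tuning width, also the grid spacing (a.u.).
    peak_rate : firing rate at the field center (Hz).
    """

    centers: np.ndarray
    sigma: float
    peak_rate: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.peak_rate <= 0:
            raise ValueError("peak_rate must be positive")

    @property
    def n_cells(self) -> int:
        return len(self.centers)


@dataclass(frozen=True)
class MembraneParams:
    """SRM0 membrane parameters.

    tau_m/tau_s are the decay/rise constants of the EPSP kernel (ms), chi the
    (negative) refractory scale (mV), eps0 the EPSP charge scale (mV*ms),
    theta the soft spike threshold (mV), delta_u the width of the stochastic
    emission window (mV) and lambda0 the firing rate at threshold (Hz).
    """

    tau_m: float = 20.0
    tau_s: float = 5.0
    chi: float = -5.0
    eps0: float = 20.0
    theta: float = 16.0
    delta_u: float = 2.0
    lambda0: float = 60.0

    def __post_init__(self) -> None:
        if not (self.tau_m > self.tau_s > 0):
            raise ValueError("require tau_m > tau_s > 0")
        if self.lambda0 <= 0 or self.delta_u <= 0:
            raise ValueError("lambda0 and delta_u must be positive")
        if self.chi > 0:
            raise ValueError("chi must be <= 0 (refractory hyperpolarization)")


@dataclass(frozen=True)
class LateralConnectivity:
    """Fixed ring connectivity of the action layer.

    Neuron k prefers angle theta_k = 2*pi*k/n_action; the weight matrix
    combines uniform inhibition w_minus/N with excitation w_plus spread over
    similar angles (sharpness zeta).  a0 scales each neuron's action vector.
    """

    n_action: int = 40
    w_minus: float = -300.0
    w_plus: float = 100.0
    zeta: float = 20.0
    a0: float = 0.08

    def __post_init__(self) -> None:
        if self.n_action < 2:
            raise ValueError("need at least two action neurons")

    @property
    def angles(self) -> np.ndarray:
        k = np.arange(1, self.n_action + 1)
        return 2.0 * np.pi * k / self.n_action

    @property
    def action_vectors(self) -> np.ndarray:
        """(N, 2) array of preferred-direction vectors a_k = a0*(sin, cos)."""
        th = self.angles
        return self.a0 * np.column_stack([np.sin(th), np.cos(th)])


@dataclass
class SpikeState:
    """Spike history of one network instant.

    Times are in ms and strictly increasing within each list.  last_post_spike
    holds t-hat_j per action neuron (NEVER if the neuron has not spiked).
    """

    place_spike_times: list[np.ndarray]
    action_spike_times: list[np.ndarray]
    last_post_spike: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.last_post_spike is None:
            self.last_post_spike = np.array(
                [t[-1] if len(t) else NEVER for t in self.action_spike_times]
            )


@dataclass(frozen=True)
class RateFilter:
    """Double-exponential causal kernel used to read out instantaneous rate.

    gamma(t) = (exp(-t/tau_gamma) - exp(-t/nu_gamma)) / (tau_gamma - nu_gamma)
    for t >= 0; its integral is exactly 1, so the filtered spike train is a
    rate in spikes/ms when t is in ms.
    """

    tau_gamma: float = 50.0
    nu_gamma: float = 20.0

    def __post_init__(self) -> None:
        if not (self.tau_gamma > self.nu_gamma > 0):
            raise ValueError("require tau_gamma > nu_gamma > 0")


def build_place_grid(
    arena_side: float, sigma: float, peak_rate: float = 400.0
) -> PlaceCellGrid:
    """Build a regular grid of place-cell centers covering the arena square.

    Centers are spaced ``sigma`` apart, span ``[-arena_side/2, arena_side/2]``
    on each axis and include the boundary rows, giving
    ``(arena_side/sigma + 1)**2`` cells.  The side must be commensurate with
    the spacing.
    """
    n_per_side_f = arena_side / sigma + 1.0
    n_per_side = int(round(n_per_side_f))
    if abs(n_per_side_f - n_per_side) > 1e-9:
        raise ValueError(
            f"arena_side/sigma + 1 = {n_per_side_f} is not an integer; "
            "grid spacing must divide the arena side"
        )
    half = arena_side / 2.0
    axis = -half + sigma * np.arange(n_per_side)
    xx, yy = np.meshgrid(axis, axis)
    centers = np.column_stack([xx.ravel(), yy.ravel()])
    return PlaceCellGrid(centers=centers, sigma=sigma, peak_rate=peak_rate)


def place_cell_rates(x: np.ndarray, grid: PlaceCellGrid) -> np.ndarray:
    """Gaussian position tuning: rate_i = peak * exp(-||x - x_i||^2 / sigma^2)."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("position must be finite")
    d2 = np.sum((grid.centers - x) ** 2, axis=1)
    return grid.peak_rate * np.exp(-d2 / grid.sigma**2)


def sample_poisson(rate_hz: float, dt_ms: float, rng: np.random.Generator) -> bool:
    """One Bernoulli thinning step of an inhomogeneous Poisson process.

    Spike probability is ``rate*dt``; the step must be fine enough that this
    stays below 1.
    """
    p = rate_hz * dt_ms * 1e-3
    if p >= 1.0:
        raise ValueError(f"rate*dt = {p} >= 1; decrease dt")
    return bool(rng.random() < p)


def epsp_kernel(t_ms, p: MembraneParams):
    """EPSP kernel eps(t) = eps0/(tau_m - tau_s) * (e^(-t/tau_m) - e^(-t/tau_s)).

    Causal: zero for t < 0.  Accepts scalars or arrays.
    """
    t = np.asarray(t_ms, dtype=float)
    out = np.where(
        t >= 0,
        p.eps0 / (p.tau_m - p.tau_s)
        * (np.exp(-np.clip(t, 0, None) / p.tau_m) - np.exp(-np.clip(t, 0, None) / p.tau_s)),
        0.0,
    )
    return out if out.ndim else float(out)


def membrane_potential(
    state: SpikeState,
    w_feed: np.ndarray,
    w_lat: np.ndarray,
    t: float,
    p: MembraneParams,
) -> np.ndarray:
    """SRM0 membrane potential of every action neuron at time t.

    u_j sums feed-forward and lateral EPSPs from presynaptic spikes that
    arrived after neuron j's own last spike t-hat_j, plus the refractory
    after-potential chi * exp((t-hat_j - t)/tau_m).  Resting potential is 0.
    """
    n_action = w_feed.shape[0]
    u = np.zeros(n_action)
    for j in range(n_action):
        t_hat = state.last_post_spike[j]
        for i, times in enumerate(state.place_spike_times):
            for tf in times:
                if tf > t_hat and tf <= t:
                    u[j] += w_feed[j, i] * epsp_kernel(t - tf, p)
        for k, times in enumerate(state.action_spike_times):
            if k == j:
                continue
            for tf in times:
                if tf > t_hat and tf <= t:
                    u[j] += w_lat[j, k] * epsp_kernel(t - tf, p)
        if np.isfinite(t_hat) and t >= t_hat:
            u[j] += p.chi * np.exp((t_hat - t) / p.tau_m)
    return u


def action_rate(u, p: MembraneParams):
    """Stochastic-emission rate lambda(u) = lambda0 * exp((u - theta)/delta_u) in Hz."""
    return p.lambda0 * np.exp((np.asarray(u, dtype=float) - p.theta) / p.delta_u)


def lateral_weights(c: LateralConnectivity) -> np.ndarray:
    """Fixed lateral weight matrix of the action ring.

    w_kk' = w_minus/N + w_plus * f(k,k') / sum_k'' f(k,k'') with
    f(k,k') = (1 - delta_kk') * exp(zeta * cos(theta_k - theta_k')): uniform
    inhibition plus excitation concentrated on neighbouring directions
    (maximal at k' = k +/- 1, zero self-excitation).
    """
    th = c.angles
    dtheta = th[:, None] - th[None, :]
    f = np.exp(c.zeta * np.cos(dtheta))
    np.fill_diagonal(f, 0.0)
    w = c.w_minus / c.n_action + c.w_plus * f / f.sum(axis=1, keepdims=True)
    return w


def filtered_rate(
    spike_times_ms: np.ndarray, t_ms, f: RateFilter
):
    """Instantaneous rate: the spike train convolved with the normalized kernel.

    Returns spikes/ms (multiply by 1000 for Hz).  gamma(0) = 0, so a spike
    contributes nothing at its own time and peaks later.
    """
    t = np.atleast_1d(np.asarray(t_ms, dtype=float))
    spikes = np.asarray(spike_times_ms, dtype=float)
    rho = np.zeros_like(t)
    denom = f.tau_gamma - f.nu_gamma
    for ts in spikes:
        lag = t - ts
        m = lag > 0
        rho[m] += (np.exp(-lag[m] / f.tau_gamma) - np.exp(-lag[m] / f.nu_gamma)) / denom
    return rho if np.ndim(t_ms) else float(rho[0])


def population_action(rho: np.ndarray, c: LateralConnectivity) -> np.ndarray:
    """Population-vector readout a = (1/N) * sum_k rho_k * a_k.

    rho is the vector of filtered rates; the result is the 2D movement
    command (a.u. per unit of the rate's time base).
    """
    rho = np.asarray(rho, dtype=float)
    return (rho @ c.action_vectors) / c.n_action
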