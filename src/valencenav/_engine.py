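"""Numba episode kernel.

Runs the coupled place-cell / action-neuron / movement dynamics for one
episode at dt = 1 ms and accumulates the sufficient statistics every
plasticity rule needs:

* ``gamma_da``  — DA proto-weight Gamma_DA(t_end) per synapse,
* ``gamma_5ht`` — 5-HT proto-weight Gamma_5HT(t_end) per synapse,
* ``int_5ht``   — integral of Gamma_5HT over the episode (seconds units),

so the (linear) SWC/CWC weight updates can be finalized outside the kernel.

Numerics
--------
EPSP sums, refractory terms, rate-filter states and STDP pre/post traces are
exact two-state exponential recursions updated every step.  The per-synapse
proto-weights are updated lazily (only when a pairing event touches a
synapse) with tabulated decay factors, which makes the per-step cost
independent of the synapse count.  SRM0 resets: a postsynaptic spike
zeroes that neuron's EPSP sums, so only presynaptic spikes after the last
postsynaptic spike contribute to the membrane potential.

Action-neuron spiking uses per-step Bernoulli thinning with probability
min(lambda(u)*dt, 1); the clamp only binds during pathological excursions
far above threshold.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# outcome codes
NONE, REWARD, PUNISH = 0, 1, -1


@njit(cache=True)
def _bounce(x, y, ax, ay, half, d0):
    """One movement step with the inward-normal bounce (returns new x, y)."""
    cx = x + ax
    cy = y + ay
    if -half <= cx <= half and -half <= cy <= half:
        return cx, cy
    nx = 0.0
    ny = 0.0
    if cx > half:
        nx = -1.0
    elif cx < -half:
        nx = 1.0
    if cy > half:
        ny = -1.0
    elif cy < -half:
        ny = 1.0
    ox = x + d0 * nx
    oy = y + d0 * ny
    if ox > half:
        ox = half
    elif ox < -half:
        ox = -half
    if oy > half:
        oy = half
    elif oy < -half:
        oy = -half
    return ox, oy


@njit(cache=True)
def run_episode_kernel(
    seed,
    dt,              # integration step (ms)
    w_feed,          # (Na, Np) feed-forward weights (read-only)
    w_lat,           # (Na, Na) lateral weights
    centers,         # (Np, 2)
    sigma,
    peak_rate_khz,
    tau_m, tau_s, chi, eps0, theta, delta_u, lambda0_khz,
    tau_g, nu_g,
    avec,            # (Na, 2) action vectors (a.u. per move step per unit rate)
    tau_stdp, a_da, a_5ht,
    dec_da,          # (max_steps+1,) exp(-d/tau_e_da_ms)
    dec_5,           # (max_steps+1,) exp(-d/tau_e_5ht_ms)
    int_5,           # (max_steps+1,) tau_e_5ht_s * (1 - dec_5)
    max_steps,
    dt_move,
    half_side, d0,
    zone_x, zone_y, zone_r2, zone_val,  # zone arrays; val: +1 reward, -1 punish
    x0, y0,
    rate_mode,       # 0: spike-pairing STDP, 1: rate-based (BCM-style) drive
    tau_e_da_ms, tau_e_5ht_ms,
    record_traj,
    record_debug,
):
    np.random.seed(seed)
    n_a = w_feed.shape[0]
    n_p = w_feed.shape[1]

    # per-step decay factors
    dm = np.exp(-dt / tau_m)
    ds = np.exp(-dt / tau_s)
    dg = np.exp(-dt / tau_g)
    dn = np.exp(-dt / nu_g)
    dstdp = np.exp(-dt / tau_stdp)
    ck = eps0 / (tau_m - tau_s)
    inv_rate_norm = 1.0 / (tau_g - nu_g)

    sm = np.zeros(n_a)      # EPSP slow component sums (feed + lateral)
    ss = np.zeros(n_a)      # EPSP fast component sums
    ref = np.zeros(n_a)     # refractory after-potential
    ag = np.zeros(n_a)      # rate-filter slow state
    bg = np.zeros(n_a)      # rate-filter fast state
    xpost = np.zeros(n_a)   # postsynaptic STDP trace
    xpre = np.zeros(n_p)    # presynaptic STDP trace
    spiked_now = np.zeros(n_p, dtype=np.uint8)
    post_spiked = np.zeros(n_a, dtype=np.uint8)

    g_da = np.zeros((n_a, n_p))
    g_5 = np.zeros((n_a, n_p))
    acc5 = np.zeros((n_a, n_p))
    ts_da = np.zeros((n_a, n_p), dtype=np.int64)
    ts_5 = np.zeros((n_a, n_p), dtype=np.int64)

    x = x0
    y = y0
    rates = np.empty(n_p)
    active = np.empty(n_p, dtype=np.int64)
    inv_s2 = 1.0 / (sigma * sigma)
    # place fields further than this are numerically silent (p < 1e-9/step)
    p_floor = 1e-9
    n_act = 0
    for i in range(n_p):
        dx = x - centers[i, 0]
        dy = y - centers[i, 1]
        rates[i] = peak_rate_khz * np.exp(-(dx * dx + dy * dy) * inv_s2)
        if rates[i] * dt >= p_floor:
            active[n_act] = i
            n_act += 1
    # below this potential the emission probability is under p_floor
    u_floor = theta + delta_u * np.log(p_floor / (lambda0_khz * dt))

    n_moves = max_steps // dt_move
    if record_traj:
        traj = np.empty((n_moves + 1, 2))
    else:
        traj = np.empty((1, 2))
    traj[0, 0] = x
    traj[0, 1] = y
    n_traj = 1

    if record_debug:
        dbg_place = np.empty((max_steps * 16, 2), dtype=np.int64)
        dbg_action = np.empty((max_steps * 8, 2), dtype=np.int64)
        dbg_u = np.empty((max_steps, n_a))
    else:
        dbg_place = np.empty((1, 2), dtype=np.int64)
        dbg_action = np.empty((1, 2), dtype=np.int64)
        dbg_u = np.empty((1, n_a))
    n_dbg_p = 0
    n_dbg_a = 0

    # eager rate-mode proto-weights (updated at the movement cadence)
    dec_mv_da = np.exp(-dt_move * dt / tau_e_da_ms)
    dec_mv_5 = np.exp(-dt_move * dt / tau_e_5ht_ms)
    int_mv_5 = (tau_e_5ht_ms * 1e-3) * (1.0 - dec_mv_5)

    outcome = NONE
    t_end = max_steps
    ok = True

    for t in range(max_steps):
        # --- exponential state decays -----------------------------------
        for j in range(n_a):
            sm[j] *= dm
            ss[j] *= ds
            ref[j] *= dm
            ag[j] *= dg
            bg[j] *= dn
            xpost[j] *= dstdp
        for i in range(n_p):
            xpre[i] *= dstdp

        # --- place-cell spikes ------------------------------------------
        for ia in range(n_act):
            i = active[ia]
            spiked_now[i] = 0
            if np.random.random() < rates[i] * dt:
                spiked_now[i] = 1
                xpre[i] += 1.0
                for j in range(n_a):
                    w = w_feed[j, i]
                    sm[j] += w
                    ss[j] += w
                if rate_mode == 0 and a_da > 0.0:
                    # acausal (post-before-pre) half of the symmetric DA window
                    for j in range(n_a):
                        if xpost[j] > 1e-12:
                            d = t - ts_da[j, i]
                            if d > 0:
                                g_da[j, i] *= dec_da[d]
                                ts_da[j, i] = t
                            g_da[j, i] += a_da * xpost[j]
                if record_debug and n_dbg_p < dbg_place.shape[0]:
                    dbg_place[n_dbg_p, 0] = t
                    dbg_place[n_dbg_p, 1] = i
                    n_dbg_p += 1

        # --- action-neuron sampling -------------------------------------
        n_post = 0
        for j in range(n_a):
            u = ck * (sm[j] - ss[j]) + ref[j]
            if record_debug:
                dbg_u[t, j] = u
            post_spiked[j] = 0
            if u < u_floor:
                continue
            lam = lambda0_khz * np.exp((u - theta) / delta_u) * dt
            if lam > 1.0:
                lam = 1.0
            if np.random.random() < lam:
                post_spiked[j] = 1
                n_post += 1

        if n_post > 0:
            for j in range(n_a):
                if post_spiked[j] == 0:
                    continue
                ag[j] += 1.0
                bg[j] += 1.0
                if rate_mode == 0:
                    # causal pairings against the presynaptic trace
                    for i in range(n_p):
                        xp = xpre[i]
                        if xp > 1e-12:
                            d = t - ts_da[j, i]
                            if d > 0:
                                g_da[j, i] *= dec_da[d]
                                ts_da[j, i] = t
                            g_da[j, i] += a_da * xp
                            x5 = xp
                            if spiked_now[i] == 1:
                                x5 -= 0.5  # W_5HT(0) = A/2
                            if x5 > 1e-12:
                                d = t - ts_5[j, i]
                                if d > 0:
                                    acc5[j, i] += g_5[j, i] * int_5[d]
                                    g_5[j, i] *= dec_5[d]
                                    ts_5[j, i] = t
                                g_5[j, i] += a_5ht * x5
                xpost[j] += 1.0
                # SRM0 reset: drop all presynaptic input before this spike
                sm[j] = 0.0
                ss[j] = 0.0
                ref[j] = chi
                if record_debug and n_dbg_a < dbg_action.shape[0]:
                    dbg_action[n_dbg_a, 0] = t
                    dbg_action[n_dbg_a, 1] = j
                    n_dbg_a += 1
            # lateral EPSPs from this step's spikes
            # (neurons that spiked this step start from a clean slate: their
            # reset discards arrivals at or before their own spike time)
            for k in range(n_a):
                if post_spiked[k] == 1:
                    for j in range(n_a):
                        if j != k and post_spiked[j] == 0:
                            w = w_lat[j, k]
                            sm[j] += w
                            ss[j] += w

        # --- movement every dt_move steps --------------------------------
        if (t + 1) % dt_move == 0:
            axv = 0.0
            ayv = 0.0
            for k in range(n_a):
                rho = (ag[k] - bg[k]) * inv_rate_norm  # spikes/ms
                axv += rho * avec[k, 0]
                ayv += rho * avec[k, 1]
            axv = axv / n_a * (dt_move * dt)
            ayv = ayv / n_a * (dt_move * dt)
            x, y = _bounce(x, y, axv, ayv, half_side, d0)
            if record_traj:
                traj[n_traj, 0] = x
                traj[n_traj, 1] = y
            n_traj += 1
            n_act = 0
            for i in range(n_p):
                dx = x - centers[i, 0]
                dy = y - centers[i, 1]
                rates[i] = peak_rate_khz * np.exp(-(dx * dx + dy * dy) * inv_s2)
                spiked_now[i] = 0
                if rates[i] * dt >= p_floor:
                    active[n_act] = i
                    n_act += 1

            if rate_mode == 1:
                for j in range(n_a):
                    rho = (ag[j] - bg[j]) * inv_rate_norm  # kHz
                    for i in range(n_p):
                        acc5[j, i] += g_5[j, i] * int_mv_5
                        g_da[j, i] = g_da[j, i] * dec_mv_da \
                            + a_da * tau_stdp * rho * rates[i] * dt_move * dt
                        g_5[j, i] = g_5[j, i] * dec_mv_5 \
                            + a_5ht * tau_stdp * rho * rates[i] * dt_move * dt

            for z in range(zone_x.shape[0]):
                dx = x - zone_x[z]
                dy = y - zone_y[z]
                if dx * dx + dy * dy <= zone_r2[z]:
                    outcome = zone_val[z]
                    break
            if outcome != NONE:
                t_end = t + 1
                break
            if not (np.isfinite(x) and np.isfinite(y)):
                ok = False
                t_end = t + 1
                break

    # --- bring every synapse to t_end -----------------------------------
    if rate_mode == 0:
        for j in range(n_a):
            for i in range(n_p):
                d = t_end - ts_da[j, i]
                if d > 0:
                    g_da[j, i] *= dec_da[d]
                d = t_end - ts_5[j, i]
                if d > 0:
                    acc5[j, i] += g_5[j, i] * int_5[d]
                    g_5[j, i] *= dec_5[d]
    for j in range(n_a):
        for i in range(n_p):
            if not (np.isfinite(g_da[j, i]) and np.isfinite(g_5[j, i])):
                ok = False

    return (
        outcome,
        t_end,
        g_da,
        g_5,
        acc5,
        traj[:n_traj],
        ok,
        dbg_place[:n_dbg_p],
        dbg_action[:n_dbg_a],
        dbg_u[: (t_end if record_debug else 0)],
    )
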