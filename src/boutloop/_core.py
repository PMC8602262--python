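"""Compiled inner loop of the closed-loop controller simulation.

The feedback controller and the virtual-reafference environment are advanced
together sample by sample; the loop is sequential by nature (the shown
grating at time t feeds the controller input at t + delay), so it is JIT
compiled.  All public entry points live in :mod:`boutloop.controller`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# condition kind codes
KIND_GAIN = 0
KIND_LAG = 1
KIND_DROP = 2

#: samples per 75 ms gain-drop segment on the 5 ms grid is supplied by callers.


@njit(cache=False)
def run_session(
    params_per_trial,  # (n_trials, 8): wf, wr, tau_s, thr, ws, wm, tau_m, wi
    cmd,               # (n,) command grating velocity, mm/s
    dt,                # sampling period, s
    delay_n,           # sensory delay, samples
    seg_n,             # gain-drop segment length, samples
    trial_of_sample,   # (n,) int64 trial index of each sample
    t_policy,          # (n_trials,) int8: 0 fixed condition, 1 pre-drawn per bout
    b_kind, b_gain, b_lagn, b_shunt, b_prof,   # pre-drawn per-bout condition arrays
    t_kind, t_gain, t_lagn, t_shunt, t_prof,   # per-trial fixed condition arrays
    stop_at_bout,      # terminate at onset of this bout serial (-1: never)
    swim_speed,
):
    n = cmd.size
    pad = 80  # longest finite lag (60 samples) + margin

    V_tr = np.zeros(n)
    M_tr = np.zeros(n)
    D_tr = np.zeros(n)
    b_tr = np.zeros(n, dtype=np.int8)
    shown = np.zeros(n)

    cap = n // 8 + 8
    onsets = np.full(cap, -1, dtype=np.int64)
    offsets = np.full(cap, -1, dtype=np.int64)
    bout_end = np.full(cap, n + pad, dtype=np.int64)
    bout_shunt = np.zeros(cap, dtype=np.int8)

    r_sched = np.zeros(n + pad)
    sched_bout = np.full(n + pad, -1, dtype=np.int64)

    V = 0.0
    M = 0.0
    bprev = 0
    nb = 0            # bouts started so far
    draw_i = 0        # pre-drawn conditions consumed so far
    cur = -1          # current bout serial
    cur_on = -1
    ck = KIND_GAIN
    cg = 1.0
    cl = 0
    cs = 0
    cp0 = cp1 = cp2 = cp3 = 1

    trial_prev = -1
    wf = wr = tau_s = thr = ws = wm = tau_m = wi = 0.0
    a_s = a_m = 0.0

    end_t = n
    for t in range(n):
        trial = trial_of_sample[t]
        if trial != trial_prev:
            wf = params_per_trial[trial, 0]
            wr = params_per_trial[trial, 1]
            tau_s = params_per_trial[trial, 2]
            thr = params_per_trial[trial, 3]
            ws = params_per_trial[trial, 4]
            wm = params_per_trial[trial, 5]
            tau_m = params_per_trial[trial, 6]
            wi = params_per_trial[trial, 7]
            a_s = np.exp(-dt / tau_s)
            a_m = np.exp(-dt / tau_m)
            trial_prev = trial

        u = shown[t - delay_n] if t >= delay_n else 0.0
        s_in = wf * u if u > 0.0 else wr * u
        V = V * a_s + s_in * (1.0 - a_s)
        if V < 0.0:
            V = 0.0
        elif V > 1.0:
            V = 1.0
        D = V + ws * bprev - wi * M
        if D < 0.0:
            D = 0.0
        b = 1 if D >= thr else 0
        M = M * a_m + wm * b * (1.0 - a_m)
        if M > 1.0:
            M = 1.0

        if b == 1 and bprev == 0:
            if nb == stop_at_bout:
                end_t = t
                V_tr[t] = V
                M_tr[t] = M
                D_tr[t] = D
                b_tr[t] = b
                if nb < cap:
                    onsets[nb] = t
                nb += 1
                break
            cur = nb
            if cur < cap:
                onsets[cur] = t
            nb += 1
            if t_policy[trial] == 1:
                ci = draw_i if draw_i < b_kind.size else b_kind.size - 1
                draw_i += 1
                ck = b_kind[ci]
                cg = b_gain[ci]
                cl = b_lagn[ci]
                cs = b_shunt[ci]
                cp0 = b_prof[ci, 0]
                cp1 = b_prof[ci, 1]
                cp2 = b_prof[ci, 2]
                cp3 = b_prof[ci, 3]
            else:
                ck = t_kind[trial]
                cg = t_gain[trial]
                cl = t_lagn[trial]
                cs = t_shunt[trial]
                cp0 = t_prof[trial, 0]
                cp1 = t_prof[trial, 1]
                cp2 = t_prof[trial, 2]
                cp3 = t_prof[trial, 3]
            if cur < cap:
                bout_shunt[cur] = cs
            cur_on = t
        elif b == 0 and bprev == 1:
            if cur < cap:
                offsets[cur] = t
                bout_end[cur] = t

        v = swim_speed * b
        r = 0.0
        if b == 1:
            if ck == KIND_GAIN:
                r = cg * v
            elif ck == KIND_DROP:
                si = (t - cur_on) // seg_n
                if si >= 4:
                    r = v
                elif si == 0:
                    r = v * cp0
                elif si == 1:
                    r = v * cp1
                elif si == 2:
                    r = v * cp2
                else:
                    r = v * cp3
            else:  # lag
                if cl >= 0:  # negative encodes infinite lag
                    r_sched[t + cl] += v
                    sched_bout[t + cl] = cur
        rs = r_sched[t]
        if rs != 0.0:
            sb = sched_bout[t]
            if sb < cap and bout_shunt[sb] == 1 and t >= bout_end[sb]:
                rs = 0.0
            r += rs
        shown[t] = cmd[t] - r

        V_tr[t] = V
        M_tr[t] = M
        D_tr[t] = D
        b_tr[t] = b
        bprev = b

    return V_tr, M_tr, D_tr, b_tr, shown, onsets, offsets, nb, end_t
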