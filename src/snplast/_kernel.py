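"""Numba-compiled inner loop of a single trial.

This is a fused, loop-level implementation of exactly the step sequence the
pure-NumPy reference (`simulate.run_trial` with ``engine="reference"``)
performs: place spikes -> membrane update -> action spikes -> rate estimate
-> action selection -> position update -> plasticity -> well check.  It is a
pure function of pre-drawn uniforms (one row of 161 per step: 121 place,
40 action draws), so the two paths consume the same random stream and can be
compared directly in tests.

The eligibility trace is stored rebased (true value = elig * g, with the
scalar g carrying the accumulated per-step decay) so that the dense 121x40
decay multiply is avoided; additions are applied as mass/g on the sparse
spike events only.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: chunk_step return status
RUNNING, REWARD, WRONG = 0, 1, 2


@njit(cache=True)
def run_chunk(
    u01,            # (chunk, 161) uniforms
    t0,             # ms, simulation time at entry
    x,              # (2,) position, mutated
    w,              # (n_pre, n_act) feedforward weights, mutated
    mask,           # (n_pre, n_act) uint8, 1 = pinned to zero
    lateral,        # (n_act, n_act); diagonal present but never delivered
    dirs,           # (n_act, 2) preferred directions (incl. a0)
    centers,        # (n_pre, 2) place-field centres
    sigma2, peak,   # place-field width^2 and peak rate (Hz)
    dt,             # ms
    ff_m, ff_s, lat_m, lat_s, rho_m, rho_s, last_spike,   # (n_act,) mutated
    pre_trace, post_trace,                                # mutated
    elig, elig_g,   # (n_pre, n_act) rebased eligibility and (1,) scale
    prev_post,      # (n_act,) uint8, action spikes of the previous step
    eps_scale, chi, tau_m, tau_s, tau_gamma, nu_gamma, tau_stdp, tau_e,
    lam0, delta_u, theta, rho_scale,
    eta_ach, eta_da, w_min, w_max,
    radius, c_bait, c_other, well_r,
):
    n_pre = centers.shape[0]
    n_act = dirs.shape[0]
    dm = np.exp(-dt / tau_m)
    ds = np.exp(-dt / tau_s)
    dg = np.exp(-dt / tau_gamma)
    dn = np.exp(-dt / nu_gamma)
    d10 = np.exp(-dt / tau_stdp)
    de = np.exp(-dt / tau_e)

    pre_spk = np.zeros(n_pre, np.uint8)
    post_spk = np.zeros(n_act, np.uint8)

    for s in range(u01.shape[0]):
        t = t0 + (s + 1) * dt

        # --- place-cell rates and spikes at the current position
        n_pre_spk = 0
        for i in range(n_pre):
            dx0 = x[0] - centers[i, 0]
            dx1 = x[1] - centers[i, 1]
            rate = peak * np.exp(-(dx0 * dx0 + dx1 * dx1) / sigma2)
            if u01[s, i] < rate * dt * 1e-3:
                pre_spk[i] = 1
                n_pre_spk += 1
            else:
                pre_spk[i] = 0

        # --- membrane: decay accumulators, deliver this step's arrivals
        for j in range(n_act):
            ff_m[j] *= dm
            ff_s[j] *= ds
            lat_m[j] *= dm
            lat_s[j] *= ds
        if n_pre_spk > 0:
            for i in range(n_pre):
                if pre_spk[i]:
                    for j in range(n_act):
                        ff_m[j] += w[i, j]
                        ff_s[j] += w[i, j]
        for k in range(n_act):
            if prev_post[k]:
                for j in range(n_act):
                    if j != k:
                        lat_m[j] += lateral[j, k]
                        lat_s[j] += lateral[j, k]

        # --- potentials, escape-rate spiking, own-spike reset
        n_post_spk = 0
        for j in range(n_act):
            u = eps_scale * (ff_m[j] - ff_s[j] + lat_m[j] - lat_s[j])
            if last_spike[j] > -1e29:
                u += chi * np.exp(-(t - last_spike[j]) / tau_m)
            p = lam0 * np.exp((u - theta) / delta_u) * dt * 1e-3
            if p > 1.0:
                p = 1.0
            if u01[s, n_pre + j] < p:
                post_spk[j] = 1
                n_post_spk += 1
                last_spike[j] = t
                ff_m[j] = 0.0
                ff_s[j] = 0.0
                lat_m[j] = 0.0
                lat_s[j] = 0.0
            else:
                post_spk[j] = 0

        # --- filtered rate estimate and population-vector action
        ax = 0.0
        ay = 0.0
        for j in range(n_act):
            rho_m[j] = rho_m[j] * dg + post_spk[j]
            rho_s[j] = rho_s[j] * dn + post_spk[j]
            rho = rho_scale * (rho_m[j] - rho_s[j])
            ax += rho * dirs[j, 0]
            ay += rho * dirs[j, 1]
        ax /= n_act
        ay /= n_act

        # --- position update with specular wall reflection
        nx = x[0] + ax
        ny = x[1] + ay
        if nx * nx + ny * ny > radius * radius:
            r = np.sqrt(x[0] * x[0] + x[1] * x[1])
            if r > 0.0:
                xh0 = x[0] / r
                xh1 = x[1] / r
                adot = ax * xh0 + ay * xh1
                ax -= 2.0 * adot * xh0
                ay -= 2.0 * adot * xh1
            else:
                ax = -ax
                ay = -ay
            nx = x[0] + ax
            ny = x[1] + ay
            n = np.sqrt(nx * nx + ny * ny)
            if n > radius:
                nx *= radius / n
                ny *= radius / n
        x[0] = nx
        x[1] = ny

        # --- sn-Plast step: pairing traces, eligibility, ACh depression
        for i in range(n_pre):
            pre_trace[i] = pre_trace[i] * d10 + pre_spk[i]
        for j in range(n_act):
            post_trace[j] *= d10
        elig_g[0] *= de
        g = elig_g[0]
        if n_post_spk > 0:
            for j in range(n_act):
                if post_spk[j]:
                    for i in range(n_pre):
                        if mask[i, j] == 0:
                            m = pre_trace[i]
                            if m > 0.0:
                                elig[i, j] += m / g
                                if eta_ach > 0.0:
                                    wv = w[i, j] - eta_ach * m
                                    w[i, j] = wv if wv > w_min else w_min
        if n_pre_spk > 0:
            for i in range(n_pre):
                if pre_spk[i]:
                    for j in range(n_act):
                        if mask[i, j] == 0:
                            m = post_trace[j]
                            if m > 0.0:
                                elig[i, j] += m / g
                                if eta_ach > 0.0:
                                    wv = w[i, j] - eta_ach * m
                                    w[i, j] = wv if wv > w_min else w_min
        for j in range(n_act):
            post_trace[j] += post_spk[j]
        for j in range(n_act):
            prev_post[j] = post_spk[j]

        # --- well check on the updated position
        db0 = x[0] - c_bait[0]
        db1 = x[1] - c_bait[1]
        if db0 * db0 + db1 * db1 <= well_r * well_r:
            # dopamine: retroactive potentiation through the eligibility trace
            for i in range(n_pre):
                for j in range(n_act):
                    if mask[i, j] == 0 and elig[i, j] != 0.0:
                        wv = w[i, j] + eta_da * elig[i, j] * g
                        if wv > w_max:
                            wv = w_max
                        elif wv < w_min:
                            wv = w_min
                        w[i, j] = wv
                        elig[i, j] = 0.0
            return REWARD, s + 1
        do0 = x[0] - c_other[0]
        do1 = x[1] - c_other[1]
        if do0 * do0 + do1 * do1 <= well_r * well_r:
            return WRONG, s + 1

    return RUNNING, u01.shape[0]
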