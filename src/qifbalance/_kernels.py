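"""Compiled inner loops (numba) for the neural mass ODEs and the spiking net.

The mean-field state vector is ``y = (R_e, V_e, R_i, V_i)`` with rates in
1/ms.  Parameter vectors ``p`` are packed as
``(g_ee, g_ei, g_ie, g_ii, I0_e, I0_i, d_ee, d_ii, tau_e, tau_i, sqrt_K)``.

Escape guard: a trajectory is declared divergent when |V| or tau_m*R exceeds
``ESCAPE_GUARD``; integrators then return the escape step so callers can
report the escape time.
"""

import numpy as np
from numba import njit

ESCAPE_GUARD = 1.0e6

# packed parameter indices
_GEE, _GEI, _GIE, _GII, _I0E, _I0I, _DEE, _DII, _TAUE, _TAUI, _SQK = range(11)


def pack_params(params):
    """Pack a ModelParams into the flat vector the kernels consume."""
    return np.array(
        [
            params.g0_ee,
            params.g0_ei,
            params.g0_ie,
            params.g0_ii,
            params.I0_e,
            params.I0_i,
            params.delta0_ee,
            params.delta0_ii,
            params.tau_m_e,
            params.tau_m_i,
            np.sqrt(params.K),
        ]
    )


@njit(cache=True)
def mf_rhs(y, p):
    re, ve, ri, vi = y[0], y[1], y[2], y[3]
    taue, taui = p[_TAUE], p[_TAUI]
    sk = p[_SQK]
    out = np.empty(4)
    out[0] = re * (2.0 * ve + p[_GEE] * p[_DEE] / np.pi) / taue
    out[1] = (
        ve * ve
        - (np.pi * re * taue) ** 2
        + sk * (p[_I0E] + (p[_GEE] * re - p[_GEI] * ri) * taue)
    ) / taue
    out[2] = ri * (2.0 * vi + p[_GII] * p[_DII] / np.pi) / taui
    out[3] = (
        vi * vi
        - (np.pi * ri * taui) ** 2
        + sk * (p[_I0I] + (p[_GIE] * re - p[_GII] * ri) * taui)
    ) / taui
    return out


@njit(cache=True)
def mf_jacobian(y, p):
    re, ve, ri, vi = y[0], y[1], y[2], y[3]
    taue, taui = p[_TAUE], p[_TAUI]
    sk = p[_SQK]
    J = np.zeros((4, 4))
    J[0, 0] = (2.0 * ve + p[_GEE] * p[_DEE] / np.pi) / taue
    J[0, 1] = 2.0 * re / taue
    J[1, 0] = -2.0 * np.pi**2 * taue * re + sk * p[_GEE]
    J[1, 1] = 2.0 * ve / taue
    J[1, 2] = -sk * p[_GEI]
    J[2, 2] = (2.0 * vi + p[_GII] * p[_DII] / np.pi) / taui
    J[2, 3] = 2.0 * ri / taui
    J[3, 0] = sk * p[_GIE]
    J[3, 2] = -2.0 * np.pi**2 * taui * ri - sk * p[_GII]
    J[3, 3] = 2.0 * vi / taui
    return J


@njit(cache=True)
def _rk4_step(y, p, dt):
    k1 = mf_rhs(y, p)
    k2 = mf_rhs(y + 0.5 * dt * k1, p)
    k3 = mf_rhs(y + 0.5 * dt * k2, p)
    k4 = mf_rhs(y + dt * k3, p)
    return y + dt / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


@njit(cache=True)
def _escaped(y, p):
    return (
        abs(y[1]) > ESCAPE_GUARD
        or abs(y[3]) > ESCAPE_GUARD
        or p[_TAUE] * y[0] > ESCAPE_GUARD
        or p[_TAUI] * y[2] > ESCAPE_GUARD
        or not (
            np.isfinite(y[0]) and np.isfinite(y[1]) and np.isfinite(y[2]) and np.isfinite(y[3])
        )
    )


@njit(cache=True)
def integrate_kernel(y0, p, dt, n_steps, stride, n_skip):
    """RK4 trajectory; samples every `stride` steps after `n_skip` steps.

    Returns (status, escape_step, n_clip, samples) where status is 0 on
    success and 1 on escape.  Negative round-off in the rates is clipped to
    zero and counted in n_clip.
    """
    y = y0.copy()
    n_keep = (n_steps - n_skip) // stride
    out = np.empty((n_keep, 4))
    k = 0
    n_clip = 0
    for s in range(n_steps):
        y = _rk4_step(y, p, dt)
        if y[0] < 0.0:
            y[0] = 0.0
            n_clip += 1
        if y[2] < 0.0:
            y[2] = 0.0
            n_clip += 1
        if _escaped(y, p):
            return 1, s, n_clip, out[:k]
        if s >= n_skip and (s - n_skip) % stride == stride - 1:
            if k < n_keep:
                out[k] = y
                k += 1
    return 0, -1, n_clip, out[:k]


@njit(cache=True)
def benettin_kernel(y0, p, dt, n_steps, n_skip, renorm_every, Q0, n_discard):
    """Benettin Lyapunov spectrum of the 4-D neural mass flow.

    Tangent vectors (columns of Q) evolve under the linearized flow along the
    reference trajectory (same RK4 stages), re-orthonormalized by modified
    Gram-Schmidt every `renorm_every` steps; the exponents are the average
    log stretch rates.  The first `n_discard` steps of the averaging window
    are treated as tangent-alignment transient: the returned `les_tail`
    averages only beyond them (removing the O(1/T) bias of the full
    average `les_full`).

    Returns (status, escape_step, les_full, les_tail, conv) where conv
    holds running lambda_1 estimates at 100 checkpoints.
    """
    y = y0.copy()
    for s in range(n_skip):
        y = _rk4_step(y, p, dt)
        if y[0] < 0.0:
            y[0] = 0.0
        if y[2] < 0.0:
            y[2] = 0.0
        if _escaped(y, p):
            return 1, s, np.zeros(4), np.zeros(4), np.zeros(100)
    Q = Q0.copy()
    lsum = np.zeros(4)
    lsum_mark = np.zeros(4)
    marked = n_discard <= 0
    conv = np.zeros(100)
    chk = max(n_steps // 100, 1)
    for s in range(n_steps):
        k1 = mf_rhs(y, p)
        J1 = mf_jacobian(y, p)
        y2 = y + 0.5 * dt * k1
        k2 = mf_rhs(y2, p)
        J2 = mf_jacobian(y2, p)
        y3 = y + 0.5 * dt * k2
        k3 = mf_rhs(y3, p)
        J3 = mf_jacobian(y3, p)
        y4 = y + dt * k3
        k4 = mf_rhs(y4, p)
        J4 = mf_jacobian(y4, p)
        for j in range(4):
            v0 = Q[0, j]
            v1 = Q[1, j]
            v2 = Q[2, j]
            v3 = Q[3, j]
            a0 = J1[0, 0] * v0 + J1[0, 1] * v1
            a1 = J1[1, 0] * v0 + J1[1, 1] * v1 + J1[1, 2] * v2
            a2 = J1[2, 2] * v2 + J1[2, 3] * v3
            a3 = J1[3, 0] * v0 + J1[3, 2] * v2 + J1[3, 3] * v3
            b0 = v0 + 0.5 * dt * a0
            b1 = v1 + 0.5 * dt * a1
            b2 = v2 + 0.5 * dt * a2
            b3 = v3 + 0.5 * dt * a3
            c0 = J2[0, 0] * b0 + J2[0, 1] * b1
            c1 = J2[1, 0] * b0 + J2[1, 1] * b1 + J2[1, 2] * b2
            c2 = J2[2, 2] * b2 + J2[2, 3] * b3
            c3 = J2[3, 0] * b0 + J2[3, 2] * b2 + J2[3, 3] * b3
            b0 = v0 + 0.5 * dt * c0
            b1 = v1 + 0.5 * dt * c1
            b2 = v2 + 0.5 * dt * c2
            b3 = v3 + 0.5 * dt * c3
            d0 = J3[0, 0] * b0 + J3[0, 1] * b1
            d1 = J3[1, 0] * b0 + J3[1, 1] * b1 + J3[1, 2] * b2
            d2 = J3[2, 2] * b2 + J3[2, 3] * b3
            d3 = J3[3, 0] * b0 + J3[3, 2] * b2 + J3[3, 3] * b3
            b0 = v0 + dt * d0
            b1 = v1 + dt * d1
            b2 = v2 + dt * d2
            b3 = v3 + dt * d3
            e0 = J4[0, 0] * b0 + J4[0, 1] * b1
            e1 = J4[1, 0] * b0 + J4[1, 1] * b1 + J4[1, 2] * b2
            e2 = J4[2, 2] * b2 + J4[2, 3] * b3
            e3 = J4[3, 0] * b0 + J4[3, 2] * b2 + J4[3, 3] * b3
            Q[0, j] = v0 + dt / 6.0 * (a0 + 2.0 * c0 + 2.0 * d0 + e0)
            Q[1, j] = v1 + dt / 6.0 * (a1 + 2.0 * c1 + 2.0 * d1 + e1)
            Q[2, j] = v2 + dt / 6.0 * (a2 + 2.0 * c2 + 2.0 * d2 + e2)
            Q[3, j] = v3 + dt / 6.0 * (a3 + 2.0 * c3 + 2.0 * d3 + e3)
        y = y + dt / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if y[0] < 0.0:
            y[0] = 0.0
        if y[2] < 0.0:
            y[2] = 0.0
        if _escaped(y, p):
            t_el = max((s + 1) * dt, dt)
            return 1, s, lsum / t_el, lsum / t_el, conv
        if (s + 1) % renorm_every == 0:
            for j in range(4):
                for i in range(j):
                    c = 0.0
                    for r in range(4):
                        c += Q[r, i] * Q[r, j]
                    for r in range(4):
                        Q[r, j] -= c * Q[r, i]
                nrm = 0.0
                for r in range(4):
                    nrm += Q[r, j] * Q[r, j]
                nrm = np.sqrt(nrm)
                lsum[j] += np.log(nrm)
                for r in range(4):
                    Q[r, j] /= nrm
        if not marked and (s + 1) >= n_discard:
            for j in range(4):
                lsum_mark[j] = lsum[j]
            marked = True
        if (s + 1) % chk == 0:
            idx = (s + 1) // chk - 1
            if idx < 100:
                conv[idx] = lsum[0] / ((s + 1) * dt)
    les_full = lsum / (n_steps * dt)
    n_tail = n_steps - n_discard if n_discard > 0 else n_steps
    les_tail = (lsum - lsum_mark) / (n_tail * dt)
    return 0, -1, les_full, les_tail, conv


@njit(cache=True)
def network_euler_kernel(
    v,
    pop,
    tau_m,
    drive,
    indptr_out,
    idx_out,
    jump_out,
    dt,
    n_steps,
    rec_from_step,
    v_peak,
    hold_steps,
    rate_bin_steps,
    v_sample_steps,
    sp_t,
    sp_i,
    spike_counts,
    rate_counts,
    v_mean,
):
    """Euler integration of the pulse-coupled QIF network.

    A neuron spikes when v >= v_peak; it is reset to -v_peak and held for
    `hold_steps` steps (the finite-threshold stand-in for the traversal of
    +/- infinity); spikes emitted at step s are delivered to postsynaptic
    membranes at step s+1; inputs arriving during the hold are discarded.
    Held neurons are excluded from the mean-potential samples.

    Returns (status, n_recorded) with status 0 = ok, 1 = non-finite
    potential encountered, 2 = spike capacity exhausted.
    """
    N = v.shape[0]
    cap = sp_t.shape[0]
    hold = np.zeros(N, np.int64)
    pend = np.zeros(N)
    spiked = np.empty(N, np.int64)
    n_rec = 0
    for s in range(n_steps):
        nsp = 0
        for j in range(N):
            if hold[j] > 0:
                hold[j] -= 1
                continue
            vj = v[j] + pend[j]
            vj += dt / tau_m[j] * (vj * vj + drive[j])
            if not np.isfinite(vj):
                return 1, n_rec
            if vj >= v_peak:
                spiked[nsp] = j
                nsp += 1
                v[j] = -v_peak
                hold[j] = hold_steps[j]
            else:
                v[j] = vj
        for j in range(N):
            pend[j] = 0.0
        for k in range(nsp):
            pre = spiked[k]
            for e in range(indptr_out[pre], indptr_out[pre + 1]):
                pend[idx_out[e]] += jump_out[e]
        if s >= rec_from_step:
            srel = s - rec_from_step
            b = srel // rate_bin_steps
            for k in range(nsp):
                j = spiked[k]
                if n_rec >= cap:
                    return 2, n_rec
                sp_t[n_rec] = s * dt
                sp_i[n_rec] = j
                n_rec += 1
                spike_counts[j] += 1
                rate_counts[b, pop[j]] += 1
            if srel % v_sample_steps == 0:
                m = srel // v_sample_steps
                s0 = 0.0
                s1 = 0.0
                c0 = 0
                c1 = 0
                for j in range(N):
                    if hold[j] == 0:
                        if pop[j] == 0:
                            s0 += v[j]
                            c0 += 1
                        else:
                            s1 += v[j]
                            c1 += 1
                v_mean[m, 0] = s0 / c0 if c0 > 0 else 0.0
                v_mean[m, 1] = s1 / c1 if c1 > 0 else 0.0
    return 0, n_rec
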