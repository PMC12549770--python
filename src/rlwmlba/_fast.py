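"""Numba fast path for the session likelihood.

Mirrors ``model.session_loglik`` exactly (the test suite asserts agreement
with the pure-Python reference); used inside the MAP optimizer where the
likelihood is evaluated tens of thousands of times.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_SQRT2 = math.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)
_LOG_FLOOR = math.log(1e-10)
_Q_INIT = 1.0 / 3.0


@njit(cache=True)
def _norm_pdf(z):
    return _INV_SQRT_2PI * math.exp(-0.5 * z * z)


@njit(cache=True)
def _norm_cdf(z):
    return 0.5 * (1.0 + math.erf(z / _SQRT2))


@njit(cache=True)
def _lba_pdf_cdf(t, v, A, b, s):
    ts = t * s
    z1 = (b - t * v) / ts
    z2 = (b - A - t * v) / ts
    f = (1.0 / A) * (
        -v * _norm_cdf(z2) + s * _norm_pdf(z2) + v * _norm_cdf(z1) - s * _norm_pdf(z1)
    )
    F = (
        1.0
        + ((b - A - t * v) / A) * _norm_cdf(z2)
        - ((b - t * v) / A) * _norm_cdf(z1)
        + (ts / A) * _norm_pdf(z2)
        - (ts / A) * _norm_pdf(z1)
    )
    return f, F


@njit(cache=True)
def lba_logpdf3(choice, rt, v0, v1, v2, A, k, s, tau):
    if rt <= tau:
        return _LOG_FLOOR
    t = rt - tau
    b = A + k
    dens = 1.0
    for j in range(3):
        vj = v0 if j == 0 else (v1 if j == 1 else v2)
        f, F = _lba_pdf_cdf(t, vj, A, b, s)
        if j == choice:
            dens *= max(f, 0.0)
        else:
            surv = 1.0 - F
            if surv < 0.0:
                surv = 0.0
            elif surv > 1.0:
                surv = 1.0
            dens *= surv
    if not np.isfinite(dens) or dens < 1e-10:
        return _LOG_FLOOR
    return math.log(dens)


@njit(cache=True)
def _softmax3(q0, q1, q2, beta):
    m = max(q0, max(q1, q2))
    e0 = math.exp(beta * (q0 - m))
    e1 = math.exp(beta * (q1 - m))
    e2 = math.exp(beta * (q2 - m))
    z = e0 + e1 + e2
    return e0 / z, e1 / z, e2 / z


@njit(cache=True)
def subject_loglik(
    stim, act, rew, rt, block_ptr, set_sizes,
    alpha, bias, phi, rho, cap, eta, A, k,
    beta, tau, s, h_floor,
):
    total = 0.0
    for bi in range(len(set_sizes)):
        ss = set_sizes[bi]
        q_rl = np.full((ss, 3), _Q_INIT)
        q_wm = np.full((ss, 3), _Q_INIT)
        w = rho * min(1.0, cap / ss)
        for idx in range(block_ptr[bi], block_ptr[bi + 1]):
            st = stim[idx]
            avg0 = 0.0
            avg1 = 0.0
            avg2 = 0.0
            pm0 = 0.0
            pm1 = 0.0
            pm2 = 0.0
            for j in range(ss):
                r0, r1, r2 = _softmax3(q_rl[j, 0], q_rl[j, 1], q_rl[j, 2], beta)
                m0, m1, m2 = _softmax3(q_wm[j, 0], q_wm[j, 1], q_wm[j, 2], beta)
                p0 = w * m0 + (1.0 - w) * r0
                p1 = w * m1 + (1.0 - w) * r1
                p2 = w * m2 + (1.0 - w) * r2
                avg0 += p0
                avg1 += p1
                avg2 += p2
                if j == st:
                    pm0 = p0
                    pm1 = p1
                    pm2 = p2
            avg0 /= ss
            avg1 /= ss
            avg2 /= ss
            h = 0.0
            if avg0 > 0.0:
                h -= avg0 * math.log(avg0)
            if avg1 > 0.0:
                h -= avg1 * math.log(avg1)
            if avg2 > 0.0:
                h -= avg2 * math.log(avg2)
            h /= math.log(2.0)
            hdiv = h if h > h_floor else h_floor
            v0 = eta * pm0 / hdiv
            v1 = eta * pm1 / hdiv
            v2 = eta * pm2 / hdiv
            total += lba_logpdf3(act[idx], rt[idx], v0, v1, v2, A, k, s, tau)
            a = act[idx]
            r = float(rew[idx])
            delta = r - q_rl[st, a]
            rate = (1.0 - bias) * alpha if delta < 0.0 else alpha
            q_rl[st, a] += rate * delta
            qw = q_wm[st, a]
            if r >= qw:
                q_wm[st, a] = r
            else:
                q_wm[st, a] = qw + (1.0 - bias) * (r - qw)
            for j in range(ss):
                for aa in range(3):
                    q_wm[j, aa] += phi * (_Q_INIT - q_wm[j, aa])
    return total
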