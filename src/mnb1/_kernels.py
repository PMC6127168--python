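"""Compiled fixed-step Heun integration kernel.

The rectified gap-junction input from each sensilla population is
evaluated per time step as sum_i theta(U_i - U) * (U_i - U).  Because the
per-sensillum presynaptic voltages at a given time sample are pre-sorted
(with suffix sums), the population sum reduces to one binary search:
sum_{U_i > U} U_i - count * U.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _rect_sum(vsorted, suffix, U):
    # vsorted ascending; suffix[j] = sum(vsorted[j:]); suffix[n] = 0
    n = vsorted.shape[0]
    lo = 0
    hi = n
    while lo < hi:
        mid = (lo + hi) // 2
        if vsorted[mid] > U:
            hi = mid
        else:
            lo = mid + 1
    return suffix[lo] - (n - lo) * U


@njit(cache=True)
def _deriv(U, m, h, n, C, gNa, gK, gL, ENa, EK, EL, shift, i_ext):
    i_ion = (
        gNa * m * m * m * h * (U - ENa)
        + gK * n * n * n * n * (U - EK)
        + gL * (U - EL)
    )
    U = U + shift  # gating-convention offset; rates only
    x = U + 40.0
    if abs(x) < 1e-7:
        am = 1.0
    else:
        am = 0.1 * x / (1.0 - np.exp(-x / 10.0))
    bm = 4.0 * np.exp(-(U + 65.0) / 18.0)
    ah = 0.07 * np.exp(-(U + 65.0) / 20.0)
    bh = 1.0 / (1.0 + np.exp(-(U + 35.0) / 10.0))
    x = U + 55.0
    if abs(x) < 1e-7:
        an = 0.1
    else:
        an = 0.01 * x / (1.0 - np.exp(-x / 10.0))
    bn = 0.125 * np.exp(-(U + 65.0) / 80.0)
    dU = (i_ext - i_ion) / C
    dm = am * (1.0 - m) - bm * m
    dh = ah * (1.0 - h) - bh * h
    dn = an * (1.0 - n) - bn * n
    return dU, dm, dh, dn


@njit(cache=True)
def _i_ext(k, kc, U, gH, gW, gINs, hal_s, hal_x, wing_s, wing_x, uin, inj):
    i = inj[k]
    if hal_s.shape[1] > 0:
        i += gH * _rect_sum(hal_s[kc], hal_x[kc], U)
    if wing_s.shape[1] > 0:
        i += gW * _rect_sum(wing_s[kc], wing_x[kc], U)
    d = uin[k] - U
    if d > 0.0:
        i += gINs * d
    return i


@njit(cache=True)
def run_model(
    U0,
    m0,
    h0,
    n0,
    C,
    gNa,
    gK,
    gL,
    ENa,
    EK,
    EL,
    shift,
    gH,
    gW,
    gINs,
    hal_sorted,
    hal_suffix,
    wing_sorted,
    wing_suffix,
    uin,
    inj,
    dt,
    n_steps,
    period_steps,
    noise_sd,
    seed,
):
    U_out = np.empty(n_steps + 1)
    m_out = np.empty(n_steps + 1)
    h_out = np.empty(n_steps + 1)
    n_out = np.empty(n_steps + 1)
    if noise_sd > 0.0:
        np.random.seed(seed)
    U, m, h, n = U0, m0, h0, n0
    U_out[0] = U
    m_out[0] = m
    h_out[0] = h
    n_out[0] = n
    for k in range(n_steps):
        kc = k % period_steps
        kc1 = (k + 1) % period_steps
        i1 = _i_ext(k, kc, U, gH, gW, gINs, hal_sorted, hal_suffix,
                    wing_sorted, wing_suffix, uin, inj)
        dU1, dm1, dh1, dn1 = _deriv(U, m, h, n, C, gNa, gK, gL, ENa, EK, EL, shift, i1)
        Ue = U + dt * dU1
        me = m + dt * dm1
        he = h + dt * dh1
        ne = n + dt * dn1
        i2 = _i_ext(k + 1, kc1, Ue, gH, gW, gINs, hal_sorted, hal_suffix,
                    wing_sorted, wing_suffix, uin, inj)
        dU2, dm2, dh2, dn2 = _deriv(Ue, me, he, ne, C, gNa, gK, gL, ENa, EK, EL, shift, i2)
        U = U + 0.5 * dt * (dU1 + dU2)
        m = m + 0.5 * dt * (dm1 + dm2)
        h = h + 0.5 * dt * (dh1 + dh2)
        n = n + 0.5 * dt * (dn1 + dn2)
        if noise_sd > 0.0:
            U += noise_sd * np.random.normal()
        U_out[k + 1] = U
        m_out[k + 1] = m
        h_out[k + 1] = h
        n_out[k + 1] = n
        if not np.isfinite(U):
            for j in range(k + 2, n_steps + 1):
                U_out[j] = np.nan
            break
    return U_out, m_out, h_out, n_out
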