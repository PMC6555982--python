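"""Numba-compiled core of the cross-bridge myofilament model.

State vector layout (10 entries)::

    0  N        non-permissive regulatory fraction
    1  P        permissive regulatory fraction
    2  XBPreR   pre-rotation strongly-bound cross-bridge fraction
    3  XBPostR  post-rotation (force-generating) cross-bridge fraction
    4  xPreR    mean strain of pre-rotation bridges (um)
    5  xPostR   mean strain of post-rotation bridges (um)
    6  TnCaL    Ca occupancy of low-affinity regulatory troponin
    7  TnCaH    Ca occupancy of high-affinity regulatory troponin
    8  SL       sarcomere length (um)
    9  intf     time-integral of net normalized force (norm * ms)

Occupancy conservation N+P+XBPreR+XBPostR = 1 is preserved exactly by the
stepper because the four derivatives sum to zero algebraically.
"""

import math

import numpy as np
from numba import njit

NSTATE = 10

# -- parameter vector indices -------------------------------------------------
M_X0, M_SL0, M_SLMIN, M_SLMAX, M_SLREST = 0, 1, 2, 3, 4
M_LTHIN, M_LTHICK, M_LHBARE = 5, 6, 7
M_FAPP, M_GAPP, M_HF, M_HB, M_GXB = 8, 9, 10, 11, 12
M_TMPC, M_QFAPP, M_QGAPP, M_QHF, M_QHB, M_QGXB = 13, 14, 15, 16, 17, 18
M_KNP, M_KPN, M_QKNP, M_QKPN, M_PERM50, M_NPERM = 19, 20, 21, 22, 23, 24
M_KON, M_KOFFL, M_KOFFH, M_QKON, M_QKOFF = 25, 26, 27, 28, 29
M_GSLMOD, M_HFMDC, M_SIGMAP, M_SIGMAN, M_XPSI, M_SPECIES = 30, 31, 32, 33, 34, 35
M_PCONT, M_PEXPT, M_SLC, M_PCONC, M_PEXPC = 36, 37, 38, 39, 40
M_MASS, M_VISC, M_FSCALE, M_RATECAP = 41, 42, 43, 44
NPARAM = 45

MODE_ISOTONIC = 0
MODE_CLAMP = 1


@njit(cache=True)
def overlap_fractions(SL, p):
    """Thick- and thin-filament single-overlap fractions at length ``SL``."""
    sovr_ze = min(p[M_LTHICK] * 0.5, SL * 0.5)
    sovr_cle = max(SL * 0.5 - (SL - p[M_LTHIN]), p[M_LHBARE] * 0.5)
    len_sovr = max(sovr_ze - sovr_cle, 0.0)
    sovf_thick = len_sovr * 2.0 / (p[M_LTHICK] - p[M_LHBARE])
    sovf_thin = len_sovr / p[M_LTHIN]
    return sovf_thick, sovf_thin


@njit(cache=True)
def temp_rates(p):
    """Q10-corrected base transition rates (ms^-1) at the working temperature."""
    q = (p[M_TMPC] - 37.0) / 10.0
    sp = p[M_SPECIES]
    fappT = p[M_FAPP] * sp * p[M_QFAPP] ** q
    gappT = p[M_GAPP] * sp * p[M_QGAPP] ** q
    hfT = p[M_HF] * sp * p[M_QHF] ** q
    hbT = p[M_HB] * sp * p[M_QHB] ** q
    gxbT = p[M_GXB] * sp * p[M_QGXB] ** q
    knpT = p[M_KNP] * p[M_QKNP] ** q
    kpnT = p[M_KPN] * p[M_QKPN] ** q
    konT = p[M_KON] * p[M_QKON] ** q
    koffLT = p[M_KOFFL] * p[M_QKOFF] ** q
    koffHT = p[M_KOFFH] * p[M_QKOFF] ** q
    return fappT, gappT, hfT, hbT, gxbT, knpT, kpnT, konT, koffLT, koffHT


@njit(cache=True)
def duty_fractions(fapp, gapp, hf, hb, gxb):
    """Steady-state occupancies of the attached cycle (P, PreR, PostR chain).

    Returns (SSXBPreR, SSXBPostR) — the normalization constants of the
    mean-strain dynamics and of the active-force normalization.
    """
    denom = (gxb * hf + fapp * hf + gxb * gapp + hb * fapp + hb * gapp + gxb * fapp)
    ss_prer = (hb * fapp + gxb * fapp) / denom
    ss_postr = fapp * hf / denom
    return ss_prer, ss_postr


@njit(cache=True)
def passive_force(SL, p):
    """Titin + collagen passive force (normalized), signed (negative below rest)."""
    d = SL - p[M_SLREST]
    s = 1.0 if d >= 0.0 else -1.0
    f = s * p[M_PCONT] * (math.exp(p[M_PEXPT] * abs(d)) - 1.0)
    if SL > p[M_SLC]:
        f += p[M_PCONC] * (math.exp(p[M_PEXPC] * (SL - p[M_SLC])) - 1.0)
    return f


@njit(cache=True)
def strain_rates(y, ca, dSLdt, p):
    """Full right-hand side of the cross-bridge stage at cytosolic Ca ``ca`` (uM).

    Returns the 10 state derivatives; SL/intf entries are filled by the caller
    (they depend on the load mode).
    """
    fappT, gappT, hfT, hbT, gxbT, knpT, kpnT, konT, koffLT, koffHT = temp_rates(p)
    sovf_thick, sovf_thin = overlap_fractions(y[8], p)

    # Ca binding to regulatory troponin
    dTnCaL = konT * ca * (1.0 - y[6]) - koffLT * y[6]
    dTnCaH = konT * ca * (1.0 - y[7]) - koffHT * y[7]

    # overlap-weighted regulatory Ca signal and cooperative permissiveness
    trop_reg = (1.0 - sovf_thin) * y[6] + sovf_thin * y[7]
    if trop_reg < 1e-8:
        trop_reg = 1e-8
    permtot = math.sqrt(1.0 / (1.0 + (p[M_PERM50] / trop_reg) ** p[M_NPERM]))
    inprmt = 1.0 / permtot
    if inprmt > 100.0:
        inprmt = 100.0

    # strain- and overlap-modified rates
    cap = p[M_RATECAP]
    x0 = p[M_X0]
    gapp_mod = gappT * (1.0 + (1.0 - sovf_thick) * p[M_GSLMOD])
    xr = y[4] / x0
    s = 1.0 if xr >= 0.0 else -1.0
    hf_mod = hfT * math.exp(-s * p[M_HFMDC] * xr * xr)
    if hf_mod > cap:
        hf_mod = cap
    dx = (y[5] - x0) / x0
    if y[5] < x0:
        gxb_mod = gxbT * math.exp(p[M_SIGMAP] * dx * dx)
    else:
        gxb_mod = gxbT * math.exp(p[M_SIGMAN] * dx * dx)
    if gxb_mod < gxbT:
        gxb_mod = gxbT
    if gxb_mod > cap:
        gxb_mod = cap

    knp = knpT * permtot
    kpn = kpnT * inprmt

    dN = -knp * y[0] + kpn * y[1]
    dPreR = fappT * y[1] - gapp_mod * y[2] - hf_mod * y[2] + hbT * y[3]
    dPostR = hf_mod * y[2] - hbT * y[3] - gxb_mod * y[3]
    dP = -(dN + dPreR + dPostR)

    # mean-strain dynamics, normalized by instantaneous duty fractions
    duty_prer, duty_postr = duty_fractions(fappT, gapp_mod, hf_mod, hbT, gxb_mod)
    if duty_prer < 1e-6:
        duty_prer = 1e-6
    if duty_postr < 1e-6:
        duty_postr = 1e-6
    xpsi = p[M_XPSI]
    dxPreR = dSLdt * 0.5 + (xpsi / duty_prer) * (
        fappT * (-y[4]) + hbT * (y[5] - x0 - y[4]))
    dxPostR = dSLdt * 0.5 + (xpsi / duty_postr) * hf_mod * (y[4] + x0 - y[5])

    out = np.empty(NSTATE)
    out[0] = dN
    out[1] = dP
    out[2] = dPreR
    out[3] = dPostR
    out[4] = dxPreR
    out[5] = dxPostR
    out[6] = dTnCaL
    out[7] = dTnCaH
    out[8] = 0.0
    out[9] = 0.0
    return out


@njit(cache=True)
def active_force_norm(y, p, ss_postr_max):
    sovf_thick, _ = overlap_fractions(y[8], p)
    return sovf_thick * (y[4] * y[2] + y[5] * y[3]) / (p[M_X0] * ss_postr_max)


@njit(cache=True)
def atp_rate_norm(y, p):
    """Cross-bridge detachment flux g_xbT * XB_PostR * SOVF_thick (ms^-1)."""
    fappT, gappT, hfT, hbT, gxbT, knpT, kpnT, konT, koffLT, koffHT = temp_rates(p)
    sovf_thick, _ = overlap_fractions(y[8], p)
    cap = p[M_RATECAP]
    x0 = p[M_X0]
    dx = (y[5] - x0) / x0
    if y[5] < x0:
        gxb_mod = gxbT * math.exp(p[M_SIGMAP] * dx * dx)
    else:
        gxb_mod = gxbT * math.exp(p[M_SIGMAN] * dx * dx)
    if gxb_mod < gxbT:
        gxb_mod = gxbT
    if gxb_mod > cap:
        gxb_mod = cap
    return gxb_mod * y[3] * sovf_thick


@njit(cache=True)
def ss_postr_max(p):
    """Duty-fraction normalization: post-rotation occupancy under optimal
    conditions (full overlap, unstrained), used to normalize active force."""
    fappT, gappT, hfT, hbT, gxbT, knpT, kpnT, konT, koffLT, koffHT = temp_rates(p)
    _, sspost = duty_fractions(fappT, gappT, hfT, hbT, gxbT)
    return sspost


@njit(cache=True)
def run_mech(ca, dt_ca, dt, p, y0, mode, load_norm, preload_norm):
    """Integrate the mechanics stage driven by a sampled Ca transient.

    ``ca`` (uM) is sampled at ``dt_ca``; the stepper runs at ``dt`` with linear
    interpolation of Ca and writes outputs on the Ca grid. ``load_norm`` is the
    afterload in normalized-force units. In MODE_ISOTONIC the sarcomere works
    against the constant afterload but cannot lengthen past SL_0 (rigid stop:
    the afterloaded-twitch convention); in MODE_CLAMP SL is held at SL_0.

    Returns ``(out, y, status)``; out columns are
    (force_norm_active, tension_dev_norm, atp_norm, SL).
    """
    n_ca = ca.shape[0]
    total_ms = (n_ca - 1) * dt_ca
    n_steps = int(round(total_ms / dt))
    sub = max(int(round(dt_ca / dt)), 1)
    out = np.empty((n_ca, 4))
    y = y0.copy()
    sspost = ss_postr_max(p)
    pre = preload_norm
    status = 0
    k = 0
    for step in range(n_steps + 1):
        t = step * dt
        # linear interpolation of the Ca drive
        pos = t / dt_ca
        i0 = int(pos)
        if i0 >= n_ca - 1:
            cav = ca[n_ca - 1]
        else:
            w = pos - i0
            cav = ca[i0] * (1.0 - w) + ca[i0 + 1] * w

        if step % sub == 0 and k < n_ca:
            act = active_force_norm(y, p, sspost)
            dev = act + passive_force(y[8], p) - pre
            out[k, 0] = act
            out[k, 1] = dev
            out[k, 2] = atp_rate_norm(y, p)
            out[k, 3] = y[8]
            k += 1
        if step == n_steps:
            break

        # velocity from the integrated force balance
        if mode == MODE_CLAMP:
            v = 0.0
        else:
            v = (y[9] + (p[M_SL0] - y[8]) * p[M_VISC]) / p[M_MASS]

        dy = strain_rates(y, cav, v, p)
        act = active_force_norm(y, p, sspost)
        ppf = passive_force(y[8], p)

        for i in range(8):
            y[i] += dt * dy[i]

        if mode != MODE_CLAMP:
            # net normalized force: afterload stretches, active+passive resist
            dintf = -(ppf) + pre - act + load_norm
            y[9] += dt * dintf
            v_new = (y[9] + (p[M_SL0] - y[8]) * p[M_VISC]) / p[M_MASS]
            y[8] += dt * v_new
            if y[8] >= p[M_SL0]:
                # rigid stop at the preloaded rest length
                y[8] = p[M_SL0]
                if y[9] > 0.0:
                    y[9] = 0.0
            if y[8] < p[M_SLMIN]:
                y[8] = p[M_SLMIN]
                if y[9] < 0.0:
                    y[9] = 0.0

        if not (math.isfinite(y[8]) and math.isfinite(y[3])):
            status = step + 1
            break
    return out[:k], y, status
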