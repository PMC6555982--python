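"""Numba-compiled core of the human ventricular ionic model.

State vector layout (19 entries)::

    0  V     membrane potential (mV)
    1  m     I_Na activation
    2  h     I_Na fast inactivation
    3  j     I_Na slow inactivation
    4  d     I_CaL activation
    5  f     I_CaL voltage inactivation (slow)
    6  f2    I_CaL voltage inactivation (fast)
    7  fcass I_CaL Ca-dependent inactivation
    8  r     I_to activation
    9  s     I_to inactivation
    10 xr1   I_Kr activation
    11 xr2   I_Kr inactivation
    12 xs    I_Ks activation
    13 rbar  fraction of closed-but-available RyR (release channel adaptation)
    14 Cai   free cytosolic Ca (mM)
    15 CaSR  free SR Ca (mM)
    16 Cass  free dyadic-subspace Ca (mM)
    17 Nai   intracellular Na (mM)
    18 Ki    intracellular K (mM)

Parameter vectors are packed by :mod:`ecalt.ionic`; the index constants below
are the single source of truth for the packing order.
"""

import math

import numpy as np
from numba import njit

NSTATE = 19

# -- parameter vector indices -------------------------------------------------
P_GNA, P_GK1, P_GTO, P_GKR, P_GKS, P_GCAL, P_KNACA, P_PNAK = 0, 1, 2, 3, 4, 5, 6, 7
P_GPCA, P_GPK, P_GBCA, P_GBNA = 8, 9, 10, 11
P_VMAXUP, P_KUP, P_VREL, P_VLEAK, P_VXFER = 12, 13, 14, 15, 16
P_CM, P_VC, P_VSR, P_VSS, P_F = 17, 18, 19, 20, 21
P_KO, P_NAO, P_CAO = 22, 23, 24
P_ENDO_S, P_TAUF_FAC, P_TAUF_REC, P_TAUF2_REC = 25, 26, 48, 49
P_BUFC, P_KBUFC, P_BUFSR, P_KBUFSR, P_BUFSS, P_KBUFSS = 27, 28, 29, 30, 31, 32
P_K1P, P_K2P, P_K3, P_K4, P_EC, P_MAXSR, P_MINSR = 33, 34, 35, 36, 37, 38, 39
P_KPCA, P_PKNA, P_KMNAI, P_KMCA, P_KSAT, P_GAMMA = 40, 41, 42, 43, 44, 45
P_KMK, P_KMNA = 46, 47
NPARAM = 50

R_GAS = 8314.472  # mJ/(mol K)
T_KELVIN = 310.0

N_GATES = 13  # m h j d f f2 fcass r s xr1 xr2 xs rbar (state indices 1..13)


@njit(cache=True)
def gate_targets(V, Cass, CaSR, p, xinf, tau):
    """Steady states and time constants for the 13 relaxation gates.

    ``xinf``/``tau`` are length-13 scratch arrays filled in place, ordered as
    state indices 1..13.
    """
    if CaSR < 1e-12:
        CaSR = 1e-12
    if Cass < 1e-12:
        Cass = 1e-12
    # I_Na gates
    xinf[0] = 1.0 / ((1.0 + math.exp((-56.86 - V) / 9.03)) ** 2)
    am = 1.0 / (1.0 + math.exp((-60.0 - V) / 5.0))
    bm = 0.1 / (1.0 + math.exp((V + 35.0) / 5.0)) + 0.1 / (1.0 + math.exp((V - 50.0) / 200.0))
    tau[0] = am * bm

    hinf = 1.0 / ((1.0 + math.exp((V + 71.55) / 7.43)) ** 2)
    xinf[1] = hinf
    if V >= -40.0:
        ah = 0.0
        bh = 0.77 / (0.13 * (1.0 + math.exp(-(V + 10.66) / 11.1)))
    else:
        ah = 0.057 * math.exp(-(V + 80.0) / 6.8)
        bh = 2.7 * math.exp(0.079 * V) + 3.1e5 * math.exp(0.3485 * V)
    tau[1] = 1.0 / (ah + bh)

    xinf[2] = hinf
    if V >= -40.0:
        aj = 0.0
        bj = 0.6 * math.exp(0.057 * V) / (1.0 + math.exp(-0.1 * (V + 32.0)))
    else:
        aj = ((-2.5428e4 * math.exp(0.2444 * V) - 6.948e-6 * math.exp(-0.04391 * V))
              * (V + 37.78) / (1.0 + math.exp(0.311 * (V + 79.23))))
        bj = 0.02424 * math.exp(-0.01052 * V) / (1.0 + math.exp(-0.1378 * (V + 40.14)))
    tau[2] = 1.0 / (aj + bj)

    # I_CaL gates
    xinf[3] = 1.0 / (1.0 + math.exp((-8.0 - V) / 7.5))
    ad = 1.4 / (1.0 + math.exp((-35.0 - V) / 13.0)) + 0.25
    bd = 1.4 / (1.0 + math.exp((V + 5.0) / 5.0))
    gd = 1.0 / (1.0 + math.exp((50.0 - V) / 20.0))
    tau[3] = ad * bd + gd

    xinf[4] = 1.0 / (1.0 + math.exp((V + 20.0) / 7.0))
    tf = (1102.5 * math.exp(-((V + 27.0) ** 2) / 225.0)
          + 200.0 / (1.0 + math.exp((13.0 - V) / 10.0))
          + 180.0 / (1.0 + math.exp((V + 30.0) / 10.0)) + 20.0)
    if V > 0.0:
        tf *= p[P_TAUF_FAC]
    else:
        # steep-restitution variants slow recovery of I_CaL from inactivation
        tf *= p[P_TAUF_REC]
    tau[4] = tf

    xinf[5] = 0.67 / (1.0 + math.exp((V + 35.0) / 7.0)) + 0.33
    tf2 = (562.0 * math.exp(-((V + 27.0) ** 2) / 240.0)
           + 31.0 / (1.0 + math.exp((25.0 - V) / 10.0))
           + 80.0 / (1.0 + math.exp((V + 30.0) / 10.0)))
    if V <= 0.0:
        tf2 *= p[P_TAUF2_REC]
    tau[5] = tf2

    css_sq = (Cass / 0.05) ** 2
    xinf[6] = 0.6 / (1.0 + css_sq) + 0.4
    tau[6] = 80.0 / (1.0 + css_sq) + 2.0

    # I_to gates
    xinf[7] = 1.0 / (1.0 + math.exp((20.0 - V) / 6.0))
    tau[7] = 9.5 * math.exp(-((V + 40.0) ** 2) / 1800.0) + 0.8

    if p[P_ENDO_S] > 0.5:
        xinf[8] = 1.0 / (1.0 + math.exp((V + 28.0) / 5.0))
        tau[8] = 1000.0 * math.exp(-((V + 67.0) ** 2) / 1000.0) + 8.0
    else:
        xinf[8] = 1.0 / (1.0 + math.exp((V + 20.0) / 5.0))
        tau[8] = (85.0 * math.exp(-((V + 45.0) ** 2) / 320.0)
                  + 5.0 / (1.0 + math.exp((V - 20.0) / 5.0)) + 3.0)

    # I_Kr gates
    xinf[9] = 1.0 / (1.0 + math.exp((-26.0 - V) / 7.0))
    axr1 = 450.0 / (1.0 + math.exp((-45.0 - V) / 10.0))
    bxr1 = 6.0 / (1.0 + math.exp((V + 30.0) / 11.5))
    tau[9] = axr1 * bxr1

    xinf[10] = 1.0 / (1.0 + math.exp((V + 88.0) / 24.0))
    axr2 = 3.0 / (1.0 + math.exp((-60.0 - V) / 20.0))
    bxr2 = 1.12 / (1.0 + math.exp((V - 60.0) / 20.0))
    tau[10] = axr2 * bxr2

    # I_Ks gate
    xinf[11] = 1.0 / (1.0 + math.exp((-5.0 - V) / 14.0))
    axs = 1400.0 / math.sqrt(1.0 + math.exp((5.0 - V) / 6.0))
    bxs = 1.0 / (1.0 + math.exp((V - 35.0) / 15.0))
    tau[11] = axs * bxs + 80.0

    # RyR availability (linear in rbar at fixed Cass/CaSR)
    kcasr = p[P_MAXSR] - (p[P_MAXSR] - p[P_MINSR]) / (1.0 + (p[P_EC] / CaSR) ** 2)
    k2 = p[P_K2P] * kcasr
    rate = k2 * Cass + p[P_K4]
    xinf[12] = p[P_K4] / rate
    tau[12] = 1.0 / rate

    for i in range(N_GATES):   # diverging V can push a rate to +inf
        if not tau[i] > 1e-9:
            tau[i] = 1e-9


@njit(cache=True)
def currents(y, p, out):
    """All twelve sarcolemmal currents (A/F), filled into ``out`` (length 12).

    Order: INa, IK1, Ito, IKr, IKs, ICaL, INaCa, INaK, IpCa, IpK, IbCa, IbNa.
    Returns the total ionic current.
    """
    V = y[0]
    Cai, Cass = y[14], y[16]
    Nai, Ki = y[17], y[18]
    # tiny floors keep the Nernst logs defined while a diverging trajectory
    # works its way to the per-beat finiteness check
    if Cai < 1e-12:
        Cai = 1e-12
    if Nai < 1e-12:
        Nai = 1e-12
    if Ki < 1e-12:
        Ki = 1e-12
    Ko, Nao, Cao = p[P_KO], p[P_NAO], p[P_CAO]
    F = p[P_F]
    rtonf = R_GAS * T_KELVIN / F
    vfrt = V * F / (R_GAS * T_KELVIN)

    Ek = rtonf * math.log(Ko / Ki)
    Ena = rtonf * math.log(Nao / Nai)
    Eks = rtonf * math.log((Ko + p[P_PKNA] * Nao) / (Ki + p[P_PKNA] * Nai))
    Eca = 0.5 * rtonf * math.log(Cao / Cai)

    out[0] = p[P_GNA] * y[1] ** 3 * y[2] * y[3] * (V - Ena)

    ak1 = 0.1 / (1.0 + math.exp(0.06 * (V - Ek - 200.0)))
    bk1 = ((3.0 * math.exp(0.0002 * (V - Ek + 100.0)) + math.exp(0.1 * (V - Ek - 10.0)))
           / (1.0 + math.exp(-0.5 * (V - Ek))))
    out[1] = p[P_GK1] * math.sqrt(Ko / 5.4) * (ak1 / (ak1 + bk1)) * (V - Ek)

    out[2] = p[P_GTO] * y[8] * y[9] * (V - Ek)
    out[3] = p[P_GKR] * math.sqrt(Ko / 5.4) * y[10] * y[11] * (V - Ek)
    out[4] = p[P_GKS] * y[12] * y[12] * (V - Eks)

    z = 2.0 * (V - 15.0) * F / (R_GAS * T_KELVIN)
    gating = p[P_GCAL] * y[4] * y[5] * y[6] * y[7]
    if abs(z) < 1e-7:
        out[5] = gating * 2.0 * F * (0.25 * Cass - Cao)
    else:
        ez = math.exp(z)
        out[5] = (gating * 4.0 * (V - 15.0) * F * F / (R_GAS * T_KELVIN)
                  * (0.25 * Cass * ez - Cao) / (ez - 1.0))

    eg = math.exp(p[P_GAMMA] * vfrt)
    eg1 = math.exp((p[P_GAMMA] - 1.0) * vfrt)
    out[6] = (p[P_KNACA]
              * (eg * Nai ** 3 * Cao - eg1 * Nao ** 3 * Cai * 2.5)
              / ((p[P_KMNAI] ** 3 + Nao ** 3) * (p[P_KMCA] + Cao)
                 * (1.0 + p[P_KSAT] * eg1)))

    out[7] = (p[P_PNAK] * Ko * Nai
              / ((Ko + p[P_KMK]) * (Nai + p[P_KMNA])
                 * (1.0 + 0.1245 * math.exp(-0.1 * vfrt) + 0.0353 * math.exp(-vfrt))))

    out[8] = p[P_GPCA] * Cai / (Cai + p[P_KPCA])
    out[9] = p[P_GPK] * (V - Ek) / (1.0 + math.exp((25.0 - V) / 5.98))
    out[10] = p[P_GBCA] * (V - Eca)
    out[11] = p[P_GBNA] * (V - Ena)

    tot = 0.0
    for i in range(12):
        tot += out[i]
    return tot


@njit(cache=True)
def sr_fluxes_core(Cai, CaSR, Cass, O, p):
    """SR leak, uptake, release and subspace-transfer fluxes (mM/ms)."""
    ileak = p[P_VLEAK] * (CaSR - Cai)
    if Cai <= 0.0:
        iup = 0.0
    else:
        iup = p[P_VMAXUP] / (1.0 + (p[P_KUP] * p[P_KUP]) / (Cai * Cai))
    irel = p[P_VREL] * O * (CaSR - Cass)
    ixfer = p[P_VXFER] * (Cass - Cai)
    return ileak, iup, irel, ixfer


@njit(cache=True)
def ryr_open_fraction(Cass, CaSR, rbar, p):
    if CaSR < 1e-12:
        CaSR = 1e-12
    if Cass < 0.0:
        Cass = 0.0
    kcasr = p[P_MAXSR] - (p[P_MAXSR] - p[P_MINSR]) / (1.0 + (p[P_EC] / CaSR) ** 2)
    k1 = p[P_K1P] / kcasr
    return k1 * Cass * Cass * rbar / (p[P_K3] + k1 * Cass * Cass)


@njit(cache=True)
def conc_derivs(y, p, cur, istim):
    """Time derivatives of V and the five concentration states.

    ``cur`` is the current breakdown from :func:`currents`.
    Returns (dV, dCai, dCaSR, dCass, dNai, dKi).
    """
    Cai, CaSR, Cass = y[14], y[15], y[16]
    F, Cm = p[P_F], p[P_CM]
    Vc, Vsr, Vss = p[P_VC], p[P_VSR], p[P_VSS]

    O = ryr_open_fraction(Cass, CaSR, y[13], p)
    ileak, iup, irel, ixfer = sr_fluxes_core(Cai, CaSR, Cass, O, p)

    tot = 0.0
    for i in range(12):
        tot += cur[i]
    dV = -(tot + istim)

    # rapid-buffering factors (free fraction of a concentration increment)
    bc = 1.0 / (1.0 + p[P_BUFC] * p[P_KBUFC] / ((Cai + p[P_KBUFC]) ** 2))
    bsr = 1.0 / (1.0 + p[P_BUFSR] * p[P_KBUFSR] / ((CaSR + p[P_KBUFSR]) ** 2))
    bss = 1.0 / (1.0 + p[P_BUFSS] * p[P_KBUFSS] / ((Cass + p[P_KBUFSS]) ** 2))

    dCai = bc * (-(cur[10] + cur[8] - 2.0 * cur[6]) * Cm / (2.0 * Vc * F)
                 + (Vsr / Vc) * (ileak - iup) + ixfer)
    dCaSR = bsr * (iup - ileak - irel)
    dCass = bss * (-cur[5] * Cm / (2.0 * Vss * F)
                   + irel * (Vsr / Vss) - ixfer * (Vc / Vss))
    dNai = -(cur[0] + cur[11] + 3.0 * cur[7] + 3.0 * cur[6]) * Cm / (Vc * F)
    dKi = -(istim + cur[1] + cur[2] + cur[3] + cur[4] - 2.0 * cur[7] + cur[9]) * Cm / (Vc * F)
    return dV, dCai, dCaSR, dCass, dNai, dKi


@njit(cache=True)
def rhs(y, p, istim, dy):
    """Full right-hand side dy/dt (for the adaptive reference solver)."""
    xinf = np.empty(N_GATES)
    tau = np.empty(N_GATES)
    cur = np.empty(12)
    gate_targets(y[0], y[16], y[15], p, xinf, tau)
    currents(y, p, cur)
    dV, dCai, dCaSR, dCass, dNai, dKi = conc_derivs(y, p, cur, istim)
    dy[0] = dV
    for g in range(N_GATES):
        dy[1 + g] = (xinf[g] - y[1 + g]) / tau[g]
    dy[14] = dCai
    dy[15] = dCaSR
    dy[16] = dCass
    dy[17] = dNai
    dy[18] = dKi


@njit(cache=True)
def run_fixed(y0, p, bcl, n_beats, dt, dt_out, stim_amp, stim_dur):
    """Fixed-step integration of ``n_beats`` paced beats.

    Rush-Larsen exponential updates for the 13 gates; Heun (two-stage,
    second order) updates for the potential and concentrations, which keeps
    the upstroke accurate at the default 0.02 ms step. The stimulus is
    applied during ``[0, stim_dur)`` of every beat.

    Returns ``(out, snaps, y, status)`` where ``out`` has columns
    (t, V, Cai, CaSR, Cass) sampled every ``dt_out``; ``snaps`` holds the full
    state at each beat start; ``status`` is 0 on success, otherwise the
    1-based beat index where a non-finite value appeared.
    """
    steps_per_beat = int(round(bcl / dt))
    out_every = max(int(round(dt_out / dt)), 1)
    total_steps = steps_per_beat * n_beats
    n_out = total_steps // out_every + 1
    out = np.empty((n_out, 5))
    snaps = np.empty((n_beats, NSTATE))
    y = y0.copy()
    xinf = np.empty(N_GATES)
    tau = np.empty(N_GATES)
    xinf2 = np.empty(N_GATES)
    tau2 = np.empty(N_GATES)
    gates0 = np.empty(N_GATES)
    cur = np.empty(12)
    status = 0
    k = 0
    step = 0
    for b in range(n_beats):
        for i in range(NSTATE):
            snaps[b, i] = y[i]
        for i in range(steps_per_beat):
            if step % out_every == 0:
                out[k, 0] = step * dt
                out[k, 1] = y[0]
                out[k, 2] = y[14]
                out[k, 3] = y[15]
                out[k, 4] = y[16]
                k += 1
            t_beat = i * dt
            # the pulse is constant across any step (duration is a step multiple)
            istim = stim_amp if t_beat < stim_dur - 1e-9 else 0.0

            gate_targets(y[0], y[16], y[15], p, xinf, tau)
            currents(y, p, cur)
            d1 = conc_derivs(y, p, cur, istim)

            # predictor (gates take a provisional full exponential step)
            for g in range(N_GATES):
                gates0[g] = y[1 + g]
                y[1 + g] = xinf[g] + (y[1 + g] - xinf[g]) * math.exp(-dt / tau[g])
            v0 = y[0]
            c0 = (y[14], y[15], y[16], y[17], y[18])
            y[0] = v0 + dt * d1[0]
            y[14] = c0[0] + dt * d1[1]
            y[15] = c0[1] + dt * d1[2]
            y[16] = c0[2] + dt * d1[3]
            y[17] = c0[3] + dt * d1[4]
            y[18] = c0[4] + dt * d1[5]

            # corrector
            currents(y, p, cur)
            d2 = conc_derivs(y, p, cur, istim)
            # gates re-stepped from their old values with trapezoidal rates
            gate_targets(y[0], y[16], y[15], p, xinf2, tau2)
            for g in range(N_GATES):
                r1 = 1.0 / tau[g]
                r2 = 1.0 / tau2[g]
                rate = 0.5 * (r1 + r2)
                target = (xinf[g] * r1 + xinf2[g] * r2) / (r1 + r2)
                y[1 + g] = target + (gates0[g] - target) * math.exp(-dt * rate)
            y[0] = v0 + 0.5 * dt * (d1[0] + d2[0])
            y[14] = c0[0] + 0.5 * dt * (d1[1] + d2[1])
            y[15] = c0[1] + 0.5 * dt * (d1[2] + d2[2])
            y[16] = c0[2] + 0.5 * dt * (d1[3] + d2[3])
            y[17] = c0[3] + 0.5 * dt * (d1[4] + d2[4])
            y[18] = c0[4] + 0.5 * dt * (d1[5] + d2[5])
            step += 1
        if not (math.isfinite(y[0]) and math.isfinite(y[14]) and math.isfinite(y[15])):
            status = b + 1
            break
    if status == 0:
        out[k, 0] = total_steps * dt
        out[k, 1] = y[0]
        out[k, 2] = y[14]
        out[k, 3] = y[15]
        out[k, 4] = y[16]
        k += 1
    return out[:k], snaps, y, status
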