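"""Human ventricular myocyte electrophysiology.

Implements the 2006-generation human ventricular ionic model (twelve
sarcolemmal currents, dyadic-subspace Ca handling with an adapting release
channel) for the three transmural variants, in its steep-APD-restitution
parameterization (maximum dynamic restitution slope ~1.8), which is the regime
in which rapid pacing produces electrical alternans.

Membrane potential follows ``dV/dt = -(I_ion + I_stim)`` with the twelve
currents expressed per unit membrane capacitance (A/F). Sarcoplasmic-reticulum
Ca cycling uses the leak/uptake/release/transfer fluxes

    I_leak = V_leak (Ca_SR - Ca_i)
    I_up   = V_maxup / (1 + K_up^2 / Ca_i^2)
    I_rel  = V_rel O (Ca_SR - Ca_ss)
    I_xfer = V_xfer (Ca_ss - Ca_i)

with ``O`` the open fraction of the release channel. The free cytosolic Ca
equation is the total-Ca balance divided through the instantaneous buffering
factor of the rapid-buffering approximation.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
from scipy.integrate import solve_ivp

from . import _ionic_core as core
from .datatypes import CaTransient, PacedTraces

CELL_VARIANTS = ("endo", "mid", "epi")

#: resting state of the published formulation (all variants start here)
RESTING_STATE = np.array([
    -86.2,            # V (mV)
    0.0, 0.75, 0.75,  # m h j
    0.0, 1.0, 1.0, 1.0,  # d f f2 fcass
    0.0, 1.0,         # r s
    0.0, 1.0, 0.0,    # xr1 xr2 xs
    1.0,              # rbar
    7.0e-5, 1.3, 7.0e-5,  # Cai CaSR Cass (mM)
    7.67, 138.3,      # Nai Ki (mM)
])

_CURRENT_NAMES = ("I_Na", "I_K1", "I_to", "I_Kr", "I_Ks", "I_CaL",
                  "I_NaCa", "I_NaK", "I_pCa", "I_pK", "I_bCa", "I_bNa")


@dataclass(frozen=True)
class IonicParams:
    """Full parameter set of the ionic stage (one transmural variant)."""

    cell_variant: str
    restitution_variant: str

    g_na: float
    g_k1: float
    g_to: float
    g_kr: float
    g_ks: float
    g_cal: float
    k_naca: float
    p_nak: float
    g_pca: float
    g_pk: float
    g_bca: float
    g_bna: float

    v_maxup: float
    k_up: float
    v_rel: float
    v_leak: float
    v_xfer: float

    c_m: float
    v_c: float
    v_sr: float
    v_ss: float
    faraday: float

    ko: float
    nao: float
    cao: float

    endo_s_gate: int
    tauf_plateau_factor: float
    tauf_recovery_factor: float
    tauf2_recovery_factor: float

    buf_c: float
    k_buf_c: float
    buf_sr: float
    k_buf_sr: float
    buf_ss: float
    k_buf_ss: float

    k1_prime: float
    k2_prime: float
    k3: float
    k4: float
    ec50_sr: float
    max_sr: float
    min_sr: float

    k_pca: float
    p_kna: float
    km_nai: float
    km_ca: float
    k_sat: float
    gamma_naca: float
    km_k: float
    km_na: float

    def __post_init__(self):
        if self.cell_variant not in CELL_VARIANTS:
            raise ValueError(f"cell_variant must be one of {CELL_VARIANTS}")
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, float) and v < 0:
                raise ValueError(f"{f.name} must be non-negative, got {v}")
        # conductances may be zeroed (current-isolation experiments); the
        # geometric/physical constants may not
        for name in ("c_m", "v_c", "v_sr", "v_ss", "faraday", "k_up"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    def to_vector(self) -> np.ndarray:
        """Pack into the flat vector consumed by the compiled kernels."""
        p = np.empty(core.NPARAM)
        p[core.P_GNA] = self.g_na
        p[core.P_GK1] = self.g_k1
        p[core.P_GTO] = self.g_to
        p[core.P_GKR] = self.g_kr
        p[core.P_GKS] = self.g_ks
        p[core.P_GCAL] = self.g_cal
        p[core.P_KNACA] = self.k_naca
        p[core.P_PNAK] = self.p_nak
        p[core.P_GPCA] = self.g_pca
        p[core.P_GPK] = self.g_pk
        p[core.P_GBCA] = self.g_bca
        p[core.P_GBNA] = self.g_bna
        p[core.P_VMAXUP] = self.v_maxup
        p[core.P_KUP] = self.k_up
        p[core.P_VREL] = self.v_rel
        p[core.P_VLEAK] = self.v_leak
        p[core.P_VXFER] = self.v_xfer
        p[core.P_CM] = self.c_m
        p[core.P_VC] = self.v_c
        p[core.P_VSR] = self.v_sr
        p[core.P_VSS] = self.v_ss
        p[core.P_F] = self.faraday
        p[core.P_KO] = self.ko
        p[core.P_NAO] = self.nao
        p[core.P_CAO] = self.cao
        p[core.P_ENDO_S] = float(self.endo_s_gate)
        p[core.P_TAUF_FAC] = self.tauf_plateau_factor
        p[core.P_TAUF_REC] = self.tauf_recovery_factor
        p[core.P_TAUF2_REC] = self.tauf2_recovery_factor
        p[core.P_BUFC] = self.buf_c
        p[core.P_KBUFC] = self.k_buf_c
        p[core.P_BUFSR] = self.buf_sr
        p[core.P_KBUFSR] = self.k_buf_sr
        p[core.P_BUFSS] = self.buf_ss
        p[core.P_KBUFSS] = self.k_buf_ss
        p[core.P_K1P] = self.k1_prime
        p[core.P_K2P] = self.k2_prime
        p[core.P_K3] = self.k3
        p[core.P_K4] = self.k4
        p[core.P_EC] = self.ec50_sr
        p[core.P_MAXSR] = self.max_sr
        p[core.P_MINSR] = self.min_sr
        p[core.P_KPCA] = self.k_pca
        p[core.P_PKNA] = self.p_kna
        p[core.P_KMNAI] = self.km_nai
        p[core.P_KMCA] = self.km_ca
        p[core.P_KSAT] = self.k_sat
        p[core.P_GAMMA] = self.gamma_naca
        p[core.P_KMK] = self.km_k
        p[core.P_KMNA] = self.km_na
        return p

    @classmethod
    def from_file(cls, path) -> "IonicParams":
        """Read a key=value parameter file (one cell variant per file)."""
        kv = _read_kv(path)
        kwargs = {}
        for f in fields(cls):
            if f.name not in kv:
                raise KeyError(f"{path}: missing parameter '{f.name}'")
            raw = kv[f.name]
            if f.name in ("cell_variant", "restitution_variant"):
                kwargs[f.name] = raw
            elif f.name == "endo_s_gate":
                kwargs[f.name] = int(float(raw))
            else:
                kwargs[f.name] = float(raw)
        return cls(**kwargs)

    @classmethod
    def for_variant(cls, variant: str) -> "IonicParams":
        """Packaged steep-restitution parameter set for one variant."""
        if variant not in CELL_VARIANTS:
            raise ValueError(f"unknown cell variant {variant!r}")
        ref = importlib.resources.files("ecalt.data") / f"ionic_{variant}.params"
        with importlib.resources.as_file(ref) as path:
            return cls.from_file(path)

    def with_baseline_restitution(self) -> "IonicParams":
        """The flat-restitution (slope ~1.1) parameterization of the same cell.

        Provided for restitution-slope comparisons; the package default is the
        steep set.
        """
        g_ks = 0.098 if self.cell_variant == "mid" else 0.392
        return replace(self, restitution_variant="baseline_1.1",
                       g_kr=0.153, g_ks=g_ks, g_pca=0.1238, g_pk=0.0146,
                       tauf_plateau_factor=1.0, tauf_recovery_factor=1.0,
                       tauf2_recovery_factor=1.0)


def _read_kv(path) -> dict:
    out = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, val = (s.strip() for s in line.split("=", 1))
        out[key] = val
    return out


@dataclass(frozen=True)
class StimulusProtocol:
    """Periodic current-pulse pacing."""

    bcl: float                 # basic cycle length (ms)
    n_beats: int = 30
    amplitude: float = -80.0   # A/F, negative = depolarizing
    duration: float = 1.0      # ms

    def __post_init__(self):
        if not self.bcl > self.duration > 0:
            raise ValueError("require BCL > duration > 0")
        if self.n_beats < 1:
            raise ValueError("n_beats must be >= 1")


@dataclass
class IonicState:
    """Named view of the flat 19-entry state vector."""

    y: np.ndarray

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        if self.y.shape != (core.NSTATE,):
            raise ValueError(f"state vector must have {core.NSTATE} entries")
        gates = self.y[1:14]
        if np.any(gates < -1e-12) or np.any(gates > 1 + 1e-12):
            raise ValueError("gating variables must lie in [0, 1]")
        if np.any(self.y[14:19] < 0):
            raise ValueError("concentrations must be non-negative")

    @classmethod
    def resting(cls) -> "IonicState":
        return cls(RESTING_STATE.copy())

    @property
    def vm(self): return self.y[0]
    @property
    def gates(self): return self.y[1:14]
    @property
    def cai(self): return self.y[14]
    @property
    def casr(self): return self.y[15]
    @property
    def cass(self): return self.y[16]
    @property
    def nai(self): return self.y[17]
    @property
    def ki(self): return self.y[18]

def ryr_open_fraction(state: IonicState, params: IonicParams) -> float:
    return float(core.ryr_open_fraction(state.cass, state.casr, state.y[13],
                                        params.to_vector()))


def sr_fluxes(state: IonicState, params: IonicParams):
    """SR Ca fluxes (I_leak, I_up, I_rel, I_xfer), all in mM/ms.

    ``I_up`` tends to 0 in the Ca_i -> 0 limit (no division fault).
    """
    p = params.to_vector()
    O = core.ryr_open_fraction(state.cass, state.casr, state.y[13], p)
    return core.sr_fluxes_core(state.cai, state.casr, state.cass, O, p)


def total_ionic_current(state: IonicState, params: IonicParams):
    """Sum of the twelve sarcolemmal currents (A/F) and the per-current
    breakdown as an ordered dict."""
    cur = np.empty(12)
    tot = core.currents(state.y, params.to_vector(), cur)
    if not np.all(np.isfinite(cur)):
        bad = [n for n, c in zip(_CURRENT_NAMES, cur) if not np.isfinite(c)]
        raise FloatingPointError(f"non-finite current(s): {', '.join(bad)}")
    return float(tot), dict(zip(_CURRENT_NAMES, cur))


def derivatives(state: IonicState, t: float, params: IonicParams,
                stim: StimulusProtocol | None = None) -> np.ndarray:
    """Full right-hand side d(state)/dt at time ``t`` (ms).

    The stimulus current is applied iff ``t mod BCL`` falls inside the pulse.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    istim = 0.0
    if stim is not None and (t % stim.bcl) < stim.duration:
        istim = stim.amplitude
    dy = np.empty(core.NSTATE)
    core.rhs(state.y, params.to_vector(), istim, dy)
    if not np.all(np.isfinite(dy)):
        _, breakdown = total_ionic_current(state, params)  # names the culprit
        raise FloatingPointError("non-finite derivative")
    return dy


def run_paced(params: IonicParams, protocol: StimulusProtocol,
              dt_out: float = 1.0, solver: str = "fixed",
              dt: float = 0.02, rtol: float = 1e-6,
              y0: np.ndarray | None = None) -> PacedTraces:
    """Integrate a paced stimulus train from rest.

    Parameters
    ----------
    solver:
        ``"fixed"`` (default): compiled fixed-step integrator, forward Euler
        with Rush-Larsen exponential gate updates at step ``dt``.
        ``"adaptive"``: stiff adaptive reference (LSODA), integrated beat by
        beat with the stimulus window as an exact segment boundary.
    dt_out:
        Output sampling interval in ms.
    """
    p = params.to_vector()
    y0 = RESTING_STATE.copy() if y0 is None else np.asarray(y0, dtype=float).copy()
    if solver == "fixed":
        out, snaps, yf, status = core.run_fixed(
            y0, p, protocol.bcl, protocol.n_beats, dt, dt_out,
            protocol.amplitude, protocol.duration)
        if status != 0:
            raise RuntimeError(
                f"fixed-step integration diverged in beat {status} "
                f"(t ~ {status * protocol.bcl:.0f} ms)")
        return PacedTraces(dt=dt_out, vm=out[:, 1].copy(), cai=out[:, 2].copy(),
                           casr=out[:, 3].copy(), cass=out[:, 4].copy(),
                           bcl=protocol.bcl, n_beats=protocol.n_beats,
                           snapshots=snaps, final_state=yf)
    if solver == "adaptive":
        return _run_adaptive(p, protocol, dt_out, rtol, y0)
    raise ValueError(f"unknown solver {solver!r}")


def _run_adaptive(p, protocol, dt_out, rtol, y0) -> PacedTraces:
    dy = np.empty(core.NSTATE)

    def make_rhs(istim):
        def f(t, y):
            core.rhs(y, p, istim, dy)
            return dy.copy()
        return f

    f_stim = make_rhs(protocol.amplitude)
    f_free = make_rhs(0.0)
    n_per_beat = int(round(protocol.bcl / dt_out))
    n_total = n_per_beat * protocol.n_beats + 1
    ys = np.empty((core.NSTATE, n_total))
    snaps = np.empty((protocol.n_beats, core.NSTATE))
    y = y0
    atol = np.full(core.NSTATE, 1e-8)
    atol[0] = 1e-6
    for b in range(protocol.n_beats):
        snaps[b] = y
        t0 = b * protocol.bcl
        t_split = t0 + protocol.duration
        grid = t0 + np.arange(n_per_beat) * dt_out
        sol1 = solve_ivp(f_stim, (t0, t_split), y, method="LSODA",
                         rtol=rtol, atol=atol, dense_output=True,
                         max_step=protocol.duration / 4)
        if not sol1.success:
            raise RuntimeError(f"adaptive solver failed in beat {b + 1} (stimulus)")
        sol2 = solve_ivp(f_free, (t_split, t0 + protocol.bcl), sol1.y[:, -1],
                         method="LSODA", rtol=rtol, atol=atol, dense_output=True)
        if not sol2.success:
            raise RuntimeError(
                f"adaptive solver failed in beat {b + 1} at t={sol2.t[-1]:.1f} ms")
        in_pulse = grid < t_split
        cols = slice(b * n_per_beat, (b + 1) * n_per_beat)
        block = np.empty((core.NSTATE, n_per_beat))
        if in_pulse.any():
            block[:, in_pulse] = sol1.sol(grid[in_pulse])
        block[:, ~in_pulse] = sol2.sol(grid[~in_pulse])
        ys[:, cols] = block
        y = sol2.y[:, -1]
    ys[:, -1] = y
    return PacedTraces(dt=dt_out, vm=ys[0].copy(), cai=ys[14].copy(),
                       casr=ys[15].copy(), cass=ys[16].copy(),
                       bcl=protocol.bcl, n_beats=protocol.n_beats,
                       snapshots=snaps, final_state=y.copy())
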