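"""Cross-bridge myofilament mechanics driven by a cytosolic Ca transient.

The contractile machinery is a regulatory-unit / cross-bridge cycle:

    N_xb  <-- K_pn (TCa_tot)^-7.5 --  P_xb  -- f_appT -->  XB_PreR  -- h_fT -->  XB_PostR
          --  K_np (TCa_tot)^7.5  -->       <-- g_appT --           <-- h_bT --
                                                  (detachment g_xbT, consumes ATP)

``N_xb``/``P_xb`` are non-permissive/permissive regulatory conformations;
``XB_PreR``/``XB_PostR`` are the pre- and post-rotation strongly-bound states.
Steep activation comes from the troponin-Ca signal raised to an effective
Hill exponent of 7.5 (implemented as the published square-root-of-15th-power
form). The attached states carry mean-strain ODEs; normalized active force is

    F_active = SOVF_thick(SL) * (xXB_PreR XB_PreR + xXB_PostR XB_PostR)
               / (x_0 * XB_PostR_max)

the contractile ATP consumption rate is ``g_xbT * XB_PostR * SOVF_thick`` and
sarcomere length follows the integrated Newtonian balance

    dSL/dt = (Integral_Force + (SL_0 - SL) * viscosity) / mass.

Loads are applied in the afterloaded-twitch convention: the sarcomere rests at
SL_0 against a rigid stop and begins to shorten once developed tension exceeds
the afterload; a 1000 kPa afterload is never exceeded, which realizes the
pseudo-isometric condition. An exact isometric clamp (dSL/dt = 0) is also
available.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, fields, replace

import numpy as np
from scipy.linalg import null_space

from . import _mech_core as core
from .datatypes import CaTransient
from .ionic import _read_kv

__all__ = [
    "MechParams", "MechState", "LoadCondition", "MechTraces",
    "single_overlap_fraction", "active_force", "atp_rate",
    "xb_transitions", "sl_dynamics", "run_mechanics",
    "xb_steady_state",
]


@dataclass(frozen=True)
class MechParams:
    """Myofilament parameters (lengths um, rates ms^-1, temp C)."""

    x_0: float
    sl_0: float
    sl_min: float
    sl_max: float
    sl_rest: float
    len_thin: float
    len_thick: float
    len_hbare: float

    f_app: float
    g_app: float
    h_f: float
    h_b: float
    g_xb: float
    temp_c: float
    q_fapp: float
    q_gapp: float
    q_hf: float
    q_hb: float
    q_gxb: float

    k_np: float
    k_pn: float
    q_knp: float
    q_kpn: float
    perm50: float
    n_perm: float

    k_on: float
    k_off_l: float
    k_off_h: float
    q_kon: float
    q_koff: float

    g_slmod: float
    h_fmdc: float
    sigma_p: float
    sigma_n: float
    x_psi: float
    species_scale: float

    p_con_t: float
    p_exp_t: float
    sl_collagen: float
    p_con_c: float
    p_exp_c: float

    mass: float
    viscosity: float
    rate_cap: float
    force_scale: float

    def __post_init__(self):
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be non-negative")
        if not self.sl_min <= self.sl_0 <= self.sl_max:
            raise ValueError("require sl_min <= sl_0 <= sl_max")
    def to_vector(self) -> np.ndarray:
        p = np.empty(core.NPARAM)
        p[core.M_X0] = self.x_0
        p[core.M_SL0] = self.sl_0
        p[core.M_SLMIN] = self.sl_min
        p[core.M_SLMAX] = self.sl_max
        p[core.M_SLREST] = self.sl_rest
        p[core.M_LTHIN] = self.len_thin
        p[core.M_LTHICK] = self.len_thick
        p[core.M_LHBARE] = self.len_hbare
        p[core.M_FAPP] = self.f_app
        p[core.M_GAPP] = self.g_app
        p[core.M_HF] = self.h_f
        p[core.M_HB] = self.h_b
        p[core.M_GXB] = self.g_xb
        p[core.M_TMPC] = self.temp_c
        p[core.M_QFAPP] = self.q_fapp
        p[core.M_QGAPP] = self.q_gapp
        p[core.M_QHF] = self.q_hf
        p[core.M_QHB] = self.q_hb
        p[core.M_QGXB] = self.q_gxb
        p[core.M_KNP] = self.k_np
        p[core.M_KPN] = self.k_pn
        p[core.M_QKNP] = self.q_knp
        p[core.M_QKPN] = self.q_kpn
        p[core.M_PERM50] = self.perm50
        p[core.M_NPERM] = self.n_perm
        p[core.M_KON] = self.k_on
        p[core.M_KOFFL] = self.k_off_l
        p[core.M_KOFFH] = self.k_off_h
        p[core.M_QKON] = self.q_kon
        p[core.M_QKOFF] = self.q_koff
        p[core.M_GSLMOD] = self.g_slmod
        p[core.M_HFMDC] = self.h_fmdc
        p[core.M_SIGMAP] = self.sigma_p
        p[core.M_SIGMAN] = self.sigma_n
        p[core.M_XPSI] = self.x_psi
        p[core.M_SPECIES] = self.species_scale
        p[core.M_PCONT] = self.p_con_t
        p[core.M_PEXPT] = self.p_exp_t
        p[core.M_SLC] = self.sl_collagen
        p[core.M_PCONC] = self.p_con_c
        p[core.M_PEXPC] = self.p_exp_c
        p[core.M_MASS] = self.mass
        p[core.M_VISC] = self.viscosity
        p[core.M_FSCALE] = self.force_scale
        p[core.M_RATECAP] = self.rate_cap
        return p

    @classmethod
    def from_file(cls, path) -> "MechParams":
        kv = _read_kv(path)
        kwargs = {}
        for f in fields(cls):
            if f.name not in kv:
                raise KeyError(f"{path}: missing parameter '{f.name}'")
            kwargs[f.name] = float(kv[f.name])
        return cls(**kwargs)

    @classmethod
    def default(cls) -> "MechParams":
        ref = importlib.resources.files("ecalt.data") / "myofilament.params"
        with importlib.resources.as_file(ref) as path:
            return cls.from_file(path)

    @property
    def xb_postr_max(self) -> float:
        """Post-rotation duty fraction under optimal conditions (Eq. normalizer)."""
        return float(core.ss_postr_max(self.to_vector()))


@dataclass
class MechState:
    """Named mechanics state; occupancies must conserve to 1."""

    n_xb: float
    p_xb: float
    xb_prer: float
    xb_postr: float
    x_prer: float
    x_postr: float
    tn_ca_l: float
    tn_ca_h: float
    sl: float
    intf: float = 0.0

    def __post_init__(self):
        occ = (self.n_xb, self.p_xb, self.xb_prer, self.xb_postr)
        if any(o < -1e-12 or o > 1 + 1e-12 for o in occ):
            raise ValueError("occupancies must lie in [0, 1]")
        if abs(sum(occ) - 1.0) > 1e-9:
            raise ValueError("occupancies must sum to 1 (within 1e-9)")
        for name in ("tn_ca_l", "tn_ca_h"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")

    def to_vector(self) -> np.ndarray:
        return np.array([self.n_xb, self.p_xb, self.xb_prer, self.xb_postr,
                         self.x_prer, self.x_postr, self.tn_ca_l, self.tn_ca_h,
                         self.sl, self.intf])

    @classmethod
    def from_vector(cls, y) -> "MechState":
        return cls(*[float(v) for v in y])

    @classmethod
    def resting(cls, params: MechParams, ca: float = 0.1) -> "MechState":
        """Approximate rest state at diastolic Ca (uM); settle before use."""
        p = params.to_vector()
        q = (params.temp_c - 37.0) / 10.0
        kon = params.k_on * params.q_kon ** q
        tl = kon * ca / (kon * ca + params.k_off_l * params.q_koff ** q)
        th = kon * ca / (kon * ca + params.k_off_h * params.q_koff ** q)
        return cls(n_xb=0.99, p_xb=0.01, xb_prer=0.0, xb_postr=0.0,
                   x_prer=0.0, x_postr=params.x_0, tn_ca_l=tl, tn_ca_h=th,
                   sl=params.sl_0, intf=0.0)


@dataclass(frozen=True)
class LoadCondition:
    """External load applied to the cell."""

    mode: str = "isotonic"       # "isotonic" (afterloaded) or "isometric_clamp"
    afterload: float = 10.0      # kPa
    preload: float | None = None  # kPa; None = passive force at SL_0

    def __post_init__(self):
        if self.mode not in ("isotonic", "isometric_clamp"):
            raise ValueError(f"unknown load mode {self.mode!r}")
        if self.mode == "isotonic" and not self.afterload > 0:
            raise ValueError("isotonic afterload must be > 0 kPa")


@dataclass
class MechTraces:
    """Mechanics output sampled on the Ca-transient grid."""

    dt: float
    tension: np.ndarray       # developed tension (kPa, >= 0)
    force_norm: np.ndarray    # normalized active force (dimensionless)
    atp: np.ndarray           # normalized ATP consumption rate (ms^-1)
    sl: np.ndarray            # sarcomere length (um)
    eq_length: np.ndarray     # SL / SL_0
    bcl: float
    n_beats: int
    final_state: MechState = field(repr=False, default=None)

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.tension.size) * self.dt

    def beat_slice(self, beat: int) -> slice:
        if not 1 <= beat <= self.n_beats:
            raise ValueError(f"beat {beat} outside 1..{self.n_beats}")
        i0 = int(round((beat - 1) * self.bcl / self.dt))
        i1 = int(round(beat * self.bcl / self.dt))
        return slice(i0, min(i1, self.tension.size))


def single_overlap_fraction(sl: float, params: MechParams) -> float:
    """Thick-filament single-overlap fraction SOVF_thick(SL), in [0, 1]."""
    if not params.sl_min <= sl <= params.sl_max:
        raise ValueError(
            f"SL={sl} um outside [{params.sl_min}, {params.sl_max}] um")
    thick, _ = core.overlap_fractions(sl, params.to_vector())
    return float(min(thick, 1.0))


def active_force(state: MechState, params: MechParams):
    """Normalized active force and developed tension (kPa)."""
    p = params.to_vector()
    f = float(core.active_force_norm(state.to_vector(), p, core.ss_postr_max(p)))
    return f, f * params.force_scale


def atp_rate(state: MechState, params: MechParams) -> float:
    """Normalized contractile ATP consumption rate (>= 0)."""
    return float(core.atp_rate_norm(state.to_vector(), params.to_vector()))


def xb_transitions(state: MechState, ca: float, params: MechParams,
                   dsl_dt: float = 0.0) -> np.ndarray:
    """Derivatives of occupancies, strains and troponin Ca at cytosolic ``ca`` (uM).

    Occupancy derivatives sum to zero exactly (conservation).
    """
    if ca < 0:
        raise ValueError("Ca must be >= 0")
    return core.strain_rates(state.to_vector(), ca, dsl_dt, params.to_vector())


def sl_dynamics(state: MechState, load: LoadCondition, params: MechParams) -> float:
    """Shortening velocity dSL/dt (um/ms) under the integrated force balance."""
    if load.mode == "isometric_clamp":
        return 0.0
    return (state.intf + (params.sl_0 - state.sl) * params.viscosity) / params.mass


def xb_steady_state(ca: float, params: MechParams, sl: float | None = None):
    """Independent equilibrium of the 4-state occupancy chain at clamped Ca/SL.

    Solves the null space of the transition-rate matrix (strains held at their
    fixed point x_prer = 0, x_postr = x_0) — used as an oracle against the
    integrated dynamics.
    """
    sl = params.sl_0 if sl is None else sl
    p = params.to_vector()
    q = (params.temp_c - 37.0) / 10.0
    kon = params.k_on * params.q_kon ** q
    tl = kon * ca / (kon * ca + params.k_off_l * params.q_koff ** q)
    th = kon * ca / (kon * ca + params.k_off_h * params.q_koff ** q)
    thick, thin = core.overlap_fractions(sl, p)
    trop_reg = max((1.0 - thin) * tl + thin * th, 1e-8)
    permtot = np.sqrt(1.0 / (1.0 + (params.perm50 / trop_reg) ** params.n_perm))
    inprmt = min(1.0 / permtot, 100.0)

    knp = params.k_np * params.q_knp ** q * permtot
    kpn = params.k_pn * params.q_kpn ** q * inprmt
    sp = params.species_scale
    fapp = params.f_app * sp * params.q_fapp ** q
    gapp = params.g_app * sp * params.q_gapp ** q * (1 + (1 - thick) * params.g_slmod)
    hf = params.h_f * sp * params.q_hf ** q          # unstrained: modifiers = 1
    hb = params.h_b * sp * params.q_hb ** q
    gxb = params.g_xb * sp * params.q_gxb ** q

    A = np.array([
        [-knp,  kpn,        0.0,  0.0],
        [knp, -(kpn + fapp), gapp, gxb],
        [0.0,  fapp, -(gapp + hf), hb],
        [0.0,  0.0,   hf, -(hb + gxb)],
    ])
    ns = null_space(A)
    v = ns[:, 0]
    v = v / v.sum()
    return {"n_xb": v[0], "p_xb": v[1], "xb_prer": v[2], "xb_postr": v[3]}


def run_mechanics(ca: CaTransient, load: LoadCondition, params: MechParams,
                  dt: float = 0.1, settle_ms: float = 1000.0,
                  y0: MechState | None = None) -> MechTraces:
    """Integrate the mechanics stage over a Ca transient (one-way coupling).

    The cross-bridge/length ODEs run at fixed step ``dt`` with the Ca drive
    linearly interpolated between samples; before the drive starts the state is
    settled for ``settle_ms`` at the first Ca sample.
    """
    if ca.dt <= 0 or ca.duration < ca.bcl:
        raise ValueError("Ca transient must cover at least one beat")
    p = params.to_vector()
    mode = core.MODE_CLAMP if load.mode == "isometric_clamp" else core.MODE_ISOTONIC
    load_norm = (load.afterload / params.force_scale) if mode == core.MODE_ISOTONIC else 0.0
    if load.preload is None:
        pre = float(core.passive_force(params.sl_0, p))
    else:
        pre = load.preload / params.force_scale

    state = MechState.resting(params, float(ca.ca[0])) if y0 is None else y0
    y = state.to_vector()
    if settle_ms > 0:
        const = np.full(max(int(settle_ms / ca.dt), 2), float(ca.ca[0]))
        _, y, status = core.run_mech(const, ca.dt, dt, p, y, mode, load_norm, pre)
        if status:
            raise RuntimeError(f"mechanics settling diverged at step {status}")
    out, y, status = core.run_mech(ca.ca.astype(float), ca.dt, dt, p, y,
                                   mode, load_norm, pre)
    if status:
        raise RuntimeError(
            f"mechanics integration diverged at t ~ {status * dt:.1f} ms")
    dev = out[:, 1]
    tension = np.clip(dev, 0.0, None) * params.force_scale
    sl = out[:, 3]
    return MechTraces(dt=ca.dt, tension=tension, force_norm=out[:, 0].copy(),
                      atp=out[:, 2].copy(), sl=sl.copy(),
                      eq_length=sl / params.sl_0, bcl=ca.bcl, n_beats=ca.n_beats,
                      final_state=MechState.from_vector(y))
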