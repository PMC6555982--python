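"""Per-beat scalar metrics, alternans detection and sweep-level curves.

Metric conventions follow the summary-table layout of rapid-pacing studies:
APD (action potential duration at a configurable repolarization fraction),
Ca_max/Ca_min of the cytosolic transient, systolic/diastolic tension (ST/DT),
time to peak tension (TPT), systolic/diastolic equivalent cell length (SL/DL),
time to peak (minimum) length (TPL), peak/minimum contractile ATP rate and
time of peak ATP (TPA). Times are reported relative to the stimulus of the
beat; diastolic values are taken in the final 5% of the beat window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BeatMetrics", "AlternansThresholds", "AlternansReport",
    "apd", "beat_metrics", "detect_alternans",
    "restitution_curve", "tension_amplitude_curve",
]

DIASTOLIC_WINDOW = 0.05  # fraction of the beat used for diastolic sampling


@dataclass
class BeatMetrics:
    """Scalar summary of one beat (ms, uM, kPa, dimensionless lengths)."""

    beat_index: int
    captured: bool
    apd: float = np.nan
    ca_max: float = np.nan
    ca_min: float = np.nan
    st: float = np.nan
    dt: float = np.nan
    tpt: float = np.nan
    sl_sys: float = np.nan
    dl: float = np.nan
    tpl: float = np.nan
    atp_peak: float = np.nan
    atp_min: float = np.nan
    tpa: float = np.nan

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass(frozen=True)
class AlternansThresholds:
    """Detection thresholds; flags require |delta| strictly above these."""

    apd_ms: float = 2.0
    rel_amplitude: float = 0.02   # fraction of the mean transient amplitude


@dataclass
class AlternansReport:
    """Beat-29-vs-30 alternans calls for one (variant, BCL, load) run."""

    status: str = "ok"                 # "ok" or "block"
    electrical: bool = False
    delta_apd: float = np.nan
    ca: bool = False
    delta_ca_max: float = np.nan
    mechanical: bool = False
    delta_peak_tension: float = np.nan
    discordant: bool = False

    def as_dict(self) -> dict:
        d = dict(self.__dict__)
        for k, v in d.items():
            if isinstance(v, (np.bool_,)):
                d[k] = bool(v)
            elif isinstance(v, (np.floating,)):
                d[k] = float(v)
        return d


def apd(t: np.ndarray, vm: np.ndarray, fraction: float = 0.9,
        capture_vm: float = 0.0, min_upstroke: float = 5.0):
    """Action potential duration of one beat window.

    Measured from the instant of maximum upstroke velocity to the interpolated
    crossing of ``V_rest + (1 - fraction) (V_peak - V_rest)``. ``V_rest`` is
    the minimum potential of the window — robust against rapid pacing, where
    the stimulus can arrive before the previous beat is fully repolarized.

    Returns ``(apd_ms, captured)``; a beat whose peak never reaches
    ``capture_vm`` or whose maximum dV/dt stays below ``min_upstroke`` mV/ms
    after the stimulus is classified as not captured (blocked).
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    t = np.asarray(t, dtype=float)
    vm = np.asarray(vm, dtype=float)
    if t.size < 4:
        return np.nan, False
    dv = np.gradient(vm, t)
    iup = int(np.argmax(dv))
    vpeak = float(vm[iup:].max())
    if vpeak < capture_vm or dv[iup] < min_upstroke:
        return np.nan, False
    vrest = float(vm.min())
    thr = vrest + (1.0 - fraction) * (vpeak - vrest)
    ipk = iup + int(np.argmax(vm[iup:]))
    below = np.nonzero(vm[ipk:] < thr)[0]
    if below.size == 0:
        return np.nan, False
    i1 = ipk + int(below[0])
    # linear interpolation between the bracketing samples
    t_cross = t[i1 - 1] + (t[i1] - t[i1 - 1]) * (vm[i1 - 1] - thr) / (vm[i1 - 1] - vm[i1])
    return float(t_cross - t[iup]), True


def beat_metrics(beat_index: int, t: np.ndarray, vm: np.ndarray | None,
                 ca: np.ndarray | None = None, tension: np.ndarray | None = None,
                 atp: np.ndarray | None = None, eq_length: np.ndarray | None = None,
                 fraction: float = 0.9) -> BeatMetrics:
    """All per-beat metrics from aligned trace windows (any subset).

    ``t`` must start at the stimulus of the beat; electrical and mechanical
    arrays must share that time base. Metrics of absent traces stay NaN; a
    blocked beat keeps its electrical metrics undefined (never zero).
    """
    t = np.asarray(t, dtype=float)
    t0 = t[0]
    m = BeatMetrics(beat_index=beat_index, captured=True)
    if vm is not None:
        m.apd, m.captured = apd(t, vm, fraction)
    n_dia = max(int(round(t.size * (1 - DIASTOLIC_WINDOW))), 1)
    if ca is not None:
        m.ca_max = float(np.max(ca))
        m.ca_min = float(np.min(ca))
    if tension is not None:
        m.st = float(np.max(tension))
        m.dt = float(np.min(tension[n_dia:]))
        m.tpt = float(t[int(np.argmax(tension))] - t0)
    if eq_length is not None:
        m.sl_sys = float(np.min(eq_length))
        m.dl = float(eq_length[-1])
        m.tpl = float(t[int(np.argmin(eq_length))] - t0)
    if atp is not None:
        m.atp_peak = float(np.max(atp))
        m.atp_min = float(np.min(atp))
        m.tpa = float(t[int(np.argmax(atp))] - t0)
    return m


def _alternating_component(x28, x29, x30):
    """Beat-to-beat alternation with linear drift removed.

    Slow accumulation (SR loading, ion drift) moves a metric monotonically
    across beats 28 -> 29 -> 30 while alternans flips its sign each beat; the
    half second-difference (x30 - 2 x29 + x28)/2 cancels a linear trend
    exactly and returns the signed alternation amplitude. Without beat-28
    information the plain difference x30 - x29 is used.
    """
    if x28 is None or not np.isfinite(x28):
        return x30 - x29
    return 0.5 * (x30 - 2.0 * x29 + x28)


def detect_alternans(m29: BeatMetrics, m30: BeatMetrics,
                     thresholds: AlternansThresholds | None = None,
                     m28: BeatMetrics | None = None) -> AlternansReport:
    """Beat-to-beat alternans calls from the two recorded steady-state beats.

    Electrical alternans: |APD(30) - APD(29)| above the APD threshold.
    Ca / tension alternans: peak difference above ``rel_amplitude`` of the
    mean transient amplitude. Discordant: electrical and Ca alternans of
    opposite sign (long-APD beat pairs with the small-Ca beat). When the
    preceding beat ``m28`` is supplied, each flag is decided on the
    drift-detrended alternation (half second-difference across beats
    28/29/30), which rejects monotone staircase drift that has not yet
    settled by beat 30.
    """
    thr = thresholds or AlternansThresholds()
    if not (m29.captured and m30.captured):
        return AlternansReport(status="block")
    if m28 is not None and not m28.captured:
        m28 = None
    rep = AlternansReport()
    rep.delta_apd = _alternating_component(
        None if m28 is None else m28.apd, m29.apd, m30.apd)
    rep.electrical = bool(abs(rep.delta_apd) > thr.apd_ms)
    if np.isfinite(m29.ca_max) and np.isfinite(m30.ca_max):
        rep.delta_ca_max = _alternating_component(
            None if m28 is None else m28.ca_max, m29.ca_max, m30.ca_max)
        amp = 0.5 * ((m29.ca_max - m29.ca_min) + (m30.ca_max - m30.ca_min))
        rep.ca = bool(abs(rep.delta_ca_max) > thr.rel_amplitude * amp)
    if np.isfinite(m29.st) and np.isfinite(m30.st):
        rep.delta_peak_tension = _alternating_component(
            None if m28 is None else m28.st, m29.st, m30.st)
        t_amp = 0.5 * ((m29.st - m29.dt) + (m30.st - m30.dt))
        rep.mechanical = bool(
            abs(rep.delta_peak_tension) > thr.rel_amplitude * t_amp)
    rep.discordant = bool(rep.electrical and rep.ca
                          and rep.delta_apd * rep.delta_ca_max < 0)
    return rep


def restitution_curve(sweep, fraction: float = 0.9):
    """APD-vs-BCL table for both recorded beats plus a maximum-slope estimate.

    The slope is taken on the pre-alternans (1:1) branch by finite differences
    of APD(30) against the diastolic interval DI = BCL - APD(29).
    """
    rows = []
    for (variant, bcl), rec in sweep.electrical_records():
        m29, m30 = rec["metrics"][29], rec["metrics"][30]
        rows.append({
            "variant": variant, "bcl": bcl,
            "apd29": m29.apd, "apd30": m30.apd,
            "captured": m29.captured and m30.captured,
            "alternans": rec["alternans"].electrical,
        })
    df = pd.DataFrame(rows).sort_values(["variant", "bcl"], ascending=[True, False])
    if df["captured"].sum() < 3:
        raise ValueError("restitution slope needs at least 3 captured BCLs")
    slopes = {}
    for variant, sub in df.groupby("variant"):
        branch = sub[sub["captured"] & ~sub["alternans"]]
        di = branch["bcl"].to_numpy() - branch["apd29"].to_numpy()
        apd30 = branch["apd30"].to_numpy()
        if di.size >= 2:
            order = np.argsort(di)
            d = np.diff(apd30[order]) / np.diff(di[order])
            slopes[variant] = float(np.nanmax(d)) if d.size else np.nan
        else:
            slopes[variant] = np.nan
    return df.reset_index(drop=True), slopes


def tension_amplitude_curve(sweep, load_kpa: float):
    """Beat-30 tension amplitude (ST - DT) and peak vs BCL for one load.

    Returns the per-BCL table and, per variant, the amplitude-maximizing BCL.
    When beats 29/30 alternate the table carries both beats' amplitudes; the
    argmax uses beat 30, matching the recorded-beat convention.
    """
    rows = []
    for (variant, bcl, load), rec in sweep.mechanical_records():
        if abs(load - load_kpa) > 1e-9:
            continue
        m29, m30 = rec["metrics"][29], rec["metrics"][30]
        rows.append({
            "variant": variant, "bcl": bcl,
            "amplitude29": m29.st - m29.dt,
            "amplitude30": m30.st - m30.dt,
            "peak30": m30.st,
        })
    if not rows:
        raise ValueError(f"no mechanics records at load {load_kpa} kPa")
    df = pd.DataFrame(rows).sort_values(["variant", "bcl"], ascending=[True, False])
    argmax = {v: float(sub.loc[sub["amplitude30"].idxmax(), "bcl"])
              for v, sub in df.groupby("variant")}
    return df.reset_index(drop=True), argmax
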