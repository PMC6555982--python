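"""Experiment orchestration: one-way coupled runs, BCL sweeps, onset refinement.

The experiment design: for each (cell variant, BCL, load) combination, pace the
ionic model for ``n_beats`` stimuli from rest, hand its cytosolic Ca transient
(uM) to the mechanics stage over the identical time base (strictly one-way),
and summarize the recorded steady-state beats (by default 29 and 30). Each
combination starts fresh from the published resting state, so results are
independent of execution order.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np

from .datatypes import CaTransient, PacedTraces
from .ionic import CELL_VARIANTS, IonicParams, StimulusProtocol, run_paced
from .metrics import (AlternansReport, AlternansThresholds, BeatMetrics,
                      beat_metrics, detect_alternans)
from .myofilament import LoadCondition, MechParams, MechTraces, run_mechanics

__all__ = ["SweepConfig", "CellRun", "SweepResult", "run_cell", "run_sweep",
           "refine_onset", "default_bcl_list"]


def default_bcl_list() -> list[float]:
    """1000 ms down to 220 ms in 30 ms decrements, plus the 200 ms endpoint."""
    return [float(b) for b in range(1000, 219, -30)] + [200.0]


def default_loads() -> tuple[LoadCondition, ...]:
    return (LoadCondition("isotonic", 0.6),
            LoadCondition("isotonic", 10.0),
            LoadCondition("isotonic", 1000.0))


@dataclass(frozen=True)
class SweepConfig:
    """Full description of a sweep experiment."""

    cell_variants: tuple[str, ...] = CELL_VARIANTS
    bcl_list: tuple[float, ...] = field(default_factory=lambda: tuple(default_bcl_list()))
    n_beats: int = 30
    record_beats: tuple[int, ...] = (29, 30)
    loads: tuple[LoadCondition, ...] = field(default_factory=default_loads)
    stim_amplitude: float = -80.0      # A/F
    stim_duration: float = 1.0         # ms
    solver: str = "fixed"
    dt: float = 0.02                   # ionic step (ms)
    dt_out: float = 1.0                # trace sampling (ms)
    mech_dt: float = 0.1               # mechanics step (ms)
    apd_fraction: float = 0.9
    thresholds: AlternansThresholds = field(default_factory=AlternansThresholds)
    continuation: bool = False         # sweep carries state across BCLs if True
    seed: int = 0                      # reserved; the pipeline is deterministic

    def __post_init__(self):
        unknown = set(self.cell_variants) - set(CELL_VARIANTS)
        if unknown:
            raise ValueError(f"unknown cell variants: {sorted(unknown)}")
        if min(self.bcl_list) < 150:
            raise ValueError("BCLs below 150 ms are outside the validated range")
        if not set(self.record_beats) <= set(range(1, self.n_beats + 1)):
            raise ValueError("record_beats must lie within 1..n_beats")

    def protocol(self, bcl: float) -> StimulusProtocol:
        return StimulusProtocol(bcl=bcl, n_beats=self.n_beats,
                                amplitude=self.stim_amplitude,
                                duration=self.stim_duration)


@dataclass
class CellRun:
    """All traces and per-beat summaries of one (variant, BCL) combination."""

    variant: str
    bcl: float
    electrical: PacedTraces
    ca: CaTransient
    mechanics: dict[float, MechTraces]              # keyed by afterload (kPa)
    metrics_electrical: dict[int, BeatMetrics]
    metrics: dict[float, dict[int, BeatMetrics]]    # [load][beat]
    alternans_electrical: AlternansReport
    alternans: dict[float, AlternansReport]


@dataclass
class SweepResult:
    """Per-combination metric records of a sweep."""

    config: SweepConfig
    electrical: dict = field(default_factory=dict)   # (variant, bcl) -> record
    mechanical: dict = field(default_factory=dict)   # (variant, bcl, load) -> record
    failures: dict = field(default_factory=dict)     # (variant, bcl) -> message

    def electrical_records(self):
        return iter(sorted(self.electrical.items()))

    def mechanical_records(self):
        return iter(sorted(self.mechanical.items()))

    def add(self, run: CellRun):
        self.electrical[(run.variant, run.bcl)] = {
            "metrics": run.metrics_electrical,
            "alternans": run.alternans_electrical,
        }
        for load, mm in run.metrics.items():
            self.mechanical[(run.variant, run.bcl, load)] = {
                "metrics": mm,
                "alternans": run.alternans[load],
            }


def _electrical_beat_metrics(tr: PacedTraces, beats, fraction) -> dict[int, BeatMetrics]:
    out = {}
    for b in beats:
        sl = tr.beat_slice(b)
        t = tr.time[sl]
        out[b] = beat_metrics(b, t, vm=tr.vm[sl], ca=tr.cai[sl] * 1e3,
                              fraction=fraction)
    return out


def run_cell(variant: str, bcl: float, config: SweepConfig | None = None,
             ionic_params: IonicParams | None = None,
             mech_params: MechParams | None = None,
             ca_override: CaTransient | None = None,
             y0=None) -> CellRun:
    """One fully coupled (variant, BCL) run across the configured loads.

    ``ca_override`` substitutes a saved or synthetic Ca transient for the
    electrical stage's output (the coupling is one-way, so mechanics driven
    from a file is bit-identical to the inline hand-off). ``y0`` overrides the
    electrical initial state (used by continuation sweeps).
    """
    config = config or SweepConfig()
    ip = ionic_params or IonicParams.for_variant(variant)
    mp = mech_params or MechParams.default()
    proto = config.protocol(bcl)
    tr = run_paced(ip, proto, dt_out=config.dt_out, solver=config.solver,
                   dt=config.dt, y0=y0)
    ca = ca_override if ca_override is not None else tr.ca_transient()

    b29, b30 = min(config.record_beats), max(config.record_beats)
    beats = tuple(sorted(set(config.record_beats) | ({b29 - 1} if b29 > 1 else set())))
    emetrics_all = _electrical_beat_metrics(tr, beats, config.apd_fraction)
    emetrics = {b: emetrics_all[b] for b in config.record_beats}
    e28 = emetrics_all.get(b29 - 1)
    ealt = detect_alternans(emetrics[b29], emetrics[b30], config.thresholds,
                            m28=e28)

    mech, mm, malt = {}, {}, {}
    for load in config.loads:
        m = run_mechanics(ca, load, mp, dt=config.mech_dt)
        mech[load.afterload] = m
        per_beat = {}
        for b in beats:
            sl = m.beat_slice(b)
            esl = tr.beat_slice(b)
            per_beat[b] = beat_metrics(
                b, m.time[sl], vm=tr.vm[esl], ca=ca.ca[sl],
                tension=m.tension[sl], atp=m.atp[sl], eq_length=m.eq_length[sl],
                fraction=config.apd_fraction)
        mm[load.afterload] = {b: per_beat[b] for b in config.record_beats}
        malt[load.afterload] = detect_alternans(per_beat[b29], per_beat[b30],
                                                config.thresholds,
                                                m28=per_beat.get(b29 - 1))
    return CellRun(variant=variant, bcl=bcl, electrical=tr, ca=ca,
                   mechanics=mech, metrics_electrical=emetrics, metrics=mm,
                   alternans_electrical=ealt, alternans=malt)


def run_sweep(config: SweepConfig | None = None, writer=None,
              progress=None) -> SweepResult:
    """Execute all (variant x BCL x load) combinations of the sweep.

    ``writer``, when given, is called with each finished :class:`CellRun`
    (used by the CLI to persist traces incrementally, so a crash loses at most
    one combination). Per-combination failures are recorded and the sweep
    continues.
    """
    config = config or SweepConfig()
    result = SweepResult(config=config)
    mp = MechParams.default()
    for variant in config.cell_variants:
        ip = IonicParams.for_variant(variant)
        bcls = (sorted(config.bcl_list, reverse=True) if config.continuation
                else config.bcl_list)
        y = None
        for bcl in bcls:
            t0 = time.perf_counter()
            try:
                run = run_cell(variant, bcl, config, ionic_params=ip,
                               mech_params=mp, y0=y)
                if config.continuation:
                    y = run.electrical.final_state
            except Exception as exc:  # record and continue
                result.failures[(variant, bcl)] = f"{type(exc).__name__}: {exc}"
                continue
            result.add(run)
            if writer is not None:
                writer(run)
            if progress is not None:
                progress(variant, bcl, time.perf_counter() - t0)
    return result


def _electrical_alternans_at(variant, bcl, config, ip, y0=None):
    """Alternans flag, capture status and final state at one BCL."""
    tr = run_paced(ip, config.protocol(bcl), dt_out=config.dt_out,
                   solver=config.solver, dt=config.dt, y0=y0)
    em = _electrical_beat_metrics(tr, config.record_beats, config.apd_fraction)
    b29, b30 = min(config.record_beats), max(config.record_beats)
    rep = detect_alternans(em[b29], em[b30], config.thresholds)
    return bool(rep.electrical), rep.status == "ok", tr.final_state


@dataclass
class OnsetResult:
    variant: str
    onset_bcl: float | None        # largest alternans-positive BCL found
    boundary_bcl: float | None     # largest BCL past the stable 1:1 regime
    resolution: float
    evaluations: int


def refine_onset(variant: str, config: SweepConfig | None = None,
                 resolution: float = 2.0, coarse_step: float = 30.0,
                 bcl_start: float = 1000.0, bcl_stop: float = 200.0,
                 ramp: bool = True) -> OnsetResult:
    """Largest BCL with beat-29/30 electrical alternans, to ``resolution`` ms.

    The default protocol is a descending pacing ramp: the coarse sweep steps
    down in ``coarse_step`` decrements carrying the cell state from one BCL to
    the next, so beats 29/30 sample the (near-)steady response rather than the
    start-up transient of a cold start. Once the stable 1:1 regime ends —
    alternans flags, or a stimulus fails to capture (rapid pacing can step
    straight into 2:2/2:1 behaviour across a narrow alternans window) — the
    1:1 boundary is bisected, each probe continuing from the nearest stable
    state above it. The result is the largest alternans-positive BCL seen;
    ``boundary_bcl`` reports the refined end of the 1:1 regime.

    ``ramp=False`` restarts every probe from rest instead (order-independent
    but transient-contaminated near the bifurcation).
    """
    config = config or SweepConfig()
    ip = IonicParams.for_variant(variant)
    n_eval = 0
    prev = None                 # last stable 1:1 BCL
    y_prev = None               # state entering `prev`
    y_stable = None             # state after pacing at `prev`
    first_pos = None
    best_alt = None
    y = None
    bcl = bcl_start
    while bcl >= bcl_stop - 1e-9:
        alt, captured, yf = _electrical_alternans_at(variant, bcl, config, ip,
                                                     y0=y if ramp else None)
        n_eval += 1
        if alt or not captured:
            first_pos = bcl
            if alt:
                best_alt = bcl
            break
        prev, y_prev, y_stable = bcl, y, yf
        if ramp:
            y = yf
        bcl -= coarse_step
    if first_pos is None:
        return OnsetResult(variant, None, None, resolution, n_eval)
    if prev is None:
        return OnsetResult(variant, best_alt, first_pos, resolution, n_eval)
    lo, hi = first_pos, prev        # lo past onset, hi stable 1:1
    anchor = y_stable               # ramp state after the last stable BCL
    while hi - lo > resolution:
        mid = round(0.5 * (hi + lo))
        alt, captured, yf = _electrical_alternans_at(
            variant, mid, config, ip, y0=anchor if ramp else None)
        n_eval += 1
        if alt or not captured:
            lo = mid
            if alt:
                best_alt = mid if best_alt is None else max(best_alt, mid)
        else:
            hi = mid
            anchor = yf
    return OnsetResult(variant, best_alt, lo, resolution, n_eval)
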