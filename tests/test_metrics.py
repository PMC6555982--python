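"""Metric extraction and alternans detection on synthetic waveforms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecalt.metrics import (AlternansThresholds, BeatMetrics, apd,
                           beat_metrics, detect_alternans, restitution_curve,
                           tension_amplitude_curve)


def square_ap(width, bcl=500.0, dt=0.5, v_rest=-85.0, v_peak=20.0, t_on=5.0):
    t = np.arange(0.0, bcl, dt)
    v = np.full_like(t, v_rest)
    v[(t >= t_on) & (t < t_on + width)] = v_peak
    return t, v


class TestApd:
    @pytest.mark.parametrize("width", [50.0, 120.0, 300.0])
    def test_square_pulse_apd_equals_width(self, width):
        t, v = square_ap(width)
        value, captured = apd(t, v, 0.9)
        assert captured
        assert value == pytest.approx(width, abs=1.0)

    def test_flat_trace_not_captured(self):
        t = np.arange(0.0, 500.0, 1.0)
        value, captured = apd(t, np.full_like(t, -85.0))
        assert not captured and np.isnan(value)

    def test_fraction_validation(self):
        t, v = square_ap(100.0)
        with pytest.raises(ValueError):
            apd(t, v, 1.5)

    def test_fraction_changes_duration_on_ramp(self):
        # triangular repolarization: APD50 < APD90
        t = np.arange(0.0, 400.0, 0.5)
        v = np.full_like(t, -85.0)
        up = (t >= 5) & (t < 10)
        v[up] = 20.0
        ramp = (t >= 10) & (t < 310)
        v[ramp] = 20.0 - (t[ramp] - 10.0) * (105.0 / 300.0)
        a50, _ = apd(t, v, 0.5)
        a90, _ = apd(t, v, 0.9)
        assert a50 < a90


class TestBeatMetrics:
    def test_sin_squared_tension_peak_time(self):
        t = np.arange(0.0, 400.0, 1.0)
        tension = np.where(t < 200.0, np.sin(np.pi * t / 200.0) ** 2, 0.0)
        m = beat_metrics(1, t, vm=None, tension=tension)
        assert m.tpt == pytest.approx(100.0, abs=1.0)
        assert m.st == pytest.approx(1.0, abs=1e-6)

    def test_constant_traces_degenerate(self):
        t = np.arange(0.0, 300.0, 1.0)
        const = np.full_like(t, 5.0)
        m = beat_metrics(1, t, vm=None, ca=const, tension=const, atp=const,
                         eq_length=const)
        assert m.st == m.dt
        assert m.ca_max == m.ca_min
        assert m.tpt == 0.0

    def test_time_base_offset_independent(self):
        t = np.arange(0.0, 400.0, 1.0)
        tension = np.where(t < 200.0, np.sin(np.pi * t / 200.0) ** 2, 0.0)
        m = beat_metrics(2, t + 8000.0, vm=None, tension=tension)
        assert m.tpt == pytest.approx(100.0, abs=1.0)

    def test_blocked_beat_metrics_undefined_not_zero(self):
        t = np.arange(0.0, 300.0, 1.0)
        v = np.full_like(t, -85.0)
        m = beat_metrics(1, t, vm=v)
        assert not m.captured
        assert np.isnan(m.apd)


def mk_metrics(beat, apd_val, ca_max=1.0, ca_min=0.1, st_val=50.0, dt_val=1.0,
               captured=True):
    return BeatMetrics(beat_index=beat, captured=captured, apd=apd_val,
                       ca_max=ca_max, ca_min=ca_min, st=st_val, dt=dt_val)


class TestDetectAlternans:
    def test_identical_beats_all_false(self):
        rep = detect_alternans(mk_metrics(29, 250.0), mk_metrics(30, 250.0))
        assert not (rep.electrical or rep.ca or rep.mechanical or rep.discordant)

    def test_large_apd_difference_flags(self):
        rep = detect_alternans(mk_metrics(29, 250.0), mk_metrics(30, 200.0))
        assert rep.electrical
        assert rep.delta_apd == pytest.approx(-50.0)

    def test_blocked_beat_reports_block(self):
        rep = detect_alternans(mk_metrics(29, np.nan, captured=False),
                               mk_metrics(30, 200.0))
        assert rep.status == "block"
        assert not rep.electrical

    def test_discordant_requires_opposite_phase(self):
        long_small_ca = mk_metrics(30, 260.0, ca_max=0.6)
        short_big_ca = mk_metrics(29, 200.0, ca_max=1.2)
        rep = detect_alternans(short_big_ca, long_small_ca)
        assert rep.discordant
        concordant = detect_alternans(mk_metrics(29, 200.0, ca_max=0.6),
                                      mk_metrics(30, 260.0, ca_max=1.2))
        assert not concordant.discordant

    def test_drift_rejected_with_beat28(self):
        m28, m29, m30 = (mk_metrics(b, a, st_val=s) for b, a, s in
                         [(28, 240.0, 40.0), (29, 245.0, 45.0),
                          (30, 250.0, 50.0)])
        rep = detect_alternans(m29, m30, m28=m28)
        assert not rep.electrical and not rep.mechanical
        # true ABA alternation keeps the flag
        m28b = mk_metrics(28, 250.0, st_val=50.0)
        rep2 = detect_alternans(mk_metrics(29, 240.0, st_val=40.0),
                                mk_metrics(30, 250.0, st_val=50.0), m28=m28b)
        assert rep2.electrical and rep2.mechanical

    @given(d_apd=st.floats(min_value=0.0, max_value=30.0),
           thr_lo=st.floats(min_value=0.5, max_value=5.0),
           extra=st.floats(min_value=0.0, max_value=10.0))
    @settings(max_examples=50, deadline=None)
    def test_threshold_monotonicity(self, d_apd, thr_lo, extra):
        """Raising thresholds never turns a false flag true."""
        m29, m30 = mk_metrics(29, 250.0), mk_metrics(30, 250.0 + d_apd)
        lo = detect_alternans(m29, m30, AlternansThresholds(apd_ms=thr_lo))
        hi = detect_alternans(m29, m30,
                              AlternansThresholds(apd_ms=thr_lo + extra))
        assert lo.electrical or not hi.electrical


class _StubSweep:
    """Duck-typed sweep with synthetic per-BCL records."""

    def __init__(self, elec, mech=()):
        self._elec, self._mech = list(elec), list(mech)

    def electrical_records(self):
        return iter(self._elec)

    def mechanical_records(self):
        return iter(self._mech)


def elec_record(variant, bcl, apd29, apd30, alternans=False, captured=True):
    m29 = mk_metrics(29, apd29, captured=captured)
    m30 = mk_metrics(30, apd30, captured=captured)
    rep = detect_alternans(m29, m30)
    rep.electrical = alternans
    return ((variant, bcl), {"metrics": {29: m29, 30: m30}, "alternans": rep})


class TestRestitutionCurve:
    def test_linear_apd_di_relation_recovers_slope(self):
        a, b = 120.0, 0.25
        records = []
        for bcl in (400.0, 600.0, 800.0, 1000.0):
            apd_val = (a + b * bcl) / (1 + b)   # fixed point of APD = a + b*DI
            records.append(elec_record("endo", bcl, apd_val, apd_val))
        df, slopes = restitution_curve(_StubSweep(records))
        assert slopes["endo"] == pytest.approx(b, rel=1e-6)

    def test_flat_apd_zero_slope(self):
        records = [elec_record("epi", bcl, 250.0, 250.0)
                   for bcl in (500.0, 700.0, 900.0)]
        _, slopes = restitution_curve(_StubSweep(records))
        assert slopes["epi"] == pytest.approx(0.0, abs=1e-12)

    def test_too_few_captured_bcls(self):
        records = [elec_record("mid", 500.0, 250.0, 250.0),
                   elec_record("mid", 700.0, np.nan, np.nan, captured=False)]
        with pytest.raises(ValueError):
            restitution_curve(_StubSweep(records))


def mech_record(variant, bcl, load, st29, st30, dt29=0.0, dt30=0.0):
    m29 = mk_metrics(29, 250.0, st_val=st29, dt_val=dt29)
    m30 = mk_metrics(30, 250.0, st_val=st30, dt_val=dt30)
    return ((variant, bcl, load),
            {"metrics": {29: m29, 30: m30},
             "alternans": detect_alternans(m29, m30)})


class TestTensionAmplitudeCurve:
    def test_argmax_at_constructed_maximum(self):
        records = [mech_record("mid", bcl, 1000.0, amp, amp)
                   for bcl, amp in [(400.0, 30.0), (600.0, 80.0),
                                    (800.0, 55.0)]]
        df, argmax = tension_amplitude_curve(_StubSweep((), records), 1000.0)
        assert argmax["mid"] == 600.0
        assert (df["amplitude30"] >= 0).all()

    def test_missing_load_errors(self):
        with pytest.raises(ValueError):
            tension_amplitude_curve(_StubSweep((), ()), 10.0)
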