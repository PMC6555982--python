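"""Mechanics stage: overlap geometry, force law, cross-bridge kinetics, loads."""

import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings, strategies as st

from ecalt.datatypes import CaTransient
from ecalt.myofilament import (LoadCondition, MechParams, MechState,
                               active_force, atp_rate, run_mechanics,
                               single_overlap_fraction, sl_dynamics,
                               xb_steady_state, xb_transitions)
from ecalt.synthetic import CaWaveformSpec, generate

PARAMS = MechParams.default()


def overlap_reference(sl, p=PARAMS):
    """Scalar-arithmetic re-derivation of the thick-filament overlap."""
    ze = min(p.len_thick / 2, sl / 2)
    cle = max(sl / 2 - (sl - p.len_thin), p.len_hbare / 2)
    return (ze - cle) * 2 / (p.len_thick - p.len_hbare)


class TestOverlap:
    def test_full_overlap_at_optimum(self):
        assert single_overlap_fraction(2.3, PARAMS) == pytest.approx(1.0)

    def test_value_at_rest_length_matches_reference(self):
        got = single_overlap_fraction(PARAMS.sl_0, PARAMS)
        assert got == pytest.approx(overlap_reference(PARAMS.sl_0), rel=1e-12)

    @given(st.floats(min_value=1.4, max_value=2.4))
    @settings(max_examples=50, deadline=None)
    def test_bounded_and_matches_reference(self, sl):
        got = single_overlap_fraction(sl, PARAMS)
        assert 0.0 <= got <= 1.0
        assert got == pytest.approx(min(overlap_reference(sl), 1.0), rel=1e-9)

    def test_non_increasing_past_optimum(self):
        grid = np.linspace(2.3, PARAMS.sl_max, 20)
        vals = [single_overlap_fraction(s, PARAMS) for s in grid]
        assert all(b <= a + 1e-12 for a, b in zip(vals, vals[1:]))

    def test_out_of_bounds_names_bound(self):
        with pytest.raises(ValueError, match="1.4"):
            single_overlap_fraction(1.0, PARAMS)


def make_state(**kw):
    base = dict(n_xb=1.0, p_xb=0.0, xb_prer=0.0, xb_postr=0.0,
                x_prer=0.0, x_postr=PARAMS.x_0, tn_ca_l=0.0, tn_ca_h=0.0,
                sl=PARAMS.sl_0)
    base.update(kw)
    return MechState(**base)


class TestActiveForce:
    def test_no_bound_bridges_no_force(self):
        f, kpa = active_force(make_state(), PARAMS)
        assert f == 0.0 and kpa == 0.0

    def test_normalization_identity(self):
        # post-rotated bridges at x_0 occupying the optimal duty fraction,
        # full overlap -> normalized force is exactly 1
        xb_max = PARAMS.xb_postr_max
        st_ = make_state(n_xb=1.0 - xb_max, xb_postr=xb_max, sl=2.3)
        f, kpa = active_force(st_, PARAMS)
        assert f == pytest.approx(1.0, rel=1e-12)
        assert kpa == pytest.approx(PARAMS.force_scale, rel=1e-12)

    def test_linear_in_postr_occupancy(self):
        s1 = make_state(n_xb=0.9, xb_postr=0.1, sl=2.3)
        s2 = make_state(n_xb=0.8, xb_postr=0.2, sl=2.3)
        f1, _ = active_force(s1, PARAMS)
        f2, _ = active_force(s2, PARAMS)
        assert f2 == pytest.approx(2 * f1, rel=1e-12)


class TestAtpRate:
    def test_zero_without_postr(self):
        assert atp_rate(make_state(), PARAMS) == 0.0

    def test_linear_in_detachment_rate(self):
        st_ = make_state(n_xb=0.7, xb_postr=0.3)
        doubled = replace(PARAMS, g_xb=2 * PARAMS.g_xb)
        assert atp_rate(st_, doubled) == pytest.approx(
            2 * atp_rate(st_, PARAMS), rel=1e-12)

    def test_never_negative_on_random_states(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            occ = rng.dirichlet(np.ones(4))
            st_ = make_state(n_xb=occ[0], p_xb=occ[1], xb_prer=occ[2],
                             xb_postr=occ[3],
                             x_prer=rng.normal(0, 0.005),
                             x_postr=PARAMS.x_0 + rng.normal(0, 0.005))
            assert atp_rate(st_, PARAMS) >= 0.0


class TestXbTransitions:
    @given(st.floats(min_value=0.0, max_value=20.0),
           st.integers(min_value=0, max_value=2 ** 31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_occupancy_derivatives_conserve(self, ca, seed):
        rng = np.random.default_rng(seed)
        occ = rng.dirichlet(np.ones(4))
        st_ = make_state(n_xb=occ[0], p_xb=occ[1], xb_prer=occ[2],
                         xb_postr=occ[3])
        dy = xb_transitions(st_, ca, PARAMS)
        assert abs(dy[:4].sum()) < 1e-12

    def test_negative_ca_rejected(self):
        with pytest.raises(ValueError):
            xb_transitions(make_state(), -1.0, PARAMS)

    def test_diastolic_clamp_relaxed(self):
        ca = CaTransient(dt=1.0, ca=np.full(3001, 0.1), bcl=3000.0, n_beats=1)
        m = run_mechanics(ca, LoadCondition("isometric_clamp"), PARAMS,
                          settle_ms=5000.0)
        assert m.final_state.xb_postr < 1e-3
        f, _ = active_force(m.final_state, PARAMS)
        assert f < 0.01

    @pytest.mark.parametrize("ca_level", [0.5, 2.0, 10.0])
    def test_clamped_equilibrium_matches_rate_matrix(self, ca_level):
        """Integrated occupancies vs the null space of the transition matrix."""
        ca = CaTransient(dt=1.0, ca=np.full(2001, ca_level), bcl=2000.0,
                         n_beats=1)
        m = run_mechanics(ca, LoadCondition("isometric_clamp"), PARAMS,
                          settle_ms=20000.0)
        expected = xb_steady_state(ca_level, PARAMS)
        got = m.final_state
        assert got.n_xb == pytest.approx(expected["n_xb"], abs=1e-6)
        assert got.p_xb == pytest.approx(expected["p_xb"], abs=1e-6)
        assert got.xb_prer == pytest.approx(expected["xb_prer"], abs=1e-6)
        assert got.xb_postr == pytest.approx(expected["xb_postr"], abs=1e-6)

    def test_occupancy_sum_preserved_through_run(self, synth_alternating):
        m = run_mechanics(synth_alternating, LoadCondition("isotonic", 10.0),
                          PARAMS)
        s = m.final_state
        assert abs(s.n_xb + s.p_xb + s.xb_prer + s.xb_postr - 1.0) < 1e-9


class TestSlDynamics:
    def test_isometric_clamp_velocity_zero(self):
        st_ = make_state(xb_postr=0.3, n_xb=0.7)
        assert sl_dynamics(st_, LoadCondition("isometric_clamp"), PARAMS) == 0.0

    def test_zero_net_force_at_rest_length(self):
        st_ = make_state()
        st_.intf = 0.0
        assert sl_dynamics(st_, LoadCondition("isotonic", 10.0), PARAMS) == 0.0

    def test_clamp_keeps_sl_constant(self, synth_twitch):
        m = run_mechanics(synth_twitch, LoadCondition("isometric_clamp"), PARAMS)
        assert np.all(m.sl == PARAMS.sl_0)

    def test_heavy_afterload_is_pseudo_isometric(self, synth_twitch):
        m = run_mechanics(synth_twitch, LoadCondition("isotonic", 1000.0), PARAMS)
        assert np.max(np.abs(m.sl - PARAMS.sl_0)) / PARAMS.sl_0 < 0.01

    def test_invalid_load_mode(self):
        with pytest.raises(ValueError):
            LoadCondition("auxotonic")


class TestRunMechanics:
    def test_relaxed_limit_constant_diastolic_ca(self):
        ca = CaTransient(dt=1.0, ca=np.full(2001, 0.1), bcl=1000.0, n_beats=2)
        m = run_mechanics(ca, LoadCondition("isotonic", 10.0), PARAMS)
        assert m.tension.max() < 0.01 * PARAMS.force_scale
        assert m.eq_length[-1] == pytest.approx(1.0, abs=1e-6)

    def test_tension_and_atp_nonnegative(self, synth_alternating):
        m = run_mechanics(synth_alternating, LoadCondition("isotonic", 10.0),
                          PARAMS)
        assert m.tension.min() >= 0.0
        assert m.atp.min() >= 0.0

    def test_alternating_drive_gives_tension_alternans(self, synth_alternating):
        m = run_mechanics(synth_alternating,
                          LoadCondition("isotonic", 1000.0), PARAMS)
        st_beats = [m.tension[m.beat_slice(b)].max() for b in (27, 28, 29, 30)]
        # odd beats carry the large Ca amplitude -> larger peak tension
        assert st_beats[0] > st_beats[1] and st_beats[2] > st_beats[3]
        ca_beats = [synth_alternating.ca[synth_alternating.beat_slice(b)].max()
                    for b in (27, 28, 29, 30)]
        assert (st_beats[0] - st_beats[1]) * (ca_beats[0] - ca_beats[1]) > 0

    def test_monotone_ca_response_isometric(self, synth_twitch):
        m1 = run_mechanics(synth_twitch, LoadCondition("isometric_clamp"), PARAMS)
        boosted = CaTransient(dt=synth_twitch.dt,
                              ca=0.1 + 1.2 * (synth_twitch.ca - 0.1),
                              bcl=synth_twitch.bcl,
                              n_beats=synth_twitch.n_beats)
        m2 = run_mechanics(boosted, LoadCondition("isometric_clamp"), PARAMS)
        assert m2.tension.max() >= m1.tension.max()

    def test_low_load_shortens_more(self, synth_twitch):
        m_low = run_mechanics(synth_twitch, LoadCondition("isotonic", 0.6), PARAMS)
        m_mid = run_mechanics(synth_twitch, LoadCondition("isotonic", 10.0), PARAMS)
        assert m_low.eq_length.min() <= m_mid.eq_length.min()

    def test_too_short_drive_rejected(self):
        ca = CaTransient(dt=1.0, ca=np.full(100, 0.1), bcl=1000.0, n_beats=1)
        with pytest.raises(ValueError):
            run_mechanics(ca, LoadCondition("isotonic", 10.0), PARAMS)


class TestMechState:
    def test_occupancy_conservation_enforced(self):
        with pytest.raises(ValueError):
            MechState(n_xb=0.5, p_xb=0.5, xb_prer=0.5, xb_postr=0.0,
                      x_prer=0.0, x_postr=0.007, tn_ca_l=0.0, tn_ca_h=0.0,
                      sl=1.9)

    def test_param_file_roundtrip(self, tmp_path):
        path = tmp_path / "mech.params"
        lines = [f"{k} = {v}" for k, v in PARAMS.__dict__.items()]
        path.write_text("\n".join(lines))
        assert MechParams.from_file(path) == PARAMS
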