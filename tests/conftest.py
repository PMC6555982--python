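"""Shared fixtures.

The expensive paced runs (30 beats at BCL 1000 ms per variant, and the full
default sweep) are session-scoped so the unit and acceptance tests share them.
"""

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from ecalt.ionic import IonicParams, StimulusProtocol, run_paced
from ecalt.myofilament import LoadCondition, MechParams
from ecalt.protocol import SweepConfig, run_cell, run_sweep
from ecalt.synthetic import CaWaveformSpec, generate


@pytest.fixture(scope="session")
def mech_params():
    return MechParams.default()


@pytest.fixture(scope="session")
def ionic_params():
    return {v: IonicParams.for_variant(v) for v in ("endo", "mid", "epi")}


@pytest.fixture(scope="session")
def runs_1000(ionic_params, mech_params):
    """Coupled 30-beat runs at BCL 1000 ms for all three variants."""
    cfg = SweepConfig(bcl_list=(1000.0,))
    return {v: run_cell(v, 1000.0, cfg, ionic_params=ionic_params[v],
                        mech_params=mech_params)
            for v in ("endo", "mid", "epi")}


@pytest.fixture(scope="session")
def full_sweep():
    """Default fresh-start sweep, 10 kPa and pseudo-isometric loads."""
    cfg = SweepConfig(loads=(LoadCondition("isotonic", 10.0),
                             LoadCondition("isotonic", 1000.0)))
    sweep = run_sweep(cfg)
    assert not sweep.failures, sweep.failures
    return sweep


@pytest.fixture()
def synth_twitch():
    """Non-alternating synthetic Ca drive, three slow beats."""
    spec = CaWaveformSpec(bcl=1000.0, n_beats=3, ca_dia=0.1, ca_amp=0.9,
                          t_rise=30.0, tau_decay=150.0)
    return generate(spec, dt=1.0)


@pytest.fixture()
def synth_alternating():
    """Synthetic Ca drive with 30-beat structure and 0.7 alternation ratio."""
    spec = CaWaveformSpec(bcl=500.0, n_beats=30, ca_dia=0.1, ca_amp=0.9,
                          alternation_ratio=0.7)
    return generate(spec, dt=1.0)
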