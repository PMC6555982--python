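"""Parametric cytosolic Ca transients emulating the electrical stage's output.

The mechanics stage only sees a sampled Ca time series, so a double-exponential
waveform with per-beat amplitude alternation is enough to exercise and test it
(and the downstream metrics) without running the ionic model. Typical human
ventricular values at slow pacing: diastolic ~0.1 uM, peak ~0.7-1.5 uM, rise to
peak in a few tens of ms, decay time constant ~100-200 ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import CaTransient

__all__ = ["CaWaveformSpec", "generate"]


@dataclass(frozen=True)
class CaWaveformSpec:
    """Specification of a synthetic periodic Ca transient."""

    bcl: float = 1000.0            # ms
    n_beats: int = 30
    ca_dia: float = 0.1            # diastolic level (uM)
    ca_amp: float = 0.63           # peak minus diastolic (uM)
    t_rise: float = 30.0           # time of peak (ms)
    tau_decay: float = 150.0       # decay time constant (ms)
    alternation_ratio: float = 1.0  # even-beat amplitude / odd-beat amplitude
    noise_sd: float = 0.0          # additive Gaussian noise (uM)
    seed: int = 0

    def __post_init__(self):
        if self.ca_dia < 0:
            raise ValueError("ca_dia must be >= 0")
        if self.ca_amp <= 0:
            raise ValueError("ca_amp must be > 0")
        if not 0 < self.alternation_ratio <= 1:
            raise ValueError("alternation_ratio must lie in (0, 1]")
        if self.t_rise <= 0 or self.tau_decay <= 0:
            raise ValueError("t_rise and tau_decay must be > 0")
        if self.n_beats < 1:
            raise ValueError("n_beats must be >= 1")


def _beat_shape(t: np.ndarray, t_rise: float, tau_decay: float) -> np.ndarray:
    """Unit-peak rise-and-decay waveform (1 - exp)-times-exp family.

    The rise constant is chosen so the waveform peaks at ~t_rise; the result is
    rescaled to exactly unit amplitude.
    """
    # peak time of (1-exp(-t/a))exp(-t/tau) is a*ln(1+tau/a); invert roughly
    a = t_rise / np.log1p(tau_decay / t_rise)
    w = (1.0 - np.exp(-t / a)) * np.exp(-t / tau_decay)
    return w / w.max()


def generate(spec: CaWaveformSpec, dt: float = 1.0) -> CaTransient:
    """Sample the synthetic transient at interval ``dt`` (ms).

    Deterministic for a fixed ``spec.seed``. Beat k (1-based) gets amplitude
    ``ca_amp`` for odd k and ``ca_amp * alternation_ratio`` for even k; noise
    is added after waveform construction and the series is clipped at zero.
    """
    if dt >= spec.bcl:
        raise ValueError("dt must be smaller than the BCL")
    n_per_beat = int(round(spec.bcl / dt))
    t_beat = np.arange(n_per_beat) * dt
    shape = _beat_shape(t_beat, spec.t_rise, spec.tau_decay)
    beats = []
    for k in range(1, spec.n_beats + 1):
        amp = spec.ca_amp if k % 2 == 1 else spec.ca_amp * spec.alternation_ratio
        beats.append(spec.ca_dia + amp * shape)
    ca = np.concatenate(beats)
    ca = np.append(ca, spec.ca_dia)  # terminal sample closes the last beat
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        ca = ca + rng.normal(0.0, spec.noise_sd, ca.size)
    return CaTransient(dt=dt, ca=np.clip(ca, 0.0, None), bcl=spec.bcl,
                       n_beats=spec.n_beats)
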