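"""Containers shared between the electrical and mechanical stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class CaTransient:
    """Uniformly sampled cytosolic free-Ca time series in micromolar.

    This is the hand-off object of the one-way coupling: the electrical stage
    produces it, the mechanics stage consumes it. ``bcl``/``n_beats`` carry the
    pacing structure so downstream code can segment beats without re-detecting
    them.
    """

    dt: float                      # sampling interval (ms)
    ca: np.ndarray                 # free cytosolic Ca (uM)
    bcl: float                     # basic cycle length (ms)
    n_beats: int

    def __post_init__(self) -> None:
        self.ca = np.asarray(self.ca, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.ca.ndim != 1 or self.ca.size < 2:
            raise ValueError("ca must be a 1-D series with at least two samples")

    @property
    def time(self) -> np.ndarray:
        """Sample times in ms, starting at 0."""
        return np.arange(self.ca.size) * self.dt

    @property
    def duration(self) -> float:
        return (self.ca.size - 1) * self.dt

    def beat_slice(self, beat: int) -> slice:
        """Index slice of one 1-based beat window [(k-1)*BCL, k*BCL)."""
        if not 1 <= beat <= self.n_beats:
            raise ValueError(f"beat {beat} outside 1..{self.n_beats}")
        i0 = int(round((beat - 1) * self.bcl / self.dt))
        i1 = int(round(beat * self.bcl / self.dt))
        return slice(i0, min(i1, self.ca.size))


@dataclass
class PacedTraces:
    """Output of a paced electrical run, uniformly sampled at ``dt``."""

    dt: float
    vm: np.ndarray                 # membrane potential (mV)
    cai: np.ndarray                # free cytosolic Ca (mM)
    casr: np.ndarray               # free SR Ca (mM)
    cass: np.ndarray               # free subspace Ca (mM)
    bcl: float
    n_beats: int
    snapshots: np.ndarray = field(repr=False, default=None)  # state at beat starts
    final_state: np.ndarray = field(repr=False, default=None)

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.vm.size) * self.dt

    def beat_slice(self, beat: int) -> slice:
        if not 1 <= beat <= self.n_beats:
            raise ValueError(f"beat {beat} outside 1..{self.n_beats}")
        i0 = int(round((beat - 1) * self.bcl / self.dt))
        i1 = int(round(beat * self.bcl / self.dt))
        return slice(i0, min(i1, self.vm.size))

    def ca_transient(self) -> CaTransient:
        """Cytosolic Ca converted to uM for the mechanics stage."""
        return CaTransient(dt=self.dt, ca=self.cai * 1e3, bcl=self.bcl, n_beats=self.n_beats)
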