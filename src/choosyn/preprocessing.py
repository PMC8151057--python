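"""From raw multi-muscle sEMG to normalized 10-cycle envelope subgroups.

The processing chain, applied on the normalized timebase of 1000 samples
per gait cycle (nominal 1000 Hz):

1. segment gait cycles at the provided events and time-normalize each
   cycle to 1000 samples (linear interpolation);
2. zero-phase 8th-order Butterworth high-pass at 35 Hz (movement-artifact
   and baseline suppression), demean, full-wave rectify, zero-phase
   5th-order Butterworth low-pass at 12 Hz -> envelopes;
3. amplitude-normalize each muscle by its global maximum over the walk;
4. group consecutive runs of 10 cycles into concatenated subgroups
   (muscles x 10,000 samples), discarding the leftover cycles.

Filtering runs on the whole-walk concatenation rather than per cycle to
avoid per-cycle edge transients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import (
    EventOrderError,
    FilterDesignError,
    InsufficientCyclesError,
    NoCompleteCycleError,
)

__all__ = [
    "EmgRecording",
    "SubgroupEnvelopes",
    "segment_and_normalize",
    "envelope_pipeline",
    "normalize_amplitude",
    "make_subgroups",
    "preprocess",
    "CYCLE_SAMPLES",
    "CYCLES_PER_SUBGROUP",
]

logger = logging.getLogger(__name__)

CYCLE_SAMPLES = 1000
CYCLES_PER_SUBGROUP = 10


@dataclass
class EmgRecording:
    """Raw multi-muscle signal plus gait events (cycle-start indices)."""

    signal: np.ndarray                 # (samples, muscles)
    muscle_names: tuple[str, ...]
    events: np.ndarray                 # 0-based, strictly increasing

    @property
    def n_muscles(self) -> int:
        return self.signal.shape[1]

    @classmethod
    def from_simulated(cls, rec) -> "EmgRecording":
        """Wrap a simulated recording, closing the final cycle.

        Simulated events mark cycle starts only; the signal ends exactly on
        a cycle boundary, so that boundary is appended as the last event.
        """
        from .simulator import DEFAULT_MUSCLE_NAMES

        m = rec.signal.shape[1]
        names = tuple(DEFAULT_MUSCLE_NAMES[:m]) if m <= len(DEFAULT_MUSCLE_NAMES) \
            else tuple(f"M{i + 1}" for i in range(m))
        events = np.append(np.asarray(rec.events), rec.signal.shape[0])
        return cls(signal=rec.signal, muscle_names=names, events=events)


@dataclass
class SubgroupEnvelopes:
    """Concatenated 10-cycle envelope matrices, all values in [0, 1]."""

    subgroups: list[np.ndarray]        # each (muscles, 10_000)
    normalization_maxima: np.ndarray   # per-muscle global maxima

    @property
    def n_subgroups(self) -> int:
        return len(self.subgroups)

    @property
    def n_muscles(self) -> int:
        return self.subgroups[0].shape[0]


def segment_and_normalize(rec: EmgRecording) -> list[np.ndarray]:
    """Split the walk into cycles, each time-normalized to 1000 samples.

    Cycle i covers the half-open interval [e_i, e_{i+1}); it is resampled
    onto the uniform grid ``e_i + k*(L/1000)``, k = 0..999, by linear
    interpolation, so a cycle that is already 1000 samples long passes
    through unchanged.  Samples after the last event are discarded.
    """
    events = np.asarray(rec.events)
    if len(events) < 2:
        raise NoCompleteCycleError("need at least 2 events for one cycle")
    if (np.diff(events) <= 0).any():
        raise EventOrderError("events must be strictly increasing")
    if events[-1] > rec.signal.shape[0]:
        raise EventOrderError("last event beyond end of signal")
    t = np.arange(rec.signal.shape[0], dtype=float)
    cycles = []
    for e0, e1 in zip(events[:-1], events[1:]):
        grid = e0 + np.arange(CYCLE_SAMPLES) * ((e1 - e0) / CYCLE_SAMPLES)
        cyc = np.empty((rec.n_muscles, CYCLE_SAMPLES))
        for ch in range(rec.n_muscles):
            cyc[ch] = np.interp(grid, t, rec.signal[:, ch])
        cycles.append(cyc)
    return cycles


def envelope_pipeline(cycles: list[np.ndarray],
                      fs_nominal: float = 1000.0,
                      hp_cutoff: float = 35.0, hp_order: int = 8,
                      lp_cutoff: float = 12.0, lp_order: int = 5
                      ) -> list[np.ndarray]:
    """High-pass, demean, rectify, low-pass: per-muscle envelopes.

    Both filters are Butterworth designs of the stated order, applied
    forward-backward (zero phase) on the concatenation of all cycles;
    negative values introduced by low-pass ringing are clipped to zero.
    """
    nyq = fs_nominal / 2.0
    if hp_cutoff >= nyq or lp_cutoff >= nyq:
        raise FilterDesignError("cutoff must be below the Nyquist frequency")
    walk = np.concatenate(cycles, axis=1)          # (m, 1000*N)
    sos_hp = sps.butter(hp_order, hp_cutoff, btype="highpass",
                        fs=fs_nominal, output="sos")
    sos_lp = sps.butter(lp_order, lp_cutoff, btype="lowpass",
                        fs=fs_nominal, output="sos")
    x = sps.sosfiltfilt(sos_hp, walk, axis=1)
    x = x - x.mean(axis=1, keepdims=True)
    x = np.abs(x)
    x = sps.sosfiltfilt(sos_lp, x, axis=1)
    np.clip(x, 0.0, None, out=x)
    return [x[:, i:i + CYCLE_SAMPLES]
            for i in range(0, x.shape[1], CYCLE_SAMPLES)]


def normalize_amplitude(cycles: list[np.ndarray]
                        ) -> tuple[list[np.ndarray], np.ndarray]:
    """Scale each muscle by its global maximum over all cycles.

    Muscles whose global maximum is zero are left untouched (and logged):
    dividing by zero would poison the factorization input.
    """
    if not cycles:
        raise ValueError("need at least one cycle")
    maxima = np.max([c.max(axis=1) for c in cycles], axis=0)
    safe = np.where(maxima > 0, maxima, 1.0)
    for ch in np.where(maxima <= 0)[0]:
        logger.warning("muscle %d has zero global maximum; left unscaled", ch)
    return [c / safe[:, None] for c in cycles], maxima


def make_subgroups(cycles: list[np.ndarray]) -> SubgroupEnvelopes:
    """Concatenate consecutive blocks of 10 cycles; drop the remainder."""
    n = len(cycles)
    n_sub = n // CYCLES_PER_SUBGROUP
    if n_sub < 1:
        raise InsufficientCyclesError(
            f"{n} cycles < {CYCLES_PER_SUBGROUP}: no complete subgroup")
    subgroups = [
        np.concatenate(cycles[i * CYCLES_PER_SUBGROUP:(i + 1) * CYCLES_PER_SUBGROUP],
                       axis=1)
        for i in range(n_sub)
    ]
    maxima = np.max([c.max(axis=1) for c in cycles], axis=0)
    return SubgroupEnvelopes(subgroups=subgroups, normalization_maxima=maxima)


def preprocess(rec: EmgRecording, fs_nominal: float = 1000.0) -> SubgroupEnvelopes:
    """Full chain: segment -> envelope -> normalize -> subgroups."""
    cycles = segment_and_normalize(rec)
    cycles = envelope_pipeline(cycles, fs_nominal=fs_nominal)
    cycles, maxima = normalize_amplitude(cycles)
    subs = make_subgroups(cycles)
    subs.normalization_maxima = maxima
    return subs
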