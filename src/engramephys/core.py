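"""Core domain containers shared across the pipeline.

The pipeline operates on three kinds of objects: multi-channel voltage
traces with sampling metadata, per-unit spike-time trains with waveform
summaries, and labeled behavior-episode timelines (freezing during fear
recall, nocifensive bouts during tonic pain).  Cell-count tables for the
dual-label overlap statistics live here as well.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

#: refractory period used for contamination bookkeeping (s)
REFRACTORY_S = 0.002


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants."""


@dataclasses.dataclass
class VoltageTrace:
    """Multi-channel extracellular voltage signal.

    Parameters
    ----------
    samples
        Array of shape ``(n_channels, n_samples)`` in volts.
    fs
        Sampling rate in Hz.
    channel_ids
        Optional channel labels; defaults to ``ch00 .. chNN``.
    """

    samples: np.ndarray
    fs: float
    channel_ids: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if self.channel_ids is None:
            self.channel_ids = [f"ch{i:02d}" for i in range(self.samples.shape[0])]
        elif len(self.channel_ids) != self.samples.shape[0]:
            raise ValidationError("channel_ids length does not match channel count")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Trace duration in seconds."""
        return self.n_samples / self.fs


@dataclasses.dataclass
class EpisodeTimeline:
    """Sorted, non-overlapping behavior episodes of one state.

    ``state`` is typically ``"freezing"`` (fear recall) or ``"nocifensive"``
    (tonic pain).  Intervals are ``(onset_s, offset_s)`` pairs.
    """

    state: str
    intervals: np.ndarray

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals, dtype=float).reshape(-1, 2)
        if iv.size and np.any(iv[:, 1] <= iv[:, 0]):
            bad = np.flatnonzero(iv[:, 1] <= iv[:, 0])
            raise ValidationError(f"episode offset must exceed onset (rows {bad.tolist()})")
        if iv.shape[0] > 1:
            order = np.argsort(iv[:, 0])
            iv = iv[order]
            if np.any(iv[1:, 0] < iv[:-1, 1]):
                bad = np.flatnonzero(iv[1:, 0] < iv[:-1, 1])
                raise ValidationError(f"episodes overlap (rows {bad.tolist()})")
        self.intervals = iv

    def __len__(self) -> int:
        return self.intervals.shape[0]

    @property
    def covered_time(self) -> float:
        """Total time spent inside episodes, in seconds."""
        if not len(self):
            return 0.0
        return float(np.sum(self.intervals[:, 1] - self.intervals[:, 0]))

    def contains(self, t: np.ndarray) -> np.ndarray:
        """Boolean mask: does each time point fall inside an episode?"""
        t = np.asarray(t, dtype=float)
        if not len(self):
            return np.zeros(t.shape, dtype=bool)
        idx = np.searchsorted(self.intervals[:, 0], t, side="right") - 1
        inside = idx >= 0
        inside[inside] &= t[inside] <= self.intervals[idx[inside], 1]
        return inside


@dataclasses.dataclass
class UnitSpikeTrain:
    """Spike times of one isolated unit plus waveform summary features."""

    unit_id: str
    spike_times: np.ndarray
    mean_waveform: np.ndarray | None = None
    fs: float | None = None
    half_amplitude_duration_ms: float | None = None
    trough_to_peak_ms: float | None = None
    mean_rate_hz: float | None = None

    def __post_init__(self) -> None:
        st = np.asarray(self.spike_times, dtype=float).ravel()
        if st.size > 1 and np.any(np.diff(st) <= 0):
            raise ValidationError(f"unit {self.unit_id}: spike times not strictly increasing")
        self.spike_times = st

    @property
    def n_spikes(self) -> int:
        return self.spike_times.size

    @property
    def refractory_fraction(self) -> float:
        """Fraction of inter-spike intervals shorter than the 2 ms refractory period."""
        if self.n_spikes < 2:
            return 0.0
        isi = np.diff(self.spike_times)
        return float(np.mean(isi < REFRACTORY_S))


@dataclasses.dataclass
class CountTable:
    """Per-region labeled-cell counts for dual-label overlap statistics.

    ``n_fos`` counts Fos-immunopositive nuclei, ``n_tag`` the activity-tagged
    population (mCherry/Venus/YFP), ``n_double`` nuclei positive for both, and
    ``n_dapi`` all nuclei.  ``volume_mm3`` is the counted tissue volume.
    """

    region: str
    n_fos: int
    n_tag: int
    n_double: int
    n_dapi: int
    volume_mm3: float

    def __post_init__(self) -> None:
        for name in ("n_fos", "n_tag", "n_double", "n_dapi"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValidationError(f"{name} must be a non-negative integer, got {v}")
            setattr(self, name, int(v))
        if self.n_double > min(self.n_fos, self.n_tag):
            raise ValidationError("n_double exceeds a single-label count")
        if max(self.n_fos, self.n_tag) > self.n_dapi:
            raise ValidationError("label counts exceed total nuclei")
        if self.volume_mm3 < 0:
            raise ValidationError("volume must be non-negative")
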