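"""Spike extraction from raw traces and duplicate-unit pruning.

The preprocessing chain is: subtract the across-channel common median,
band-pass 300-6,000 Hz with a fourth-order zero-phase Butterworth filter,
then detect threshold crossings at 9x the per-channel median absolute
deviation.  Duplicate units (the same neuron registering on neighboring
channel groups) are pruned by the >10% common-spike-time rule, removing the
member of each flagged pair with the higher refractory-violation fraction.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import signal, stats

from .core import UnitSpikeTrain, ValidationError, VoltageTrace

MAD_TO_SIGMA = 1.0 / stats.norm.ppf(0.75)  # ~1/0.6745


class FeatureUndefinedError(ValueError):
    """Waveform has no trough/peak structure to measure."""


@dataclasses.dataclass
class SpikeEvent:
    """One detected threshold-crossing event."""

    time: float
    channel: str
    waveform: np.ndarray
    amplitude: float  # signed extremum, volts


def subtract_common_median(trace: VoltageTrace) -> VoltageTrace:
    """Remove the across-channel median at every sample (common-mode noise).

    A single-channel trace is returned unchanged with a warning: there is no
    common mode to estimate.
    """
    if trace.n_channels < 2:
        warnings.warn("common-median subtraction skipped: fewer than 2 channels")
        return VoltageTrace(trace.samples.copy(), trace.fs, list(trace.channel_ids))
    med = np.median(trace.samples, axis=0, keepdims=True)
    return VoltageTrace(trace.samples - med, trace.fs, list(trace.channel_ids))


def bandpass(
    trace: VoltageTrace, low: float = 300.0, high: float = 6000.0, order: int = 4
) -> VoltageTrace:
    """Zero-phase Butterworth band-pass (forward-backward, so spike shapes keep their phase)."""
    if not (0 < low < high):
        raise ValidationError(f"need 0 < low < high, got ({low}, {high})")
    if high >= trace.fs / 2:
        raise ValidationError(
            f"upper band edge {high} Hz must be below Nyquist ({trace.fs / 2} Hz)"
        )
    sos = signal.butter(order, [low, high], btype="bandpass", fs=trace.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, trace.samples, axis=1)
    return VoltageTrace(filtered, trace.fs, list(trace.channel_ids))


def noise_sigma_mad(trace: VoltageTrace) -> np.ndarray:
    """Per-channel robust noise s.d.: MAD scaled to Gaussian sigma."""
    return stats.median_abs_deviation(trace.samples, axis=1, scale="normal")


def detect_spikes(
    trace: VoltageTrace,
    k: float = 9.0,
    snippet_ms: float = 2.0,
    dead_time_ms: float = 1.0,
) -> list[SpikeEvent]:
    """Detect events whose absolute amplitude exceeds ``k`` x MAD per channel.

    Each contiguous supra-threshold run contributes one event at its signed
    extremum; events closer than ``dead_time_ms`` on a channel are merged,
    keeping the larger one.  An all-zero channel (MAD = 0) yields no events.
    """
    half = int(round(snippet_ms / 1000.0 * trace.fs / 2))
    dead = int(round(dead_time_ms / 1000.0 * trace.fs))
    events: list[SpikeEvent] = []
    for c in range(trace.n_channels):
        x = trace.samples[c]
        mad = stats.median_abs_deviation(x)
        if mad == 0:
            continue
        thr = k * mad
        above = np.flatnonzero(np.abs(x) > thr)
        if above.size == 0:
            continue
        run_starts = np.flatnonzero(np.diff(above) > 1)
        groups = np.split(above, run_starts + 1)
        peaks: list[int] = []
        for g in groups:
            peaks.append(int(g[np.argmax(np.abs(x[g]))]))
        kept: list[int] = []
        for p in peaks:
            if kept and p - kept[-1] < dead:
                if abs(x[p]) > abs(x[kept[-1]]):
                    kept[-1] = p
            else:
                kept.append(p)
        pad = np.pad(x, half)
        for p in kept:
            events.append(
                SpikeEvent(
                    time=p / trace.fs,
                    channel=trace.channel_ids[c],
                    waveform=pad[p : p + 2 * half].copy(),
                    amplitude=float(x[p]),
                )
            )
    events.sort(key=lambda e: (e.time, e.channel))
    return events


def waveform_features(mean_waveform: np.ndarray, fs: float) -> tuple[float, float]:
    """Half-amplitude duration and trough-to-peak time of a mean waveform, in ms.

    The half-amplitude duration is the width of the (negative) trough at half
    its depth, with sub-sample linear interpolation of the crossings; the
    trough-to-peak time runs from the trough to the subsequent maximum.  Both
    are invariant to amplitude scaling.
    """
    w = np.asarray(mean_waveform, dtype=float)
    if w.size < 3:
        raise FeatureUndefinedError("waveform too short")
    ti = int(np.argmin(w))
    if w[ti] >= 0 or ti == 0 or ti == w.size - 1:
        raise FeatureUndefinedError("waveform has no interior negative trough")
    level = w[ti] / 2.0
    left = ti
    while left > 0 and w[left - 1] <= level:
        left -= 1
    if left == 0 and w[0] <= level:
        raise FeatureUndefinedError("trough is not delimited on the left")
    t_left = (left - 1) + (w[left - 1] - level) / (w[left - 1] - w[left])
    right = ti
    while right < w.size - 1 and w[right + 1] <= level:
        right += 1
    if right == w.size - 1 and w[-1] <= level:
        raise FeatureUndefinedError("trough is not delimited on the right")
    t_right = right + (w[right] - level) / (w[right] - w[right + 1])
    half_amp_ms = (t_right - t_left) / fs * 1000.0
    after = w[ti:]
    pi = ti + int(np.argmax(after))
    if pi == ti or w[pi] <= w[ti]:
        raise FeatureUndefinedError("no peak after the trough")
    t2p_ms = (pi - ti) / fs * 1000.0
    return float(half_amp_ms), float(t2p_ms)


def coincident_fraction(
    a: np.ndarray, b: np.ndarray, window_s: float = 0.0005
) -> float:
    """Fraction of the smaller train's spikes with a partner in the other train.

    Two spikes coincide when they differ by at most ``window_s``.  The
    denominator is the smaller spike count, so fully nested duplicates score 1.
    """
    small, large = (a, b) if a.size <= b.size else (b, a)
    if small.size == 0:
        return 0.0
    idx = np.searchsorted(large, small)
    d = np.full(small.size, np.inf)
    left = idx > 0
    d[left] = small[left] - large[idx[left] - 1]
    right = idx < large.size
    d[right] = np.minimum(d[right], large[idx[right]] - small[right])
    return float(np.mean(d <= window_s))


def remove_duplicates(
    units: list[UnitSpikeTrain],
    coincidence_window_ms: float = 0.5,
    frac: float = 0.10,
) -> list[UnitSpikeTrain]:
    """Prune duplicate units sharing more than ``frac`` of their spike times.

    Iteratively finds the pair with the highest shared fraction above the
    cutoff and removes its member with the higher refractory-violation
    fraction (ties: fewer spikes, then later unit id), until no pair remains
    above the cutoff.  Idempotent.
    """
    window_s = coincidence_window_ms / 1000.0
    alive = list(units)
    while len(alive) > 1:
        worst: tuple[float, int, int] | None = None
        for i in range(len(alive)):
            for j in range(i + 1, len(alive)):
                f = coincident_fraction(
                    alive[i].spike_times, alive[j].spike_times, window_s
                )
                if f > frac and (worst is None or f > worst[0]):
                    worst = (f, i, j)
        if worst is None:
            break
        _, i, j = worst
        drop = max(
            alive[i],
            alive[j],
            key=lambda u: (u.refractory_fraction, -u.n_spikes, u.unit_id),
        )
        alive.remove(drop)
    return alive


def build_unit(
    unit_id: str,
    spike_times: np.ndarray,
    duration: float,
    mean_waveform: np.ndarray | None = None,
    fs: float | None = None,
) -> UnitSpikeTrain:
    """Assemble a UnitSpikeTrain, computing waveform features when possible."""
    half_amp = t2p = None
    if mean_waveform is not None and fs is not None:
        try:
            half_amp, t2p = waveform_features(mean_waveform, fs)
        except FeatureUndefinedError:
            warnings.warn(f"unit {unit_id}: waveform features undefined")
    st = np.asarray(spike_times, dtype=float)
    return UnitSpikeTrain(
        unit_id=unit_id,
        spike_times=st,
        mean_waveform=mean_waveform,
        fs=fs,
        half_amplitude_duration_ms=half_amp,
        trough_to_peak_ms=t2p,
        mean_rate_hz=st.size / duration if duration > 0 else None,
    )
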