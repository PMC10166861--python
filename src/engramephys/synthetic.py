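"""Ground-truth-labeled synthetic data for the whole pipeline.

Emulates a three-session tetrode experiment — an unstimulated neutral
baseline, a cued fear-recall session with intermittent freezing episodes,
and a capsaicin tonic-pain session with intermittent nocifensive episodes.
Units spike as (piecewise-homogeneous) Poisson processes whose rate is
multiplied by ``episode_gain`` inside the episodes of their matched
behavioral state(s); waveforms come in two phenotypes, broad/slow principal
neurons and narrow/fast interneurons.  Cell-count tables for the dual-label
overlap statistics are Poisson/multinomial sampled around analytic
expectations.

Every generator is deterministic given a seed.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd

from .core import CountTable, EpisodeTimeline, ValidationError, VoltageTrace

CODING_CLASSES = ("fear_specific", "pain_specific", "common", "unspecific")
SESSION_NAMES = ("baseline", "fear", "pain")

#: which session's episodes each coding class responds to
_CLASS_SESSIONS = {
    "fear_specific": ("fear",),
    "pain_specific": ("pain",),
    "common": ("fear", "pain"),
    "unspecific": (),
}

_SESSION_STATE = {"fear": "freezing", "pain": "nocifensive"}


@dataclasses.dataclass
class SimConfig:
    """Study-design parameters for the synthetic experiment.

    Defaults mirror the recording design: 5-min neutral baseline, 7-min
    cued fear-recall session and 5-min post-capsaicin session, intermittent
    behavioral bouts of ~5 s covering ~30% of the session, and a threefold
    rate gain inside matched episodes.
    """

    n_units: int = 120
    class_fractions: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {
            "fear_specific": 0.20,
            "pain_specific": 0.20,
            "common": 0.15,
            "unspecific": 0.45,
        }
    )
    base_rate_range: tuple[float, float] = (0.5, 10.0)
    episode_gain: float = 3.0
    session_durations: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"baseline": 300.0, "fear": 420.0, "pain": 300.0}
    )
    #: per state: (mean episode length s, duty cycle)
    episode_stats: Mapping[str, tuple[float, float]] = dataclasses.field(
        default_factory=lambda: {"freezing": (5.0, 0.3), "nocifensive": (5.0, 0.3)}
    )
    in_fraction: float = 0.12
    #: per phenotype: (mean, s.d.) of each waveform/rate feature
    waveform_params: Mapping[str, Mapping[str, tuple[float, float]]] = dataclasses.field(
        default_factory=lambda: {
            "principal": {
                "half_amplitude_duration_ms": (0.40, 0.05),
                "trough_to_peak_ms": (0.70, 0.08),
                "mean_rate_hz": (2.5, 1.0),
            },
            "interneuron": {
                "half_amplitude_duration_ms": (0.20, 0.03),
                "trough_to_peak_ms": (0.33, 0.05),
                "mean_rate_hz": (11.0, 3.0),
            },
        }
    )
    noise_sigma: float = 1.0e-5
    fs: float = 30_000.0
    refractory_s: float = 0.002
    enforce_refractory: bool = True
    bandpass_high_hz: float = 6_000.0
    seed: int = 0

    def validate(self) -> None:
        fr = self.class_fractions
        if set(fr) != set(CODING_CLASSES):
            raise ValidationError(f"class_fractions must have keys {CODING_CLASSES}")
        vals = np.array([fr[c] for c in CODING_CLASSES], dtype=float)
        if np.any(vals < 0) or np.any(vals > 1) or abs(vals.sum() - 1.0) > 1e-9:
            raise ValidationError("class fractions must lie in [0,1] and sum to 1")
        if self.episode_gain < 1:
            raise ValidationError("episode_gain must be >= 1")
        if any(d <= 0 for d in self.session_durations.values()):
            raise ValidationError("session durations must be positive")
        if self.fs <= 2 * self.bandpass_high_hz:
            raise ValidationError("fs must exceed twice the bandpass upper edge")
        lo, hi = self.base_rate_range
        if not (0 < lo <= hi):
            raise ValidationError("base_rate_range must be a positive interval")
        if not (0 <= self.in_fraction <= 1):
            raise ValidationError("in_fraction must be in [0,1]")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be non-negative")


@dataclasses.dataclass
class SimulatedExperiment:
    """Spike trains, behavior timelines and ground truth of one simulated run."""

    #: session name -> unit_id -> strictly increasing spike times (s)
    spikes: dict[str, dict[str, np.ndarray]]
    #: session name -> EpisodeTimeline (baseline session has an empty timeline)
    timelines: dict[str, EpisodeTimeline]
    #: per-unit ground truth: coding class, phenotype, base rate, gain, features
    truth: pd.DataFrame
    config: SimConfig


def generate_episode_timeline(
    state: str,
    duration: float,
    mean_len: float,
    duty: float,
    seed: int | np.random.Generator,
) -> EpisodeTimeline:
    """Alternating exponential on/off bout process truncated at the session end.

    Off periods have mean ``mean_len * (1/duty - 1)`` so long-run coverage is
    ``duty``.  ``duty = 0`` returns an empty timeline (zero-coverage limit).
    """
    if duty >= 1:
        raise ValidationError(f"duty cycle must be < 1, got {duty}")
    if duty < 0:
        raise ValidationError(f"duty cycle must be >= 0, got {duty}")
    if mean_len <= 0:
        raise ValidationError(f"mean episode length must be positive, got {mean_len}")
    if mean_len >= duration:
        raise ValidationError("mean episode length must be below the session duration")
    if duty == 0:
        return EpisodeTimeline(state=state, intervals=np.empty((0, 2)))
    rng = np.random.default_rng(seed)
    mean_off = mean_len * (1.0 / duty - 1.0)
    intervals = []
    t = rng.exponential(mean_off)
    while t < duration:
        length = rng.exponential(mean_len)
        end = min(t + length, duration)
        if end > t:
            intervals.append((t, end))
        t = end + rng.exponential(mean_off)
    return EpisodeTimeline(state=state, intervals=np.asarray(intervals).reshape(-1, 2))


def _enforce_dead_time(times: np.ndarray, dead: float) -> np.ndarray:
    """Drop spikes closer than ``dead`` seconds to the previously kept spike."""
    if times.size < 2 or dead <= 0:
        return times
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= dead:
            kept.append(t)
    return np.asarray(kept)


def piecewise_poisson(
    base_rate: float,
    gain: float,
    timeline: EpisodeTimeline | None,
    duration: float,
    rng: np.random.Generator,
    refractory_s: float = 0.0,
) -> np.ndarray:
    """Poisson spike train at ``base_rate``, multiplied by ``gain`` inside episodes.

    Optionally thinned by an absolute dead time (``refractory_s``) after each
    kept spike; at the default rates this removes <2% of spikes.
    """
    segments: list[tuple[float, float, float]] = []
    t = 0.0
    if timeline is not None and len(timeline):
        for on, off in timeline.intervals:
            on, off = max(on, 0.0), min(off, duration)
            if on > t:
                segments.append((t, on, base_rate))
            if off > on:
                segments.append((on, off, base_rate * gain))
            t = max(t, off)
    if t < duration:
        segments.append((t, duration, base_rate))
    pieces = []
    for t0, t1, rate in segments:
        n = rng.poisson(rate * (t1 - t0))
        if n:
            pieces.append(t0 + rng.random(n) * (t1 - t0))
    if not pieces:
        return np.empty(0)
    times = np.sort(np.concatenate(pieces))
    # strict monotonicity: merge coincident samples (prob ~0 but guard)
    times = times[np.concatenate(([True], np.diff(times) > 0))]
    if refractory_s > 0:
        times = _enforce_dead_time(times, refractory_s)
    return times


def generate_unit_sessions(config: SimConfig) -> SimulatedExperiment:
    """Simulate the three-session experiment for a ground-truth-labeled population.

    Coding classes are assigned in fixed proportion (largest-remainder
    rounding), base rates drawn uniformly from ``base_rate_range``, waveform
    phenotypes with probability ``in_fraction`` of being an interneuron.
    Each session shares one behavior timeline across units, as in a real
    recording.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_assign, rng_timeline, rng_units = [np.random.default_rng(s) for s in ss.spawn(3)]

    n = config.n_units
    counts = _largest_remainder([config.class_fractions[c] for c in CODING_CLASSES], n)
    classes = np.repeat(CODING_CLASSES, counts)
    rng_assign.shuffle(classes)

    phenotypes = np.where(rng_assign.random(n) < config.in_fraction, "interneuron", "principal")
    lo, hi = config.base_rate_range
    base_rates = rng_assign.uniform(lo, hi, n)

    timelines: dict[str, EpisodeTimeline] = {
        "baseline": EpisodeTimeline(state="none", intervals=np.empty((0, 2)))
    }
    for session in ("fear", "pain"):
        state = _SESSION_STATE[session]
        mean_len, duty = config.episode_stats[state]
        timelines[session] = generate_episode_timeline(
            state, config.session_durations[session], mean_len, duty, rng_timeline
        )

    feats = {k: np.empty(n) for k in ("half_amplitude_duration_ms", "trough_to_peak_ms")}
    spikes: dict[str, dict[str, np.ndarray]] = {s: {} for s in SESSION_NAMES}
    unit_ids = [f"u{i:04d}" for i in range(n)]
    dead = config.refractory_s if config.enforce_refractory else 0.0
    for i, uid in enumerate(unit_ids):
        wf = config.waveform_params[str(phenotypes[i])]
        for k in feats:
            mu, sd = wf[k]
            feats[k][i] = max(rng_units.normal(mu, sd), 0.05)
        gained = _CLASS_SESSIONS[str(classes[i])]
        for session in SESSION_NAMES:
            gain = config.episode_gain if session in gained else 1.0
            spikes[session][uid] = piecewise_poisson(
                base_rates[i],
                gain,
                timelines[session],
                config.session_durations[session],
                rng_units,
                refractory_s=dead,
            )

    truth = pd.DataFrame(
        {
            "unit_id": unit_ids,
            "coding_class": classes,
            "phenotype": phenotypes,
            "base_rate_hz": base_rates,
            "gain": [
                config.episode_gain if _CLASS_SESSIONS[str(c)] else 1.0 for c in classes
            ],
            "half_amplitude_duration_ms": feats["half_amplitude_duration_ms"],
            "trough_to_peak_ms": feats["trough_to_peak_ms"],
        }
    )
    return SimulatedExperiment(spikes=spikes, timelines=timelines, truth=truth, config=config)


def generate_same_state_pairs(
    n_units: int,
    duration: float = 240.0,
    rate_range: tuple[float, float] = (0.5, 10.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Repeated same-state sessions: each unit keeps one Poisson rate in both.

    Returns a frame with the true rate and the two empirical mean rates over
    ``duration``-second windows, the input for calibrating the same-state
    firing-rate null.
    """
    rng = np.random.default_rng(seed)
    rates = rng.uniform(*rate_range, n_units)
    c1 = rng.poisson(rates * duration)
    c2 = rng.poisson(rates * duration)
    return pd.DataFrame(
        {
            "unit_id": [f"u{i:04d}" for i in range(n_units)],
            "true_rate_hz": rates,
            "rate1_hz": c1 / duration,
            "rate2_hz": c2 / duration,
        }
    )


def biphasic_template(
    half_amplitude_duration_ms: float,
    trough_to_peak_ms: float,
    amplitude: float,
    fs: float,
    peak_fraction: float = 0.4,
    snippet_ms: float = 2.0,
) -> np.ndarray:
    """Piecewise-linear biphasic spike template with exact designed features.

    Trough depth is ``amplitude`` (volts, inserted negative); the subsequent
    positive peak is ``peak_fraction`` of the depth, placed exactly
    ``trough_to_peak_ms`` after the trough.  The descent width is solved so
    the width of the trough at half its depth equals
    ``half_amplitude_duration_ms``.
    """
    if amplitude <= 0:
        raise ValidationError(f"template amplitude must be positive, got {amplitude}")
    h = half_amplitude_duration_ms / 1000.0
    t2p = trough_to_peak_ms / 1000.0
    if h <= 0 or t2p <= 0:
        raise ValidationError("waveform features must be positive")
    p = peak_fraction
    # ascent (trough -> +p*A over t2p) crosses -A/2 at t2p/(2(1+p)) after the trough
    ascent_cross = t2p / (2.0 * (1.0 + p))
    descent = max(2.0 * (h - ascent_cross), 2.0 / fs)
    decay = 0.3 * t2p
    total = descent + t2p + decay
    n = int(round(snippet_ms / 1000.0 * fs))
    n = max(n, int(np.ceil(total * fs)) + 2)
    t = np.arange(n) / fs
    w = np.zeros(n)
    trough_t = descent
    m = t <= trough_t
    w[m] = -amplitude * (t[m] / descent)
    m = (t > trough_t) & (t <= trough_t + t2p)
    w[m] = -amplitude + (1.0 + p) * amplitude * (t[m] - trough_t) / t2p
    m = (t > trough_t + t2p) & (t <= trough_t + t2p + decay)
    w[m] = p * amplitude * (1.0 - (t[m] - trough_t - t2p) / decay)
    return w


def generate_voltage_trace(
    spike_trains: Mapping[str, np.ndarray],
    config: SimConfig,
    duration: float,
    n_channels: int = 4,
    amplitude_sigma: float = 10.0,
    templates: Mapping[str, np.ndarray] | None = None,
    channel_of: Mapping[str, int] | None = None,
    seed: int | None = None,
) -> tuple[VoltageTrace, dict[str, np.ndarray]]:
    """Gaussian noise plus biphasic templates inserted at each unit's spike times.

    Template amplitude is ``amplitude_sigma`` times the noise s.d.; units are
    assigned round-robin to channels unless ``channel_of`` is given.  Returns
    the trace together with the ground-truth spike times actually inserted
    (those whose template fits inside the trace).
    """
    if amplitude_sigma <= 0:
        raise ValidationError("spike amplitude (in noise s.d. units) must be positive")
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_samples = int(round(duration * config.fs))
    sigma = config.noise_sigma
    if n_samples == 0:
        return VoltageTrace(np.zeros((n_channels, 0)), fs=config.fs), {
            uid: np.empty(0) for uid in spike_trains
        }
    samples = rng.normal(0.0, sigma, size=(n_channels, n_samples))
    default_template = biphasic_template(0.35, 0.60, amplitude_sigma * sigma, config.fs)
    inserted: dict[str, np.ndarray] = {}
    for j, (uid, times) in enumerate(spike_trains.items()):
        tpl = default_template if templates is None else templates[uid]
        ch = j % n_channels if channel_of is None else channel_of[uid]
        trough_idx = int(np.argmin(tpl))
        starts = np.round(np.asarray(times) * config.fs).astype(int) - trough_idx
        ok = (starts >= 0) & (starts + tpl.size <= n_samples)
        for s in starts[ok]:
            samples[ch, s : s + tpl.size] += tpl
        inserted[uid] = (starts[ok] + trough_idx) / config.fs
    return VoltageTrace(samples, fs=config.fs), inserted


def generate_count_table(
    densities: Mapping[str, float],
    true_overlap: float,
    volume_mm3: float,
    seed: int | np.random.Generator,
    region: str = "PL",
) -> CountTable:
    """Poisson/multinomial-sampled dual-label cell-count table.

    ``densities`` gives expected counts per mm^3 for keys ``fos``, ``tag``
    and ``dapi``.  ``true_overlap`` interpolates the double-positive
    probability between statistical independence (0) and complete nesting of
    the rarer label inside the commoner one (1).
    """
    if any(v < 0 for v in densities.values()):
        raise ValidationError("densities must be non-negative")
    if not (0 <= true_overlap <= 1):
        raise ValidationError("true_overlap must be in [0,1]")
    if volume_mm3 < 0:
        raise ValidationError("volume must be non-negative")
    rng = np.random.default_rng(seed)
    if volume_mm3 == 0:
        return CountTable(region, 0, 0, 0, 0, 0.0)
    d_dapi = densities["dapi"]
    if d_dapi <= 0:
        raise ValidationError("dapi density must be positive for a non-empty volume")
    p_fos = min(densities["fos"] / d_dapi, 1.0)
    p_tag = min(densities["tag"] / d_dapi, 1.0)
    p_ind = p_fos * p_tag
    p_double = p_ind + true_overlap * (min(p_fos, p_tag) - p_ind)
    probs = np.array(
        [p_double, p_fos - p_double, p_tag - p_double, 1.0 - p_fos - p_tag + p_double]
    )
    probs = np.clip(probs, 0.0, 1.0)
    probs /= probs.sum()
    n_dapi = int(rng.poisson(d_dapi * volume_mm3))
    n_double, n_fos_only, n_tag_only, _ = rng.multinomial(n_dapi, probs)
    return CountTable(
        region=region,
        n_fos=int(n_double + n_fos_only),
        n_tag=int(n_double + n_tag_only),
        n_double=int(n_double),
        n_dapi=n_dapi,
        volume_mm3=volume_mm3,
    )


def generate_feature_mixture(
    n_units: int,
    in_fraction: float = 0.12,
    separation: float | None = None,
    seed: int = 0,
    waveform_params: Mapping[str, Mapping[str, tuple[float, float]]] | None = None,
) -> pd.DataFrame:
    """Two-phenotype Gaussian feature clouds for cell-typing experiments.

    With ``separation`` set, the per-feature gap between phenotype means is
    rescaled to exactly ``separation`` within-phenotype standard deviations
    (the pooled within-cluster s.d. of that feature), keeping the realistic
    feature scales and orientation of the default parameters.
    """
    params = waveform_params or SimConfig().waveform_params
    rng = np.random.default_rng(seed)
    n_in = int(round(n_units * in_fraction))
    labels = np.array(["interneuron"] * n_in + ["principal"] * (n_units - n_in))
    rng.shuffle(labels)
    cols = ["half_amplitude_duration_ms", "trough_to_peak_ms", "mean_rate_hz"]
    out = {"unit_id": [f"u{i:04d}" for i in range(n_units)], "phenotype": labels}
    for c in cols:
        mu = {ph: params[ph][c][0] for ph in ("principal", "interneuron")}
        sd = {ph: params[ph][c][1] for ph in ("principal", "interneuron")}
        if separation is not None:
            pooled_sd = 0.5 * (sd["principal"] + sd["interneuron"])
            center = 0.5 * (mu["principal"] + mu["interneuron"])
            sign = np.sign(mu["principal"] - mu["interneuron"]) or 1.0
            mu = {
                "principal": center + sign * separation * pooled_sd / 2.0,
                "interneuron": center - sign * separation * pooled_sd / 2.0,
            }
        vals = np.where(
            labels == "principal",
            rng.normal(mu["principal"], sd["principal"], n_units),
            rng.normal(mu["interneuron"], sd["interneuron"], n_units),
        )
        out[c] = np.maximum(vals, 1e-3)
    return pd.DataFrame(out)


def _largest_remainder(fractions: list[float], n: int) -> np.ndarray:
    """Integer class counts proportional to ``fractions`` summing exactly to n."""
    raw = np.asarray(fractions) * n
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:rem]] += 1
    return base
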