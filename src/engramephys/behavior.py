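"""Behavior-episode-locked firing-rate analysis.

Firing is binned with a 0.8-s sliding window advanced in 0.4-s steps.  Bins
of the fear and pain sessions are split into those falling inside a freezing
or nocifensive episode and those outside; boundary-straddling bins are
excluded.  Each unit's in-episode rates are compared to the binned rates of
the unstimulated baseline session with a randomized permutation test on the
group-mean difference; a unit counts as behavior-locked in a state when
p < 0.001 and the standardized effect size exceeds 0.5.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd

from .core import EpisodeTimeline, UnitSpikeTrain, ValidationError

BEHAVIOR_CATEGORIES = ("fear_specific", "pain_specific", "common", "unspecific")
DEFAULT_ALPHA = 0.001
DEFAULT_MIN_EFFECT = 0.5


@dataclasses.dataclass
class BinnedRates:
    """Sliding-window firing rates of one unit over one session."""

    bin_onsets: np.ndarray
    bin_width: float
    rates: np.ndarray

    @property
    def bin_offsets(self) -> np.ndarray:
        return self.bin_onsets + self.bin_width

    def normalized(self, baseline_mean: float) -> np.ndarray:
        """Rates divided by the baseline-session mean rate (heat-map display)."""
        if baseline_mean <= 0:
            raise ValidationError("baseline mean rate must be positive to normalize")
        return self.rates / baseline_mean


@dataclasses.dataclass
class PermutationResult:
    p: float
    effect: float
    observed_diff: float
    n_in: int
    n_ref: int


def bin_rates(
    spikes: UnitSpikeTrain | np.ndarray,
    span: tuple[float, float],
    width: float = 0.8,
    step: float = 0.4,
) -> BinnedRates:
    """Sliding-window mean rates: count in [onset, onset+width) / width."""
    if width <= 0 or not (0 < step <= width):
        raise ValidationError(f"need width > 0 and 0 < step <= width, got ({width}, {step})")
    t0, t1 = span
    if t1 - t0 < width:
        raise ValidationError(f"span {span} is shorter than one bin ({width} s)")
    times = spikes.spike_times if isinstance(spikes, UnitSpikeTrain) else np.asarray(spikes)
    n_bins = int(np.floor((t1 - t0 - width) / step + 1e-9)) + 1
    onsets = t0 + step * np.arange(n_bins)
    counts = np.searchsorted(times, onsets + width, "left") - np.searchsorted(
        times, onsets, "left"
    )
    return BinnedRates(bin_onsets=onsets, bin_width=width, rates=counts / width)


def assign_bins(
    bins: BinnedRates, timeline: EpisodeTimeline
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Partition bins into in-episode / out-of-episode / excluded index arrays.

    A bin is *in* when it lies entirely inside one episode, *out* when it
    does not overlap any episode, and *excluded* when it straddles an episode
    boundary.  An empty timeline puts every bin in the out group.
    """
    on, off = bins.bin_onsets, bins.bin_offsets
    if not len(timeline):
        idx = np.arange(on.size)
        return np.empty(0, dtype=int), idx, np.empty(0, dtype=int)
    ep_on, ep_off = timeline.intervals[:, 0], timeline.intervals[:, 1]
    cand = np.searchsorted(ep_on, on, side="right") - 1
    valid = cand >= 0
    in_mask = np.zeros(on.size, dtype=bool)
    in_mask[valid] = off[valid] <= ep_off[cand[valid]]
    # overlap: some episode starts before the bin ends and ends after it starts
    first_possible = np.searchsorted(ep_off, on, side="right")
    overlap = (first_possible < len(timeline)) & (
        ep_on[np.minimum(first_possible, len(timeline) - 1)] < off
    )
    out_mask = ~overlap
    excluded_mask = ~in_mask & ~out_mask
    idx = np.arange(on.size)
    return idx[in_mask], idx[out_mask], idx[excluded_mask]


def permutation_test(
    in_rates: np.ndarray,
    reference_rates: np.ndarray,
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
    block: int = 1,
) -> PermutationResult:
    """One-sided randomized permutation test for an increase of the in-group mean.

    The observed statistic is mean(in) - mean(reference); the null pools both
    groups and re-splits them at the original sizes ``n_perm`` times, giving
    p = (1 + #{null >= observed}) / (n_perm + 1).  The effect size is the
    standardized mean difference with the pooled s.d. in the denominator.
    ``block > 1`` permutes contiguous blocks of bins instead of single bins
    (an exchangeability-respecting variant for overlapping windows).
    """
    a = np.asarray(in_rates, dtype=float).ravel()
    b = np.asarray(reference_rates, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValidationError("permutation test needs both groups non-empty")
    if n_perm < 999:
        raise ValidationError(f"n_perm must be >= 999, got {n_perm}")
    obs = float(a.mean() - b.mean())
    va = a.var(ddof=1) if a.size > 1 else 0.0
    vb = b.var(ddof=1) if b.size > 1 else 0.0
    dof = a.size + b.size - 2
    pooled_sd = float(np.sqrt(((a.size - 1) * va + (b.size - 1) * vb) / dof)) if dof > 0 else 0.0
    if pooled_sd == 0.0:
        if obs == 0.0:
            return PermutationResult(1.0, 0.0, 0.0, a.size, b.size)
        effect = np.inf if obs > 0 else -np.inf
    else:
        effect = obs / pooled_sd
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    if block > 1:
        nb = int(np.ceil(pooled.size / block))
        pad = np.full(nb * block - pooled.size, np.nan)
        blocks = np.concatenate([pooled, pad]).reshape(nb, block)
        exceed = 0
        for _ in range(n_perm):
            perm = blocks[rng.permutation(nb)].ravel()
            perm = perm[~np.isnan(perm)]
            if perm[: a.size].mean() - perm[a.size :].mean() >= obs:
                exceed += 1
    else:
        exceed = _null_exceedances(pooled, a.size, obs, n_perm, rng)
    p = (1.0 + exceed) / (n_perm + 1.0)
    return PermutationResult(float(p), float(effect), obs, a.size, b.size)


def _null_exceedances(
    pooled: np.ndarray, n_in: int, obs: float, n_perm: int, rng: np.random.Generator
) -> int:
    """Count permutations whose group-mean difference meets or exceeds ``obs``.

    The statistic is monotone in the in-group sum, so only that sum is
    resampled.  Permutations are vectorized in chunks to bound memory.
    """
    n = pooled.size
    n_ref = n - n_in
    # diff = s_in/n_in - (total - s_in)/n_ref, increasing in s_in
    total = pooled.sum()
    s_obs = obs * n_in * n_ref / n + total * n_in / n
    chunk = max(1, int(4e7) // n)
    exceed = 0
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        mat = np.broadcast_to(pooled, (m, n)).copy()
        rng.permuted(mat, axis=1, out=mat)
        s_in = mat[:, :n_in].sum(axis=1)
        exceed += int(np.sum(s_in >= s_obs - 1e-9 * max(1.0, abs(s_obs))))
        done += m
    return exceed


def test_unit_state(
    spikes: np.ndarray,
    session_span: tuple[float, float],
    timeline: EpisodeTimeline,
    baseline_spikes: np.ndarray,
    baseline_span: tuple[float, float],
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
    width: float = 0.8,
    step: float = 0.4,
) -> PermutationResult:
    """Behavior-locked test of one unit in one state against baseline bins."""
    bins = bin_rates(spikes, session_span, width, step)
    in_idx, _, _ = assign_bins(bins, timeline)
    if in_idx.size == 0:
        raise ValidationError("no bins fall entirely inside an episode")
    base_bins = bin_rates(baseline_spikes, baseline_span, width, step)
    return permutation_test(bins.rates[in_idx], base_bins.rates, n_perm, seed)


def classify_behavior(
    results: Mapping[str, Mapping[str, PermutationResult]],
    alpha: float = DEFAULT_ALPHA,
    min_effect: float = DEFAULT_MIN_EFFECT,
) -> pd.DataFrame:
    """Assign units to fear-specific / pain-specific / common / unspecific.

    ``results`` maps unit id -> {"fear": PermutationResult, "pain": ...}.
    A unit is significant in a state when p < alpha and effect > min_effect.
    Units missing either state are excluded.
    """
    rows = []
    for uid, res in results.items():
        if "fear" not in res or "pain" not in res:
            continue
        sig = {
            s: (res[s].p < alpha) and (res[s].effect > min_effect) for s in ("fear", "pain")
        }
        if sig["fear"] and sig["pain"]:
            cat = "common"
        elif sig["fear"]:
            cat = "fear_specific"
        elif sig["pain"]:
            cat = "pain_specific"
        else:
            cat = "unspecific"
        rows.append(
            {
                "unit_id": uid,
                "p_fear": res["fear"].p,
                "effect_fear": res["fear"].effect,
                "p_pain": res["pain"].p,
                "effect_pain": res["pain"].effect,
                "category": cat,
            }
        )
    return pd.DataFrame(rows)
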