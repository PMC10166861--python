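"""Global rate-coding classification against a same-state null.

A unit's mean firing rate is measured over fixed windows — 4 min of the
unstimulated baseline, 7 min of the cued fear-recall session and the first
3 min after capsaicin injection — and the log ratio of each state's rate to
the baseline rate is compared to a threshold of 2 standard deviations of an
empirically calibrated null: the pooled distribution of log rate ratios
between repeated encounters of the *same* state.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .core import UnitSpikeTrain, ValidationError

MIN_RATE_HZ = 0.05
GLOBAL_CATEGORIES = ("fear_only", "pain_only", "common", "neither")


@dataclasses.dataclass
class SessionWindows:
    """Analysis windows (s from session start) for the three sessions."""

    baseline: tuple[float, float] = (0.0, 240.0)
    fear: tuple[float, float] = (0.0, 420.0)
    pain: tuple[float, float] = (0.0, 180.0)

    def __post_init__(self) -> None:
        for name in ("baseline", "fear", "pain"):
            t0, t1 = getattr(self, name)
            if t1 <= t0:
                raise ValidationError(f"{name} window must have positive length")

    def clipped(self, durations: Mapping[str, float]) -> "SessionWindows":
        """Shrink each window to the available session duration."""
        out = {}
        for name in ("baseline", "fear", "pain"):
            t0, t1 = getattr(self, name)
            out[name] = (t0, min(t1, durations[name]))
        return SessionWindows(**out)


@dataclasses.dataclass
class SameStateNull:
    """Empirical null for log firing-rate ratios between same-state sessions."""

    log_ratios: np.ndarray
    sigma: float
    mean: float
    n: int

    @property
    def threshold(self) -> float:
        return 2.0 * self.sigma


@dataclasses.dataclass
class GlobalCoding:
    """Per-unit global rate-coding outcome."""

    unit_id: str
    fear_direction: str  # increased | decreased | none | unclassifiable
    pain_direction: str
    category: str  # fear_only | pain_only | common | neither | unclassifiable
    log_ratio_fear: float | None = None
    log_ratio_pain: float | None = None


def mean_rate(
    spikes: UnitSpikeTrain | np.ndarray, window: tuple[float, float]
) -> float:
    """Mean firing rate (Hz): spike count inside the window / window length."""
    t0, t1 = window
    if t1 <= t0:
        raise ValidationError(f"window must have positive length, got {window}")
    times = spikes.spike_times if isinstance(spikes, UnitSpikeTrain) else np.asarray(spikes)
    count = int(np.searchsorted(times, t1, "left") - np.searchsorted(times, t0, "left"))
    return count / (t1 - t0)


def fit_same_state_null(
    rate_pairs: Iterable[tuple[float, float]], min_rate: float = MIN_RATE_HZ
) -> SameStateNull:
    """Pool log ratios of second- to first-session rates from same-state pairs.

    Pairs with either rate below ``min_rate`` are excluded (a log ratio of a
    near-zero rate would dominate the spread).  The s.d. is computed about the
    sample mean; a mean larger than sigma/2 triggers a data-quality warning
    since the pooled distribution should be centered on 0.
    """
    pairs = np.asarray(list(rate_pairs), dtype=float).reshape(-1, 2)
    ok = np.all(pairs >= min_rate, axis=1)
    pairs = pairs[ok]
    if pairs.shape[0] < 10:
        raise ValidationError(
            f"only {pairs.shape[0]} usable same-state pairs (need >= 10): null unstable"
        )
    log_ratios = np.log(pairs[:, 1] / pairs[:, 0])
    sigma = float(np.std(log_ratios, ddof=1))
    mu = float(np.mean(log_ratios))
    if sigma > 0 and abs(mu) >= sigma / 2:
        warnings.warn(
            f"same-state log ratios not centered on 0 (mean {mu:.3f}, sigma {sigma:.3f}); "
            "possible drift between repeated sessions"
        )
    return SameStateNull(log_ratios=log_ratios, sigma=sigma, mean=mu, n=pairs.shape[0])


def _direction(log_ratio: float, threshold: float) -> str:
    if log_ratio > threshold:
        return "increased"
    if log_ratio < -threshold:
        return "decreased"
    return "none"


def categorize(fear_direction: str, pain_direction: str) -> str:
    """Category is a pure function of the two per-state directions."""
    f, p = fear_direction != "none", pain_direction != "none"
    if f and p:
        return "common"
    if f:
        return "fear_only"
    if p:
        return "pain_only"
    return "neither"


def classify_global(
    rates: Mapping[str, Mapping[str, float]] | pd.DataFrame,
    null: SameStateNull,
    min_rate: float = MIN_RATE_HZ,
) -> pd.DataFrame:
    """Classify every unit's global rate change in fear and pain vs baseline.

    ``rates`` maps unit id -> {baseline, fear, pain} mean rates (or a frame
    with those columns indexed by unit id).  A unit whose baseline — or
    either comparison — rate falls below ``min_rate`` is unclassifiable and
    excluded from category totals.
    """
    if isinstance(rates, pd.DataFrame):
        rates = {uid: row for uid, row in rates[["baseline", "fear", "pain"]].iterrows()}
    rows = []
    thr = null.threshold
    for uid, r in rates.items():
        rb, rf, rp = r["baseline"], r["fear"], r["pain"]
        if rb < min_rate or rf < min_rate or rp < min_rate:
            rows.append(
                GlobalCoding(str(uid), "unclassifiable", "unclassifiable", "unclassifiable")
            )
            continue
        lf, lp = math.log(rf / rb), math.log(rp / rb)
        fd, pdir = _direction(lf, thr), _direction(lp, thr)
        rows.append(GlobalCoding(str(uid), fd, pdir, categorize(fd, pdir), lf, lp))
    return pd.DataFrame(
        {
            "unit_id": [g.unit_id for g in rows],
            "fear_direction": [g.fear_direction for g in rows],
            "pain_direction": [g.pain_direction for g in rows],
            "category": [g.category for g in rows],
            "log_ratio_fear": [g.log_ratio_fear for g in rows],
            "log_ratio_pain": [g.log_ratio_pain for g in rows],
        }
    )


def session_rates(
    spikes: Mapping[str, Mapping[str, np.ndarray]], windows: SessionWindows
) -> pd.DataFrame:
    """Mean rate per unit per session over the analysis windows."""
    units = sorted(spikes["baseline"])
    data = {
        name: [mean_rate(spikes[name][u], getattr(windows, name)) for u in units]
        for name in ("baseline", "fear", "pain")
    }
    return pd.DataFrame(data, index=pd.Index(units, name="unit_id"))


def summarize_categories(coding: pd.DataFrame) -> pd.Series:
    """Category counts, with the common-increased subset reported separately."""
    counts = coding["category"].value_counts()
    common_increased = int(
        ((coding["fear_direction"] == "increased") & (coding["pain_direction"] == "increased")).sum()
    )
    counts["common_increased"] = common_increased
    return counts
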