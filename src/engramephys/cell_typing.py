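"""Waveform-based cell typing: putative principal neurons vs interneurons.

Units are clustered by Ward-linkage agglomerative clustering on Euclidean
distances over the z-scored half-amplitude duration, trough-to-peak time and
mean firing rate, cut at the two most prominent clusters.  The narrow-
waveform, fast-firing cluster is labeled interneuron — the standard cortical
extracellular convention.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .core import ValidationError

FEATURE_COLUMNS = ("half_amplitude_duration_ms", "trough_to_peak_ms", "mean_rate_hz")


@dataclasses.dataclass
class FeatureMatrix:
    """Per-unit waveform/rate features with a z-scored copy."""

    unit_ids: list[str]
    raw: pd.DataFrame  # columns = FEATURE_COLUMNS (constant ones dropped)
    z: np.ndarray

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "FeatureMatrix":
        """Build from a frame with unit_id and the three feature columns.

        Constant columns (zero spread) carry no clustering information and are
        dropped with a warning.
        """
        missing = [c for c in FEATURE_COLUMNS if c not in frame.columns]
        if missing:
            raise ValidationError(f"missing feature columns: {missing}")
        if frame[list(FEATURE_COLUMNS)].isna().any().any():
            raise ValidationError("feature matrix contains missing values")
        ids = [str(u) for u in frame["unit_id"]] if "unit_id" in frame.columns else [
            str(i) for i in range(len(frame))
        ]
        raw = frame[list(FEATURE_COLUMNS)].astype(float).reset_index(drop=True)
        keep = []
        for c in raw.columns:
            if raw[c].std(ddof=0) > 0:
                keep.append(c)
            else:
                warnings.warn(f"feature {c} is constant; dropped from clustering")
        if not keep:
            raise ValidationError("all feature columns are constant")
        kept = raw[keep]
        z = (kept - kept.mean()) / kept.std(ddof=0)
        return cls(unit_ids=ids, raw=raw[keep], z=z.to_numpy())


def cluster_units(features: FeatureMatrix, k: int = 2) -> np.ndarray:
    """Ward-linkage clustering on z-scored features; tree cut at ``k`` clusters.

    Returns integer labels in 0..k-1 (relabeled by first occurrence, so the
    labeling is row-order stable).
    """
    n = features.z.shape[0]
    if n < k:
        raise ValidationError(f"need at least {k} units to form {k} clusters, got {n}")
    tree = linkage(features.z, method="ward", metric="euclidean")
    labels = fcluster(tree, t=k, criterion="maxclust") - 1
    _, labels = np.unique(labels, return_inverse=True)
    return labels


def label_clusters(labels: np.ndarray, features: FeatureMatrix) -> pd.DataFrame:
    """Name the two clusters: narrow-waveform & fast-firing -> interneuron.

    The cluster with the smaller mean trough-to-peak time *and* higher mean
    firing rate is the putative interneuron cluster; if the two criteria
    disagree (or rate is unavailable), trough-to-peak alone decides, with an
    ambiguity warning.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValidationError(f"phenotype labeling needs exactly 2 clusters, got {uniq.size}")
    t2p = features.raw["trough_to_peak_ms"] if "trough_to_peak_ms" in features.raw else None
    rate = features.raw["mean_rate_hz"] if "mean_rate_hz" in features.raw else None
    if t2p is None:
        raise ValidationError("trough_to_peak_ms required to name clusters")
    t2p_means = {c: t2p[labels == c].mean() for c in uniq}
    narrow = min(uniq, key=lambda c: t2p_means[c])
    if rate is not None:
        rate_means = {c: rate[labels == c].mean() for c in uniq}
        fast = max(uniq, key=lambda c: rate_means[c])
        if fast != narrow:
            warnings.warn(
                "ambiguous clusters (narrower waveform but slower firing); "
                "assigning interneuron by trough-to-peak alone"
            )
    phen = np.where(labels == narrow, "interneuron", "principal")
    return pd.DataFrame({"unit_id": features.unit_ids, "cluster": labels, "phenotype": phen})


def type_units(frame: pd.DataFrame) -> pd.DataFrame:
    """Convenience: features -> Ward clusters -> named phenotypes."""
    fm = FeatureMatrix.from_frame(frame)
    labels = cluster_units(fm, k=2)
    return label_clusters(labels, fm)
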