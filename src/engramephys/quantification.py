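"""Dual-label overlap statistics, cell densities and intensity binning.

The chance level of dual labeling under independence is
(Fos+/DAPI) x (tag+/DAPI) x 100%; the observed overlap is the
double-positive count as a percentage of either single-label population.
The projection-image intensity rule maps 8-bit pixel values onto nine
coarse levels (fine 10-wide steps up to 50, then 50-wide steps).
"""

from __future__ import annotations

import numpy as np

from .core import CountTable, ValidationError

_INTENSITY_EDGES = np.array([0, 10, 20, 30, 40, 50, 100, 150, 200], dtype=float)


def chance_overlap(table: CountTable) -> float:
    """Expected double-positive percentage of all nuclei under independence."""
    if table.n_dapi == 0:
        raise ValidationError("chance overlap undefined: no DAPI nuclei counted")
    return 100.0 * (table.n_fos / table.n_dapi) * (table.n_tag / table.n_dapi)


def observed_overlap(table: CountTable, denominator: str = "tag") -> float:
    """Double-positive count as a percentage of one single-label population.

    ``denominator`` is ``"tag"`` (double positives among tagged neurons) or
    ``"fos"`` (among Fos-expressing neurons); both framings are reported in
    dual-label engram studies.
    """
    if denominator not in ("tag", "fos"):
        raise ValidationError(f"denominator must be 'tag' or 'fos', got {denominator!r}")
    denom = table.n_tag if denominator == "tag" else table.n_fos
    if denom == 0:
        raise ValidationError(f"observed overlap undefined: {denominator} count is 0")
    return 100.0 * table.n_double / denom


def double_positive_fraction_of_dapi(table: CountTable) -> float:
    """Observed double-positive percentage of all nuclei (chance-comparable scale)."""
    if table.n_dapi == 0:
        raise ValidationError("undefined: no DAPI nuclei counted")
    return 100.0 * table.n_double / table.n_dapi


def density(count: int, volume_mm3: float) -> float:
    """Labeled cells per mm^3."""
    if volume_mm3 <= 0:
        raise ValidationError(f"volume must be positive, got {volume_mm3}")
    if count < 0:
        raise ValidationError("count must be non-negative")
    return count / volume_mm3


def bin_intensity(value):
    """Coarse-bin 8-bit pixel intensities onto nine levels.

    [0,10)->0, [10,20)->10, [20,30)->20, [30,40)->30, [40,50)->40,
    [50,100)->50, [100,150)->100, [150,200)->150, [200,255]->200.
    Lower edges inclusive; the top bin is closed at 255.  Accepts scalars or
    arrays; rejects values outside [0, 255].
    """
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0) or np.any(arr > 255):
        raise ValidationError("pixel intensity must lie in [0, 255]")
    idx = np.searchsorted(_INTENSITY_EDGES, arr, side="right") - 1
    out = _INTENSITY_EDGES[idx]
    if np.isscalar(value) or np.ndim(value) == 0:
        return float(out)
    return out
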