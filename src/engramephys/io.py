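"""Fixed, documented file dialects for everything the pipeline touches.

Traces travel as flat little-endian int16, channel-interleaved, with a JSON
sidecar ``{fs_hz, n_channels, volts_per_bit}``.  Spike trains, episode
timelines, count tables and result tables are headered CSV with seconds
printed to 6 decimals, so every writer is byte-deterministic.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .core import CountTable, EpisodeTimeline, UnitSpikeTrain, ValidationError, VoltageTrace

FLOAT_FORMAT = "%.6f"


@dataclasses.dataclass
class TraceSidecar:
    """Metadata accompanying a flat-binary voltage trace."""

    fs_hz: float
    n_channels: int
    volts_per_bit: float

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, indent=0) + "\n"

    @classmethod
    def from_path(cls, path: Path) -> "TraceSidecar":
        if not path.exists():
            raise ValidationError(f"missing sidecar {path}")
        d = json.loads(path.read_text())
        return cls(fs_hz=d["fs_hz"], n_channels=int(d["n_channels"]), volts_per_bit=d["volts_per_bit"])


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_trace(path: str | Path, trace: VoltageTrace, volts_per_bit: float = 1.0e-7) -> None:
    """Write int16 channel-interleaved binary plus JSON sidecar."""
    path = Path(path)
    q = np.clip(np.round(trace.samples / volts_per_bit), -32768, 32767).astype("<i2")
    q.T.reshape(-1).tofile(path)  # channel-interleaved: sample-major
    _sidecar_path(path).write_text(
        TraceSidecar(trace.fs, trace.n_channels, volts_per_bit).to_json()
    )


def read_trace(path: str | Path, sidecar: TraceSidecar | None = None) -> VoltageTrace:
    """Read a flat-binary trace; the sidecar is loaded from ``<path>.json`` if not given."""
    path = Path(path)
    sc = sidecar or TraceSidecar.from_path(_sidecar_path(path))
    nbytes = path.stat().st_size
    if nbytes % (2 * sc.n_channels) != 0:
        raise ValidationError(
            f"{path}: size {nbytes} B is not a multiple of 2 x {sc.n_channels} channels"
        )
    raw = np.fromfile(path, dtype="<i2").reshape(-1, sc.n_channels).T
    return VoltageTrace(raw.astype(float) * sc.volts_per_bit, fs=sc.fs_hz)


def write_spikes(path: str | Path, units: Mapping[str, np.ndarray]) -> None:
    """CSV (unit_id, time_s), sorted by unit id then time, 6-decimal seconds."""
    rows = []
    for uid in sorted(units):
        for t in np.sort(np.asarray(units[uid], dtype=float)):
            rows.append((uid, t))
    df = pd.DataFrame(rows, columns=["unit_id", "time_s"])
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_spikes(path: str | Path) -> dict[str, np.ndarray]:
    """Read a spike-time CSV into unit_id -> strictly increasing times."""
    df = pd.read_csv(path)
    for col in ("unit_id", "time_s"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    out: dict[str, np.ndarray] = {}
    for uid, g in df.groupby("unit_id", sort=True):
        t = np.sort(g["time_s"].to_numpy(dtype=float))
        t = t[np.concatenate(([True], np.diff(t) > 0))] if t.size else t
        out[str(uid)] = t
    return out


def write_episodes(path: str | Path, timelines: list[EpisodeTimeline]) -> None:
    """CSV (state, onset_s, offset_s), sorted by state then onset."""
    rows = []
    for tl in sorted(timelines, key=lambda t: t.state):
        for on, off in tl.intervals:
            rows.append((tl.state, on, off))
    pd.DataFrame(rows, columns=["state", "onset_s", "offset_s"]).to_csv(
        path, index=False, float_format=FLOAT_FORMAT
    )


def read_episodes(path: str | Path) -> list[EpisodeTimeline]:
    """Read and validate an episode CSV; overlap errors name the offending rows."""
    df = pd.read_csv(path)
    for col in ("state", "onset_s", "offset_s"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    out = []
    for state, g in df.groupby("state", sort=True):
        iv = g[["onset_s", "offset_s"]].to_numpy(dtype=float)
        bad = np.flatnonzero(iv[:, 1] <= iv[:, 0])
        if bad.size:
            raise ValidationError(
                f"{path}: offset <= onset at rows {g.index[bad].tolist()} (state {state!r})"
            )
        order = np.argsort(iv[:, 0])
        iv = iv[order]
        olap = np.flatnonzero(iv[1:, 0] < iv[:-1, 1])
        if olap.size:
            raise ValidationError(
                f"{path}: overlapping episodes at rows "
                f"{g.index[order][olap + 1].tolist()} (state {state!r})"
            )
        out.append(EpisodeTimeline(state=str(state), intervals=iv))
    return out


def write_count_tables(path: str | Path, tables: list[CountTable]) -> None:
    df = pd.DataFrame(
        [
            (t.region, t.n_fos, t.n_tag, t.n_double, t.n_dapi, t.volume_mm3)
            for t in sorted(tables, key=lambda t: t.region)
        ],
        columns=["region", "n_fos", "n_tag", "n_double", "n_dapi", "volume_mm3"],
    )
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_count_tables(path: str | Path) -> list[CountTable]:
    df = pd.read_csv(path)
    needed = ["region", "n_fos", "n_tag", "n_double", "n_dapi", "volume_mm3"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    return [
        CountTable(
            region=str(r.region),
            n_fos=int(r.n_fos),
            n_tag=int(r.n_tag),
            n_double=int(r.n_double),
            n_dapi=int(r.n_dapi),
            volume_mm3=float(r.volume_mm3),
        )
        for r in df.itertuples()
    ]


def write_results(out_dir: str | Path, tables: Mapping[str, pd.DataFrame]) -> list[Path]:
    """Write each result table as ``<name>.csv`` with fixed float formatting."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name in sorted(tables):
        p = out_dir / f"{name}.csv"
        tables[name].to_csv(p, index=False, float_format=FLOAT_FORMAT)
        paths.append(p)
    return paths


def write_unit_table(path: str | Path, units: list[UnitSpikeTrain]) -> None:
    """Per-unit summary CSV (spike counts, features, refractory fraction)."""
    df = pd.DataFrame(
        [
            {
                "unit_id": u.unit_id,
                "n_spikes": u.n_spikes,
                "mean_rate_hz": u.mean_rate_hz,
                "half_amplitude_duration_ms": u.half_amplitude_duration_ms,
                "trough_to_peak_ms": u.trough_to_peak_ms,
                "refractory_fraction": u.refractory_fraction,
            }
            for u in sorted(units, key=lambda u: u.unit_id)
        ]
    )
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def provenance_record(config: Mapping, seed: int) -> dict:
    """Reproducibility record: config hash, seed and software versions."""
    blob = json.dumps({k: repr(v) for k, v in sorted(config.items())}, sort_keys=True)
    return {
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": int(seed),
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }


def write_provenance(path: str | Path, config: Mapping, seed: int) -> None:
    Path(path).write_text(json.dumps(provenance_record(config, seed), indent=2, sort_keys=True) + "\n")
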