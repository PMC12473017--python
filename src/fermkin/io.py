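"""Delimited-text formats and metadata sidecars.

The exchange format for trajectories is a plain CSV with header

    time_d,replicate,dcw_g_per_L,glucose_g_per_L,dha_g_per_L

one row per observation, missing values empty.  Floats are written
with Python's shortest round-trip representation, so a write/read
cycle is lossless to full double precision.

Every written data file gets a JSON sidecar (``<file>.meta.json``)
carrying the tool version, the seed (when randomness was involved) and
a SHA-256 hash of the canonicalized run configuration, enabling exact
re-runs.  Sidecars contain no timestamps: identical configurations
produce byte-identical outputs.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import TimeCourse

__all__ = [
    "TIMECOURSE_COLUMNS",
    "read_timecourse",
    "write_timecourse",
    "timecourse_frame",
    "config_hash",
    "write_sidecar",
]

TIMECOURSE_COLUMNS = (
    "time_d",
    "replicate",
    "dcw_g_per_L",
    "glucose_g_per_L",
    "dha_g_per_L",
)


def timecourse_frame(tc: TimeCourse) -> pd.DataFrame:
    """Tabular view of a trajectory, one row per observation."""
    return pd.DataFrame(
        {
            "time_d": tc.times,
            "replicate": tc.replicate,
            "dcw_g_per_L": tc.X,
            "glucose_g_per_L": tc.S,
            "dha_g_per_L": tc.P,
        }
    )


def write_timecourse(tc: TimeCourse, path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write(",".join(TIMECOURSE_COLUMNS) + "\n")
        for i in range(len(tc)):
            vals = (tc.X[i], tc.S[i], tc.P[i])
            fh.write(
                f"{float(tc.times[i])!r},{int(tc.replicate[i])},"
                + ",".join("" if np.isnan(v) else repr(float(v)) for v in vals)
                + "\n"
            )
    return path


def read_timecourse(path, label: str | None = None) -> TimeCourse:
    """Parse a trajectory CSV; a malformed cell is reported with its line."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    missing = set(TIMECOURSE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    cols = {}
    for col in TIMECOURSE_COLUMNS:
        values = np.empty(len(df), dtype=float)
        for i, raw in enumerate(df[col]):
            blank = raw is None or (isinstance(raw, float) and np.isnan(raw)) or str(raw).strip() == ""
            if blank:
                if col in ("time_d", "replicate"):
                    raise ValueError(f"{path}, line {i + 2}: {col} must not be missing")
                values[i] = np.nan
                continue
            try:
                values[i] = float(raw)  # float() is correctly rounded: lossless round-trip
            except ValueError:
                raise ValueError(
                    f"{path}, line {i + 2}: cannot parse {col} value {raw!r}"
                ) from None
        cols[col] = values
    return TimeCourse(
        cols["time_d"],
        cols["dcw_g_per_L"],
        cols["glucose_g_per_L"],
        cols["dha_g_per_L"],
        replicate=cols["replicate"].astype(int),
        label=path.stem if label is None else label,
    )


def config_hash(config: dict) -> str:
    """SHA-256 of the canonical (sorted-key) JSON rendering of a config."""
    blob = json.dumps(config, sort_keys=True, separators=(",", ":"), default=str)
    return hashlib.sha256(blob.encode()).hexdigest()


def write_sidecar(data_path, config: dict, **extra) -> Path:
    """Write ``<data_path>.meta.json`` next to a data file."""
    from . import __version__

    meta = {
        "tool": "fermkin",
        "version": __version__,
        "config": config,
        "config_hash": config_hash(config),
        **extra,
    }
    side = Path(str(data_path) + ".meta.json")
    side.write_text(json.dumps(meta, indent=2, sort_keys=True, default=str) + "\n")
    return side
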