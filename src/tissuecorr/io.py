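"""CSV/JSON readers and writers with a provenance header.

Every table written by the pipeline starts with a single comment line
``# tissuecorr-meta: {...json...}`` carrying the config hash and seed, so any
output can be traced to the run that produced it.  Readers skip the line
transparently.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

__all__ = [
    "config_hash",
    "write_table",
    "read_table",
    "write_tracks_csv",
    "read_tracks_csv",
]

_META_PREFIX = "# tissuecorr-meta: "


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serialisable configuration."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if meta is not None:
            fh.write(_META_PREFIX + json.dumps(meta, sort_keys=True, default=str) + "\n")
        df.to_csv(fh, index=False)


def read_table(path) -> tuple[pd.DataFrame, dict | None]:
    """Read a table written by :func:`write_table`; returns (frame, meta)."""
    meta = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith(_META_PREFIX):
            meta = json.loads(first[len(_META_PREFIX):])
        else:
            fh.seek(0)
        df = pd.read_csv(fh)
    return df, meta


def write_tracks_csv(tracks: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Write a cell-track table (cell_id, time_h, x_um, y_um, ch1, ch2)."""
    required = {"cell_id", "time_h", "x_um", "y_um", "ch1", "ch2"}
    missing = required - set(tracks.columns)
    if missing:
        raise ValueError(f"tracks table missing columns: {sorted(missing)}")
    write_table(tracks, path, meta)


def read_tracks_csv(path) -> pd.DataFrame:
    df, _ = read_table(path)
    return df
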