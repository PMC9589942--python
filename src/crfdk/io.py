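"""Plain-text input/output helpers for spike tables."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .simulate import SPIKE_TABLE_COLUMNS

__all__ = ["read_spike_table", "write_spike_table"]


def read_spike_table(path) -> pd.DataFrame:
    """Read a flat spike table (unit, direction, contrast, trial, spike time).

    CSV or JSON (records orientation), chosen by extension.  Raises a schema
    error naming any missing column.
    """
    p = Path(path)
    if p.suffix.lower() == ".json":
        df = pd.read_json(p, orient="records")
    else:
        df = pd.read_csv(p)
    missing = [c for c in SPIKE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"spike table {p} is missing columns: {missing}")
    return df


def write_spike_table(df: pd.DataFrame, path) -> None:
    p = Path(path)
    if p.suffix.lower() == ".json":
        df.to_json(p, orient="records")
    else:
        df.to_csv(p, index=False)
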