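"""Raven-style tab-separated selection tables.

A selection table is the exchange format between analyst annotation and the
measurement pipeline: one row per selection with begin/end time (s) and
low/high frequency (Hz), optionally a class label, plus any extra columns,
which are preserved verbatim on round trip.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

__all__ = ["SelectionRecord", "read_selection_table", "write_selection_table"]

_CORE_COLUMNS = {
    "Selection": "selection",
    "Begin Time (s)": "begin_s",
    "End Time (s)": "end_s",
    "Low Freq (Hz)": "low_hz",
    "High Freq (Hz)": "high_hz",
    "Class": "label",
}


@dataclass
class SelectionRecord:
    """One time-frequency annotation; intervals are half-open [begin, end)."""

    begin_s: float
    end_s: float
    low_hz: float
    high_hz: float
    label: str | None = None
    selection: int | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.begin_s < self.end_s:
            raise ValueError("begin_s must be before end_s")
        if not self.low_hz < self.high_hz:
            raise ValueError("low_hz must be below high_hz")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.begin_s


def read_selection_table(path: str | Path) -> list[SelectionRecord]:
    """Parse a Raven-style TSV into selection records (CRLF tolerated)."""
    df = pd.read_csv(path, sep="\t")
    required = ["Begin Time (s)", "End Time (s)", "Low Freq (Hz)", "High Freq (Hz)"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"selection table {path} is missing columns: {missing}")
    for c in required:
        if not pd.api.types.is_numeric_dtype(df[c]):
            raise ValueError(f"non-numeric values in column {c!r} of {path}")
    records = []
    extra_cols = [c for c in df.columns if c not in _CORE_COLUMNS]
    for _, row in df.iterrows():
        records.append(
            SelectionRecord(
                begin_s=float(row["Begin Time (s)"]),
                end_s=float(row["End Time (s)"]),
                low_hz=float(row["Low Freq (Hz)"]),
                high_hz=float(row["High Freq (Hz)"]),
                label=str(row["Class"]) if "Class" in df.columns and pd.notna(row["Class"]) else None,
                selection=int(row["Selection"]) if "Selection" in df.columns else None,
                extras={c: row[c] for c in extra_cols},
            )
        )
    return records


def write_selection_table(records: Sequence[SelectionRecord], path: str | Path) -> None:
    """Write records as a Raven-style TSV (full float precision, lossless)."""
    rows = []
    for i, r in enumerate(records, start=1):
        row = {
            "Selection": r.selection if r.selection is not None else i,
            "Begin Time (s)": repr(float(r.begin_s)),
            "End Time (s)": repr(float(r.end_s)),
            "Low Freq (Hz)": repr(float(r.low_hz)),
            "High Freq (Hz)": repr(float(r.high_hz)),
        }
        if r.label is not None:
            row["Class"] = r.label
        row.update(r.extras)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
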