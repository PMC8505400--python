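"""Readers and writers for the wide sample table and tidy result tables.

The on-disk sample format is a wide UTF-8 CSV: ``site_id, phase`` then one
column per parameter code, one row per site × phase.  Empty cells are
declared-absent values (never zero-filled); unknown columns are warnings,
not errors.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import FormatError
from .registry import SampleRecord, StandardsTable, validate_samples

logger = logging.getLogger("riverwq")

__all__ = ["read_samples", "write_samples", "samples_to_frame"]


def samples_to_frame(records: Sequence[SampleRecord]) -> pd.DataFrame:
    """Wide DataFrame (site_id, phase, one column per code) from records."""
    codes: list[str] = []
    for rec in records:
        for code in rec.values:
            if code not in codes:
                codes.append(code)
    rows = [
        {"site_id": r.site_id, "phase": r.phase, **{c: r.values.get(c) for c in codes}}
        for r in records
    ]
    return pd.DataFrame(rows, columns=["site_id", "phase", *codes])


def write_samples(records: Sequence[SampleRecord], path: str | Path) -> None:
    samples_to_frame(records).to_csv(path, index=False)


def read_samples(path: str | Path, standards: StandardsTable) -> list[SampleRecord]:
    """Parse and validate a wide sample CSV.

    Raises :class:`FormatError` for duplicate (site, phase) pairs or
    unparseable numbers (reported with row and column).
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str)
    for required in ("site_id", "phase"):
        if required not in frame.columns:
            raise FormatError(f"{path}: missing required column {required!r}")
    dupes = frame.duplicated(subset=["site_id", "phase"])
    if dupes.any():
        first = frame.loc[dupes, ["site_id", "phase"]].iloc[0]
        raise FormatError(
            f"{path}: duplicate (site_id, phase) pair ({first.site_id}, {first.phase})"
        )
    codes = [c for c in frame.columns if c not in ("site_id", "phase")]
    for code in codes:
        if code not in standards.parameters:
            logger.warning("%s: unknown parameter column %r (kept as-is)", path, code)
    records = []
    for row_idx, row in frame.iterrows():
        values = {}
        for code in codes:
            cell = row[code]
            if cell is None or (isinstance(cell, float) and pd.isna(cell)) or str(cell).strip() == "":
                continue  # declared absent
            try:
                values[code] = float(cell)
            except ValueError:
                raise FormatError(
                    f"{path}: unparseable number {cell!r} at row {row_idx + 2}, "
                    f"column {code!r}"
                ) from None
        records.append(
            SampleRecord(site_id=str(row.site_id), phase=str(row.phase), values=values)
        )
    return validate_samples(records, standards)
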