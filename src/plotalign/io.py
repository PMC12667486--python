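"""Readers and writers for the engine's delimited-text formats.

Matrices are CSV/TSV with row ids in the first column and column ids in the
header; empty cells or "NA" are missing values (kept as NaN, never silently
zeroed). Alteration tables are a minimal MAF-like TSV subset with columns
sample, gene, alteration. Grouping tables are two-column (id, group) with a
required header.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .plots import AlterationRecord

__all__ = [
    "LabeledMatrix",
    "read_matrix",
    "write_matrix",
    "read_alterations",
    "write_alterations",
    "read_groups",
]

_MISSING_TOKENS = {"", "NA"}


@dataclass(frozen=True)
class LabeledMatrix:
    """A numeric matrix with unique row and column identifiers."""

    values: np.ndarray
    row_ids: tuple[str, ...]
    col_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError(
                f"matrix shape {v.shape} does not match "
                f"{len(self.row_ids)} row ids x {len(self.col_ids)} column ids"
            )
        for ids, what in ((self.row_ids, "row"), (self.col_ids, "column")):
            if len(set(ids)) != len(ids):
                dup = sorted({i for i in ids if list(ids).count(i) > 1})
                raise ValueError(f"duplicate {what} ids: {dup}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.row_ids),
                            columns=list(self.col_ids))


def _sniff_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def read_matrix(path: str | Path, delimiter: str | None = None) -> LabeledMatrix:
    """Read a labeled numeric matrix; first row = column ids, first column =
    row ids. Empty cells and "NA" become NaN. Ragged rows raise with their
    line number."""
    path = Path(path)
    delim = _sniff_delimiter(path, delimiter)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter=delim))
    if not rows:
        raise ValueError(f"{path}: empty file")
    header = rows[0]
    ncol = len(header) - 1
    if ncol < 1:
        raise ValueError(f"{path}: header must hold at least one column id")
    col_ids = tuple(h.strip() for h in header[1:])
    row_ids: list[str] = []
    body: list[list[float]] = []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != ncol + 1:
            raise ValueError(
                f"{path}: ragged row at line {lineno}: expected {ncol + 1} "
                f"fields, got {len(row)}"
            )
        row_ids.append(row[0].strip())
        vals = []
        for cell in row[1:]:
            cell = cell.strip()
            if cell in _MISSING_TOKENS:
                vals.append(np.nan)
            else:
                try:
                    vals.append(float(cell))
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric value {cell!r} at line {lineno}"
                    ) from None
        body.append(vals)
    return LabeledMatrix(np.asarray(body, dtype=float), tuple(row_ids), col_ids)


def write_matrix(m: LabeledMatrix, path: str | Path,
                 delimiter: str | None = None) -> None:
    """Write a labeled matrix; missing values become empty cells."""
    path = Path(path)
    delim = _sniff_delimiter(path, delimiter)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=delim, lineterminator="\n")
        w.writerow(["id", *m.col_ids])
        for i, rid in enumerate(m.row_ids):
            w.writerow([rid] + ["" if np.isnan(v) else f"{v:.12g}"
                                for v in m.values[i]])


def read_alterations(path: str | Path) -> list[AlterationRecord]:
    """Read an alteration table (TSV with sample/gene/alteration columns).

    Duplicate (sample, gene, alteration) rows collapse to one with a warning;
    unknown extra columns are ignored with a warning."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    required = ("sample", "gene", "alteration")
    missing = [c for c in required if c not in cols]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}; "
                         f"found {list(df.columns)}")
    extra = [c for c in df.columns if c.lower() not in required]
    if extra:
        warnings.warn(f"{path}: ignoring extra columns {extra}", stacklevel=2)
    seen: set[tuple[str, str, str]] = set()
    out: list[AlterationRecord] = []
    dups = 0
    for _, row in df.iterrows():
        key = (row[cols["sample"]], row[cols["gene"]], row[cols["alteration"]])
        if key in seen:
            dups += 1
            continue
        seen.add(key)
        out.append(AlterationRecord(sample=key[0], gene=key[1], type=key[2]))
    if dups:
        warnings.warn(f"{path}: collapsed {dups} duplicate alteration row(s)",
                      stacklevel=2)
    return out


def write_alterations(records: Sequence[AlterationRecord],
                      path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sample", "gene", "alteration"])
        for r in records:
            w.writerow([r.sample, r.gene, r.type])


def read_groups(path: str | Path, delimiter: str | None = None) -> dict[str, str]:
    """Read a two-column (id, group) table with a required header."""
    path = Path(path)
    delim = _sniff_delimiter(path, delimiter)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter=delim))
    if len(rows) < 1 or len(rows[0]) < 2:
        raise ValueError(f"{path}: expected a two-column table with a header")
    out: dict[str, str] = {}
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) < 2:
            raise ValueError(f"{path}: ragged row at line {lineno}")
        key = row[0].strip()
        if key in out:
            raise ValueError(f"{path}: duplicate id {key!r} at line {lineno}")
        out[key] = row[1].strip()
    return out
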