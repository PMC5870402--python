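"""Delimited-matrix readers/writers, flat config files and run manifests."""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["MatrixData", "read_matrix", "write_matrix", "read_config", "write_manifest"]


@dataclass(frozen=True)
class MatrixData:
    """A numeric matrix plus optional row/column identifiers."""

    values: np.ndarray
    row_ids: list[str] | None = None
    col_ids: list[str] | None = None


def _detect_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def _is_number(cell: str) -> bool:
    cell = cell.strip()
    if cell == "" or cell.upper() in ("NA", "NAN"):
        return False
    try:
        float(cell)
    except ValueError:
        return False
    return True


def read_matrix(
    path: str | Path,
    delimiter: str | None = None,
    header: bool | None = None,
    row_ids: bool | None = None,
) -> MatrixData:
    """Read a delimited numeric matrix.

    ``header`` marks a leading row of variable identifiers; ``row_ids`` a
    leading column of observation identifiers; either may be ``None`` to
    auto-detect (non-numeric first row/column).  Ragged rows, non-numeric
    cells and missing values raise with the offending line number (missing
    values are not supported; filter or impute upstream).
    """
    path = Path(path)
    sep = _detect_delimiter(path, delimiter)
    with path.open(newline="") as fh:
        rows = list(csv.reader(fh, delimiter=sep))
    rows = [r for r in rows if r]  # ignore blank lines
    if not rows:
        raise ValueError(f"{path}: empty file")
    width = len(rows[0])
    for lineno, row in enumerate(rows, start=1):
        if len(row) != width:
            raise ValueError(
                f"{path}: ragged row at line {lineno} "
                f"({len(row)} fields, expected {width})"
            )
    if header is None:
        header = not all(_is_number(c) for c in rows[0][1:])
    if row_ids is None:
        body = rows[1:] if header else rows
        row_ids = bool(body) and not any(_is_number(r[0]) for r in body)
    col_names = None
    start = 0
    if header:
        col_names = rows[0][1:] if row_ids else rows[0]
        start = 1
    ids: list[str] | None = [] if row_ids else None
    data = []
    for lineno, row in enumerate(rows[start:], start=start + 1):
        cells = row
        if row_ids:
            ids.append(cells[0])
            cells = cells[1:]
        parsed = []
        for k, cell in enumerate(cells):
            cell = cell.strip()
            if cell == "" or cell.upper() in ("NA", "NAN"):
                raise ValueError(f"{path}: missing value at line {lineno}, field {k + 1}")
            try:
                parsed.append(float(cell))
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell {cell!r} at line {lineno}, field {k + 1}"
                ) from None
        data.append(parsed)
    if not data:
        raise ValueError(f"{path}: no data rows")
    return MatrixData(values=np.asarray(data), row_ids=ids, col_ids=col_names)


def write_matrix(
    path: str | Path,
    values: np.ndarray,
    row_ids: list[str] | None = None,
    col_ids: list[str] | None = None,
    delimiter: str | None = None,
) -> None:
    """Write a matrix at full precision (round-trips bit-identically)."""
    path = Path(path)
    sep = _detect_delimiter(path, delimiter)
    values = np.atleast_2d(np.asarray(values, dtype=float))
    df = pd.DataFrame(values, index=row_ids, columns=col_ids)
    df.to_csv(
        path,
        sep=sep,
        index=row_ids is not None,
        header=col_ids is not None,
        float_format="%.17g",
    )


def read_config(path: str | Path) -> dict[str, str]:
    """Parse a flat ``key = value`` config file (# starts a comment)."""
    out: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}: line {lineno} is not 'key = value'")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip().strip('"').strip("'")
    return out


def write_manifest(out_dir: str | Path, settings: dict) -> Path:
    """Record every setting of a run (the reproducibility contract).

    Deliberately contains no timestamp: identical configurations must produce
    bit-identical artifacts.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = dict(settings)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
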