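"""Reading and validating localization tables.

The on-disk interchange format is a text table with columns
``X (nm), Y (nm), STDEV (nm)`` (comma- or tab-separated), optionally
followed by a frame column.  In memory a table is a
:class:`pandas.DataFrame` with columns ``x_nm``, ``y_nm``, ``sd_nm`` and
optionally ``frame``, ``molecule_id``, ``true_label``.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .types import FormatError, ValidationError

#: canonical column order for in-memory tables
CORE_COLUMNS = ("x_nm", "y_nm", "sd_nm")
OPTIONAL_COLUMNS = ("frame", "molecule_id", "true_label")

# header aliases, matched case-insensitively after stripping whitespace
_ALIASES = {
    "x_nm": {"x (nm)", "x_nm", "x"},
    "y_nm": {"y (nm)", "y_nm", "y"},
    "sd_nm": {"stdev (nm)", "stdev", "sd_nm", "sd (nm)", "precision (nm)"},
    "frame": {"frame", "frames"},
    "molecule_id": {"molecule_id", "molecule"},
    "true_label": {"true_label", "label"},
}


def make_table(
    x_nm: np.ndarray,
    y_nm: np.ndarray,
    sd_nm: np.ndarray,
    frame: np.ndarray | None = None,
    molecule_id: np.ndarray | None = None,
    true_label: np.ndarray | None = None,
) -> pd.DataFrame:
    """Assemble and validate a localization table from arrays."""
    data: dict[str, np.ndarray] = {
        "x_nm": np.asarray(x_nm, dtype=np.float64),
        "y_nm": np.asarray(y_nm, dtype=np.float64),
        "sd_nm": np.asarray(sd_nm, dtype=np.float64),
    }
    if frame is not None:
        data["frame"] = np.asarray(frame, dtype=np.int64)
    if molecule_id is not None:
        data["molecule_id"] = np.asarray(molecule_id, dtype=np.int64)
    if true_label is not None:
        data["true_label"] = np.asarray(true_label, dtype=np.int64)
    table = pd.DataFrame(data)
    validate_table(table)
    return table


def validate_table(table: pd.DataFrame) -> None:
    """Check table invariants; raise :class:`ValidationError` on violation."""
    for col in CORE_COLUMNS:
        if col not in table.columns:
            raise FormatError(f"missing required column {col!r}")
    if len(table):
        for col in ("x_nm", "y_nm"):
            if not np.all(np.isfinite(table[col].to_numpy())):
                raise ValidationError(f"non-finite values in {col}")
        sd = table["sd_nm"].to_numpy()
        bad = np.flatnonzero(~(sd > 0) | ~np.isfinite(sd))
        if bad.size:
            raise ValidationError(
                f"non-positive localization precision in row {int(bad[0])} "
                f"(sd_nm = {sd[bad[0]]!r})"
            )
        if "frame" in table.columns:
            fr = table["frame"].to_numpy()
            if np.any(fr < 0):
                raise ValidationError("negative frame index")


def _resolve_columns(header: list[str]) -> dict[str, str] | None:
    """Map raw header names to canonical names; None if not a header row."""
    lowered = [h.strip().lower() for h in header]
    mapping: dict[str, str] = {}
    for canon, aliases in _ALIASES.items():
        for raw, low in zip(header, lowered):
            if low in aliases:
                mapping[raw] = canon
                break
    if all(c in mapping.values() for c in CORE_COLUMNS):
        return mapping
    return None


def _sniff_delimiter(path: Path, dialect: str) -> str:
    if dialect == "csv":
        return ","
    if dialect == "tsv":
        return "\t"
    sample = path.read_text().splitlines()[:5]
    text = "\n".join(sample)
    try:
        return csv.Sniffer().sniff(text, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


def read_localizations(path: str | Path, dialect: str = "auto") -> pd.DataFrame:
    """Read a localization table from a text/CSV file.

    Columns are resolved by header name (``X (nm)`` / ``Y (nm)`` /
    ``STDEV (nm)``, case-insensitive, plus an optional ``frame``); a file
    without a recognizable header is read positionally as x, y, sd
    (, frame).  All coordinates are taken to be in nm.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect not in ("csv", "tsv", "auto"):
        raise ValueError(f"unknown dialect {dialect!r}")
    sep = _sniff_delimiter(path, dialect)

    first = pd.read_csv(path, sep=sep, header=None, nrows=1)
    if first.empty:
        raise FormatError(f"{path}: empty file")
    header = [str(v) for v in first.iloc[0]]
    mapping = _resolve_columns(header)
    if mapping is not None:
        raw = pd.read_csv(path, sep=sep)
        raw = raw.rename(columns={c: mapping.get(str(c).strip(), c) for c in raw.columns})
    else:
        # no recognizable header: positional x, y, sd (, frame)
        if any(_is_non_numeric(v) for v in header):
            raise FormatError(
                f"{path}: header does not name X (nm)/Y (nm)/STDEV (nm) and "
                "first row is not numeric"
            )
        raw = pd.read_csv(path, sep=sep, header=None)
        if raw.shape[1] < 3:
            raise FormatError(f"{path}: expected at least 3 columns, got {raw.shape[1]}")
        names = ["x_nm", "y_nm", "sd_nm"]
        if raw.shape[1] >= 4:
            names.append("frame")
        raw = raw.iloc[:, : len(names)]
        raw.columns = names

    cols = [c for c in CORE_COLUMNS + OPTIONAL_COLUMNS if c in raw.columns]
    table = raw[cols].reset_index(drop=True)
    for col in CORE_COLUMNS:
        table[col] = table[col].astype(np.float64)
    for col in ("frame", "molecule_id", "true_label"):
        if col in table.columns:
            table[col] = table[col].astype(np.int64)
    validate_table(table)
    return table


def _is_non_numeric(value: str) -> bool:
    try:
        float(value)
        return False
    except (TypeError, ValueError):
        return True


def write_localizations(table: pd.DataFrame, path: str | Path, dialect: str = "csv") -> None:
    """Write a table using the interchange header names."""
    validate_table(table)
    sep = "\t" if dialect == "tsv" else ","
    out = table.rename(
        columns={"x_nm": "X (nm)", "y_nm": "Y (nm)", "sd_nm": "STDEV (nm)"}
    )
    out.to_csv(path, sep=sep, index=False)
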