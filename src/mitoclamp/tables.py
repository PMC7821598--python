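"""Strict CSV readers/writers for the pipeline's tabular interchange.

Schema validation is deliberately unforgiving: missing columns are named,
malformed numeric cells are reported with their line number, and
comma-decimal locales are rejected outright rather than silently
misparsed.  Write -> read round-trips are lossless (floats serialized via
``repr``).
"""

from __future__ import annotations

import csv
from pathlib import Path

import pandas as pd

from .errors import ParseError

COHORT_REQUIRED = ["animal", "sex", "group"]
FORCE_FLOW_COLUMNS = ["sample_id", "substrate", "step", "dG_ATP", "jo2"]
CLEARANCE_COLUMNS = ["animal_id", "time_min", "fluorescence"]


def _check_numeric(value: str, column: str, line: int) -> float:
    if "," in value:
        raise ParseError(
            f"line {line}, column {column!r}: {value!r} contains a comma — "
            "comma decimal separators are not accepted; use '.'"
        )
    try:
        return float(value)
    except ValueError as exc:
        raise ParseError(
            f"line {line}, column {column!r}: {value!r} is not a number"
        ) from exc


def read_table(
    path: str | Path,
    required: list[str],
    numeric: list[str] | None = None,
) -> pd.DataFrame:
    """Read a CSV with required-column and numeric-cell validation."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ParseError(f"{path}: empty file")
        missing = [c for c in required if c not in reader.fieldnames]
        if missing:
            raise ParseError(f"{path}: missing required column(s) {missing}")
        numeric = [c for c in (numeric or []) if c in reader.fieldnames]
        rows = []
        for i, row in enumerate(reader, start=2):  # header is line 1
            if None in row or any(v is None for v in row.values()):
                raise ParseError(f"{path}: line {i}: wrong number of fields")
            for col in numeric:
                row[col] = _check_numeric(row[col], col, i)
            rows.append(row)
    return pd.DataFrame(rows, columns=reader.fieldnames)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Lossless CSV writer: full-precision floats, no index."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=None)


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = read_table(path, required=COHORT_REQUIRED)
    phenotypes = [c for c in df.columns if c not in COHORT_REQUIRED]
    for c in phenotypes:
        df[c] = pd.to_numeric(df[c])
    return df


def read_force_flow(path: str | Path) -> pd.DataFrame:
    return read_table(
        path, required=FORCE_FLOW_COLUMNS, numeric=["step", "dG_ATP", "jo2"]
    )


def read_clearance(path: str | Path) -> pd.DataFrame:
    return read_table(
        path, required=CLEARANCE_COLUMNS, numeric=["time_min", "fluorescence"]
    )


def write_feature_table(intensities: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    intensities.to_csv(path, index_label="feature_id")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "feature_id" not in df.columns:
        raise ParseError(f"{path}: missing required column(s) ['feature_id']")
    return df.set_index("feature_id")
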