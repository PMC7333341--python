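"""CSV input/output for responses, scores, and the agreement report.

Formats
-------
* Responses CSV: ``subject_id`` followed by the ten item columns (by
  name), optional ``age`` and ``sex``; integer cells in 0..5.
* Scores CSV: ``subject_id,ndi10,ndi8,ndi5``.
* Agreement report CSV: one row per comparison with the Bland-Altman
  columns (n, df, d, CI, SD, LoA, SE) plus the Wilcoxon p, rounded to one
  decimal for report parity; p-values below 0.001 print as ``<0.001``.

Every writer prepends ``#``-comment header lines carrying the
configuration digest and transform-table provenance so an output file is
traceable to the run that produced it.
"""

from __future__ import annotations

import hashlib
import json
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .agreement import BAStats, WilcoxonResult
from .scoring import (
    CANONICAL_ITEMS,
    MAX_RESPONSE,
    ResponseRecord,
    ValidationError,
    validate_record,
)

__all__ = [
    "RESPONSES_COLUMNS",
    "REPORT_COLUMNS",
    "read_responses_csv",
    "read_responses_frame",
    "write_responses_csv",
    "read_scores_csv",
    "write_scores_csv",
    "write_table2_report",
    "read_table2_report",
    "config_digest",
]

RESPONSES_COLUMNS = ["subject_id", *CANONICAL_ITEMS]
REPORT_COLUMNS = [
    "comparison", "n", "df", "d", "ci_low", "ci_high",
    "sd", "loa_upper", "loa_lower", "se", "wilcoxon_p",
]


class FormatError(ValueError):
    """A file does not match the expected CSV dialect."""


def config_digest(config: dict) -> str:
    """Short deterministic digest of a run configuration for provenance lines."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _write_with_header(df: pd.DataFrame, path, header_lines: Sequence[str]) -> None:
    with open(path, "w", newline="") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def read_responses_frame(path) -> pd.DataFrame:
    """Read a responses CSV into a validated DataFrame (file order kept)."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in RESPONSES_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: malformed header, missing column(s) {missing}; "
            f"expected {','.join(RESPONSES_COLUMNS)}[,age,sex]"
        )
    for col in CANONICAL_ITEMS:
        vals = df[col]
        numeric = pd.to_numeric(vals, errors="coerce")
        bad = numeric.isna() | (numeric != numeric.round())
        if bad.any():
            row = int(np.argmax(bad.to_numpy()))
            raise FormatError(
                f"{path}: row {row + 2}, column {col!r}: "
                f"non-integer cell {vals.iloc[row]!r}"
            )
        out_of_range = (numeric < 0) | (numeric > MAX_RESPONSE)
        if out_of_range.any():
            row = int(np.argmax(out_of_range.to_numpy()))
            raise ValidationError(
                f"{path}: row {row + 2}, column {col!r}: "
                f"response {vals.iloc[row]!r} outside 0..{MAX_RESPONSE}"
            )
        df[col] = numeric.astype(int)
    df["subject_id"] = df["subject_id"].astype(str)
    return df


def read_responses_csv(path) -> list[ResponseRecord]:
    """Read and validate a responses CSV into :class:`ResponseRecord` objects."""
    df = read_responses_frame(path)
    records = []
    for row in df.itertuples(index=False):
        rec = ResponseRecord(
            subject_id=row.subject_id,
            responses=tuple(int(getattr(row, it)) for it in CANONICAL_ITEMS),
            age=float(row.age) if "age" in df.columns and pd.notna(row.age) else None,
            sex=str(row.sex) if "sex" in df.columns and pd.notna(row.sex) else None,
        )
        records.append(validate_record(rec))
    return records


def write_responses_csv(df: pd.DataFrame, path,
                        header_lines: Sequence[str] = ()) -> None:
    """Write a responses DataFrame in the standard dialect."""
    cols = RESPONSES_COLUMNS + [c for c in ("age", "sex") if c in df.columns]
    _write_with_header(df[cols], path, header_lines)


def write_scores_csv(scores: pd.DataFrame, path,
                     header_lines: Sequence[str] = ()) -> None:
    _write_with_header(scores[["subject_id", "ndi10", "ndi8", "ndi5"]],
                       path, header_lines)


def read_scores_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in ("subject_id", "ndi10", "ndi8", "ndi5")
               if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: scores file missing column(s) {missing}")
    return df


def _fmt_p(p: float, threshold: float = 0.001) -> str:
    if np.isnan(p):
        return "NA"
    return f"<{threshold}" if p < threshold else f"{p:.3f}"


def write_table2_report(results: Iterable[tuple[BAStats, WilcoxonResult]], path,
                        digits: int = 1,
                        header_lines: Sequence[str] = ()) -> pd.DataFrame:
    """Write the agreement report CSV (one row per comparison).

    Numeric columns are rounded to ``digits`` decimals for report parity;
    p-values below 0.001 are printed as ``<0.001``.  Returns the frame as
    written.
    """
    rows = []
    for ba, wil in results:
        rows.append({
            "comparison": ba.comparison,
            "n": ba.n,
            "df": ba.df,
            "d": round(ba.d, digits),
            "ci_low": round(ba.ci_low, digits),
            "ci_high": round(ba.ci_high, digits),
            "sd": round(ba.sd, digits),
            "loa_upper": round(ba.loa_upper, digits),
            "loa_lower": round(ba.loa_lower, digits),
            "se": round(ba.se, digits),
            "wilcoxon_p": _fmt_p(wil.p_value),
        })
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    _write_with_header(df, path, header_lines)
    return df


def read_table2_report(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in REPORT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: report missing column(s) {missing}")
    return df
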