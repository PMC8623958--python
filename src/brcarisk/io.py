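"""Cohort CSV round-tripping and result files.

The cohort dialect is one row per patient with the 16 factor columns
(``classification`` being the variant class in its input role) plus a
``class_label`` column (the same class in its supervision role) — 17
fixed columns.  An optional leading ``subject_id`` column and optional
``reported_*_score`` columns (used by the packaged fixture) are
accepted.  The literal string ``"Unknown"`` (case-insensitive, also
``""`` or ``NA``) marks a missing value.  Parse errors name the row and
column of the offending cell.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Optional, Sequence, Union

from .datamodel import (
    FACTOR_NAMES,
    FactorValueError,
    PatientRecord,
    build_catalogue,
    encode_record,
)

__all__ = ["read_cohort_csv", "write_cohort_csv", "write_results_csv",
           "COHORT_COLUMNS"]

#: The fixed 17-column dialect.
COHORT_COLUMNS: tuple[str, ...] = FACTOR_NAMES + ("class_label",)

_OPTIONAL_COLUMNS = ("subject_id", "reported_fuzzy_score",
                     "reported_network_score")
_NUMERIC_FACTORS = ("age", "n_affected_family", "tumour_size_cm")
_MISSING_TOKENS = {"", "unknown", "na", "n/a", "nan", "none", "missing"}


class CohortParseError(ValueError):
    """A malformed cohort CSV cell, named by row and column."""


def _parse_cell(raw: str, column: str, row: int) -> Union[str, float, None]:
    text = raw.strip()
    if text.lower() in _MISSING_TOKENS:
        return None
    if column in _NUMERIC_FACTORS:
        try:
            return float(text)
        except ValueError:
            raise CohortParseError(
                f"row {row}, column {column!r}: {raw!r} is not a number"
            ) from None
    return text


def read_cohort_csv(
    path: Union[str, Path], return_extras: bool = False
) -> Union[list[PatientRecord], tuple[list[PatientRecord], list[dict]]]:
    """Read a cohort CSV into patient records.

    Every record is validated against the factor catalogue on read, so
    unknown category labels fail here with the row and factor named.
    """
    catalogue = build_catalogue()
    path = Path(path)
    with path.open(newline="") as handle:
        reader = csv.DictReader(handle)
        header = reader.fieldnames or []
        unknown = [c for c in header
                   if c not in COHORT_COLUMNS and c not in _OPTIONAL_COLUMNS]
        if unknown:
            raise CohortParseError(f"{path.name}: unknown columns {unknown}")
        missing_cols = [c for c in COHORT_COLUMNS if c not in header]
        if missing_cols:
            raise CohortParseError(
                f"{path.name}: missing required columns {missing_cols}"
            )
        records: list[PatientRecord] = []
        extras: list[dict] = []
        for row_no, row in enumerate(reader, start=2):
            values = {
                name: _parse_cell(row[name] or "", name, row_no)
                for name in FACTOR_NAMES
            }
            class_label = _parse_cell(row["class_label"] or "",
                                      "class_label", row_no)
            record = PatientRecord(
                values=values,
                class_label=class_label,
                record_id=(row.get("subject_id") or "").strip() or None,
            )
            try:
                encode_record(record, catalogue)
            except FactorValueError as err:
                raise CohortParseError(f"row {row_no}: {err}") from None
            records.append(record)
            extras.append(
                {
                    key: _parse_float_or_none(row.get(key))
                    for key in ("reported_fuzzy_score",
                                "reported_network_score")
                    if key in header
                }
            )
    if return_extras:
        return records, extras
    return records


def _parse_float_or_none(raw: Optional[str]) -> Optional[float]:
    if raw is None or raw.strip().lower() in _MISSING_TOKENS:
        return None
    return float(raw)


def _format_cell(value: Union[str, float, None]) -> str:
    if value is None:
        return "Unknown"
    if isinstance(value, float) and value == int(value):
        return str(int(value))
    return str(value)


def write_cohort_csv(
    path: Union[str, Path], cohort: Sequence[PatientRecord]
) -> None:
    """Write patient records in the cohort dialect (lossless round-trip
    including missing markers)."""
    with Path(path).open("w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(("subject_id",) + COHORT_COLUMNS)
        for i, rec in enumerate(cohort, start=1):
            row = [rec.record_id or f"row-{i}"]
            row.extend(_format_cell(rec.values.get(n)) for n in FACTOR_NAMES)
            row.append(_format_cell(rec.class_label))
            writer.writerow(row)


def write_results_csv(path: Union[str, Path], results: Sequence) -> None:
    """Write subject results (scores and classes for both engines)."""
    fields = (
        "subject_id", "expected_class",
        "fuzzy_score", "fuzzy_class",
        "network_score", "network_class",
        "reported_fuzzy_score", "reported_network_score",
        "fuzzy_error",
    )
    with Path(path).open("w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(fields)
        for res in results:
            writer.writerow(
                ["" if getattr(res, f, None) is None else getattr(res, f)
                 for f in fields]
            )
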