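"""Readers and writers for injection tables, sample metadata, and reports.

Injection tables are delimited text (comma-separated; tabs accepted on read)
with a required header row naming the fields of
:class:`~mrmval.records.InjectionRecord`. Row provenance (1-based line number)
is kept on each record so validation errors can point at the offending line.
"""

from __future__ import annotations

import csv
import math
from typing import Dict, Iterable, List, Optional, Sequence

import pandas as pd

from .records import InjectionRecord, RecordValidationError, Role
from .rounding import round_half_up, round_sigfig

_MANDATORY = ("sample_id", "role", "analyte", "area", "run_id")
_OPTIONAL = ("nominal_conc", "dilution_factor", "urine_lot", "timepoint")


class FormatError(ValueError):
    """Malformed injection table (missing columns, unparsable header)."""


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line and "," not in header_line else ","


def _parse_optional_float(value: str) -> Optional[float]:
    if value is None or value.strip() == "":
        return None
    return float(value)


def read_injection_table(path) -> List[InjectionRecord]:
    """Parse a delimited injection table into records.

    Raises :class:`FormatError` when a mandatory column is absent and
    :class:`~mrmval.records.RecordValidationError` (with the line number)
    when a row violates a record invariant.
    """
    with open(path, "r", newline="") as fh:
        first = fh.readline()
        if not first.strip():
            raise FormatError(f"{path}: empty file, expected a header row")
        delim = _sniff_delimiter(first)
        fh.seek(0)
        reader = csv.DictReader(fh, delimiter=delim)
        missing = [c for c in _MANDATORY if c not in (reader.fieldnames or [])]
        if missing:
            raise FormatError(
                f"{path}: missing mandatory column(s): {', '.join(missing)}"
            )
        records: List[InjectionRecord] = []
        for lineno, row in enumerate(reader, start=2):
            try:
                role = Role(row["role"].strip())
            except ValueError as exc:
                raise RecordValidationError(
                    f"{path}:{lineno}: unknown role {row['role']!r}"
                ) from exc
            try:
                dilution = _parse_optional_float(row.get("dilution_factor", ""))
                rec = InjectionRecord(
                    sample_id=row["sample_id"].strip(),
                    role=role,
                    analyte=row["analyte"].strip(),
                    area=float(row["area"]),
                    run_id=row["run_id"].strip(),
                    nominal_conc=_parse_optional_float(row.get("nominal_conc", "")),
                    dilution_factor=1.0 if dilution is None else dilution,
                    urine_lot=(row.get("urine_lot") or "").strip() or None,
                    timepoint=(row.get("timepoint") or "").strip() or None,
                    source_line=lineno,
                )
            except RecordValidationError as exc:
                raise RecordValidationError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    return records


def records_to_frame(records: Iterable[InjectionRecord]) -> pd.DataFrame:
    rows = [
        {
            "sample_id": r.sample_id,
            "role": r.role.value,
            "analyte": r.analyte,
            "area": r.area,
            "run_id": r.run_id,
            "nominal_conc": r.nominal_conc,
            "dilution_factor": r.dilution_factor,
            "urine_lot": r.urine_lot,
            "timepoint": r.timepoint,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=_MANDATORY + _OPTIONAL)


def write_injection_table(records: Sequence[InjectionRecord], path) -> None:
    frame = records_to_frame(records)
    # full float precision so round-trips preserve areas bit-for-bit
    frame.to_csv(path, index=False, float_format="%.17g")


def read_sample_sg(path) -> Dict[str, float]:
    """Read a (sample_id, sg) metadata table."""
    frame = pd.read_csv(path)
    for col in ("sample_id", "sg"):
        if col not in frame.columns:
            raise FormatError(f"{path}: missing mandatory column(s): {col}")
    return dict(zip(frame["sample_id"].astype(str), frame["sg"].astype(float)))


def write_sample_sg(sg_by_sample: Dict[str, float], path) -> None:
    pd.DataFrame(
        {"sample_id": list(sg_by_sample), "sg": list(sg_by_sample.values())}
    ).to_csv(path, index=False, float_format="%.17g")


def _render(value, kind: str):
    """Apply the reporting-rounding convention for a column kind."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ""
    if isinstance(value, str):
        return value
    if kind == "integer":
        return int(round_half_up(value))
    if kind == "sig3":
        return round_sigfig(value, 3)
    return value


def write_report(results, path, rounding: Optional[Dict[str, str]] = None) -> None:
    """Write a result table as CSV with reporting rounding.

    ``results`` may be a DataFrame or a sequence of result objects exposing
    ``to_row()`` (the reporting dataclasses of the downstream modules do).
    ``rounding`` maps column name to ``"integer"`` (half-up to whole numbers,
    the validation-table convention) or ``"sig3"`` (three significant figures,
    the study-concentration convention).
    """
    if isinstance(results, pd.DataFrame):
        frame = results.copy()
    else:
        rows = []
        for item in results:
            if hasattr(item, "to_row"):
                rows.append(item.to_row())
            elif isinstance(item, dict):
                rows.append(item)
            else:
                raise TypeError(f"cannot render result of type {type(item)!r}")
        frame = pd.DataFrame(rows)
    if rounding:
        for col, kind in rounding.items():
            if col in frame.columns:
                frame[col] = [_render(v, kind) for v in frame[col]]
    frame.to_csv(path, index=False)
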