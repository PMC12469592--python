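"""Pair analyte rows with their internal-standard rows into response ratios.

MRM exports carry one transition per row, so an injection of one physical
sample yields an analyte row and an IS row sharing ``sample_id`` and
``run_id``. Quantitation operates on the ratio of the two areas.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Tuple

from .records import InjectionRecord, Role


class PairingError(ValueError):
    """An analyte row has no matching internal-standard row (or its IS area
    is zero)."""


def response_ratios(
    records: Iterable[InjectionRecord],
    analyte: str,
    internal_standard: str,
    roles: Optional[Iterable[Role]] = None,
) -> List[Tuple[InjectionRecord, float]]:
    """Return ``(analyte_record, analyte_area / is_area)`` pairs keyed by
    (sample_id, run_id). With ``roles`` given, only analyte rows with one of
    those roles are paired (rows of other roles — e.g. IS-free blanks — are
    ignored rather than raising)."""
    wanted = None if roles is None else set(roles)
    is_area: Dict[Tuple[str, str], float] = {}
    analyte_rows: List[InjectionRecord] = []
    for r in records:
        if r.analyte == internal_standard:
            is_area[(r.sample_id, r.run_id)] = r.area
        elif r.analyte == analyte:
            if wanted is None or r.role in wanted:
                analyte_rows.append(r)
    out: List[Tuple[InjectionRecord, float]] = []
    for r in analyte_rows:
        key = (r.sample_id, r.run_id)
        if key not in is_area:
            raise PairingError(
                f"no internal-standard ({internal_standard!r}) row for sample "
                f"{r.sample_id!r} in run {r.run_id!r}"
            )
        denom = is_area[key]
        if denom <= 0:
            raise PairingError(
                f"internal-standard area is not positive for sample "
                f"{r.sample_id!r} in run {r.run_id!r}"
            )
        out.append((r, r.area / denom))
    return out
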