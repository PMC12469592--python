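"""Matrix-effect quantification and internal-standard selection.

The matrix factor (MF) of an analyte in a urine lot is the ratio (x100) of
its mean peak area in post-extraction-spiked matrix to its mean area in pure
solvent: 100 means no effect, below 100 ion suppression, above 100
enhancement. The IS-corrected matrix factor divides the analyte MF by the MF
of its internal standard (x100); the coefficient of variation (CV) of the
corrected factor across lots measures the relative matrix effect, and the
candidate internal standard with the lowest such CV is assigned to the
analyte. A CV of at most 15 % is the customary acceptance bound.

Mean matrix factors are classified into suppression/enhancement bands:
soft [80, 120], medium suppression [50, 80), medium enhancement (120, 150],
strong elsewhere. The half-open boundary closures make the bands tile the
positive axis without gaps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from ._log import log_decision
from .records import InjectionRecord, Role


class InsufficientDataError(ValueError):
    pass


class SuppressionClass(str, Enum):
    SOFT = "soft"
    MEDIUM_SUPPRESSION = "medium_suppression"
    MEDIUM_ENHANCEMENT = "medium_enhancement"
    STRONG = "strong"


@dataclass
class MatrixFactorSet:
    analyte: str
    per_lot: Dict[str, float]  # lot -> matrix factor %
    mean_mf: float
    internal_standard: Optional[str] = None
    per_lot_corrected: Dict[str, float] = field(default_factory=dict)
    mean_corrected: Optional[float] = None
    cv_corrected: Optional[float] = None

    def to_row(self) -> dict:
        row = {"analyte": self.analyte}
        for lot in sorted(self.per_lot):
            row[f"mf_{lot}"] = self.per_lot[lot]
        row["mean_mf"] = self.mean_mf
        row["internal_standard"] = self.internal_standard
        for lot in sorted(self.per_lot_corrected):
            row[f"corrected_{lot}"] = self.per_lot_corrected[lot]
        row["mean_corrected"] = self.mean_corrected
        row["cv_corrected"] = self.cv_corrected
        return row


def matrix_factor(area_in_matrix: float, area_in_solvent: float) -> float:
    """100 x (mean area in post-extraction-spiked matrix / mean area in
    solvent)."""
    if area_in_solvent <= 0:
        raise ZeroDivisionError("solvent area must be positive")
    return 100.0 * area_in_matrix / area_in_solvent


def is_corrected_matrix_factor(analyte_mf: float, is_mf: float) -> float:
    """100 x analyte MF / internal-standard MF."""
    if is_mf == 0:
        raise ZeroDivisionError("internal-standard matrix factor is zero")
    return 100.0 * analyte_mf / is_mf


def cv_percent(values: Sequence[float]) -> float:
    """Coefficient of variation in % using the sample (n-1) standard
    deviation."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise InsufficientDataError("CV needs at least two values")
    mean = arr.mean()
    if mean == 0:
        raise ZeroDivisionError("CV undefined for zero mean")
    return float(100.0 * arr.std(ddof=1) / mean)


def classify_matrix_effect(mean_mf: float) -> SuppressionClass:
    if mean_mf <= 0 or not math.isfinite(mean_mf):
        raise ValueError("mean matrix factor must be positive and finite")
    if 80.0 <= mean_mf <= 120.0:
        return SuppressionClass.SOFT
    if 50.0 <= mean_mf < 80.0:
        return SuppressionClass.MEDIUM_SUPPRESSION
    if 120.0 < mean_mf <= 150.0:
        return SuppressionClass.MEDIUM_ENHANCEMENT
    return SuppressionClass.STRONG


def select_internal_standard(
    per_candidate: Mapping[str, float], declared_order: Sequence[str]
) -> str:
    """Candidate with the lowest corrected-factor CV; ties break by position
    in ``declared_order``."""
    finite = {k: v for k, v in per_candidate.items() if math.isfinite(v)}
    if not finite:
        raise InsufficientDataError("no candidate internal standard with a finite CV")
    best_cv = min(finite.values())
    tied = [k for k, v in finite.items() if v == best_cv]
    if len(tied) == 1:
        return tied[0]
    ranked = sorted(
        tied,
        key=lambda k: declared_order.index(k) if k in declared_order else len(declared_order),
    )
    return ranked[0]


def _mean_areas_by_lot(
    records: Iterable[InjectionRecord], name: str
) -> Tuple[Dict[str, float], Optional[float]]:
    """Per-lot mean post-extraction-spike area and mean solvent area."""
    by_lot: Dict[str, List[float]] = {}
    solvent: List[float] = []
    for r in records:
        if r.analyte != name:
            continue
        if r.role is Role.POST_EXTRACTION_SPIKE:
            by_lot.setdefault(r.urine_lot or "", []).append(r.area)
        elif r.role is Role.SOLVENT:
            solvent.append(r.area)
    lot_means = {lot: float(np.mean(a)) for lot, a in by_lot.items()}
    solvent_mean = float(np.mean(solvent)) if solvent else None
    return lot_means, solvent_mean


def summarize_matrix_effect(
    records: Sequence[InjectionRecord],
    analyte: str,
    internal_standard: Optional[str] = None,
) -> MatrixFactorSet:
    """Per-lot matrix factors (from replicate-mean areas), their mean over
    lots, and — when an internal standard is given — the IS-corrected factors
    with their CV.
    """
    lot_means, solvent_mean = _mean_areas_by_lot(records, analyte)
    if solvent_mean is None:
        raise InsufficientDataError(
            f"no solvent replicates for {analyte!r}; matrix factors need a "
            "pure-solvent reference"
        )
    if not lot_means:
        raise InsufficientDataError(f"no post-extraction spikes for {analyte!r}")
    per_lot = {
        lot: matrix_factor(m, solvent_mean) for lot, m in sorted(lot_means.items())
    }
    result = MatrixFactorSet(
        analyte=analyte,
        per_lot=per_lot,
        mean_mf=float(np.mean(list(per_lot.values()))),
    )
    if internal_standard is not None:
        is_lots, is_solvent = _mean_areas_by_lot(records, internal_standard)
        if is_solvent is None or not is_lots:
            raise InsufficientDataError(
                f"internal standard {internal_standard!r} lacks matrix-effect records"
            )
        is_mf = {lot: matrix_factor(m, is_solvent) for lot, m in is_lots.items()}
        corrected = {
            lot: is_corrected_matrix_factor(mf, is_mf[lot])
            for lot, mf in per_lot.items()
            if lot in is_mf
        }
        result.internal_standard = internal_standard
        result.per_lot_corrected = corrected
        result.mean_corrected = float(np.mean(list(corrected.values())))
        if len(corrected) >= 2:
            result.cv_corrected = cv_percent(list(corrected.values()))
            ok = result.cv_corrected <= 15.0
            log_decision(
                "relative matrix effect",
                "CV of IS-corrected MF <= 15%",
                f"{result.cv_corrected:.1f}%",
                ok,
                context=f"{analyte}/{internal_standard}",
            )
    return result


def assign_internal_standards(
    records: Sequence[InjectionRecord],
    analytes: Mapping[str, Sequence[str]],
) -> Dict[str, MatrixFactorSet]:
    """For each analyte, evaluate every candidate IS on the matrix-effect
    records and keep the one with the lowest corrected-factor CV."""
    out: Dict[str, MatrixFactorSet] = {}
    for name, candidates in analytes.items():
        per_candidate: Dict[str, float] = {}
        sets: Dict[str, MatrixFactorSet] = {}
        for cand in candidates:
            mfs = summarize_matrix_effect(records, name, cand)
            sets[cand] = mfs
            if mfs.cv_corrected is not None:
                per_candidate[cand] = mfs.cv_corrected
        if per_candidate:
            chosen = select_internal_standard(per_candidate, list(candidates))
            out[name] = sets[chosen]
        else:
            out[name] = summarize_matrix_effect(records, name, None)
    return out
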