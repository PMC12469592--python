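"""End-to-end orchestration: injection records in, validated models and
cohort summaries out. The CLI subcommands are thin wrappers over these."""

from __future__ import annotations

from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .calibration import (
    CalibrationModel,
    CalibrationPoint,
    assess_calibration,
    fit_weighted_ls,
    select_weighting,
)
from .config import StudyConfig
from .matrix_effect import MatrixFactorSet, assign_internal_standards
from .pairing import response_ratios
from .quantify import QuantResult, quantify_sample
from .records import InjectionRecord, Role
from .validation import (
    DilutionVerdict,
    QCAssessment,
    StabilityVerdict,
    assess_qc_batch,
    dilution_integrity_assess,
    stability_from_records,
)


def calibration_curves(
    records: Sequence[InjectionRecord], analyte: str, internal_standard: str
) -> List[List[CalibrationPoint]]:
    """Replicate calibration point sets (one per run) from calibrator rows."""
    by_run: Dict[str, List[CalibrationPoint]] = {}
    for r, ratio in response_ratios(
        records, analyte, internal_standard, roles=[Role.CALIBRATOR]
    ):
        by_run.setdefault(r.run_id, []).append(
            CalibrationPoint(
                level_conc=r.nominal_conc, response_ratio=ratio, run_id=r.run_id
            )
        )
    return [by_run[k] for k in sorted(by_run)]


def fit_study_calibrations(
    records: Sequence[InjectionRecord], config: StudyConfig
) -> Tuple[Dict[str, CalibrationModel], Dict[str, Dict[str, CalibrationModel]]]:
    """Per-analyte assessed (pooled) models plus per-run models.

    Returns ``(assessed, per_run)`` where ``assessed[name]`` carries the
    level assessments / LLOQ and ``per_run[name][run_id]`` the run-specific
    fit used for QC back-calculation.
    """
    assessed: Dict[str, CalibrationModel] = {}
    per_run: Dict[str, Dict[str, CalibrationModel]] = {}
    for a in config.analytes:
        istd = a.assigned_is or (a.candidate_is[0] if a.candidate_is else None)
        if istd is None:
            raise ValueError(f"{a.name!r} has no internal standard")
        curves = calibration_curves(records, a.name, istd)
        if not curves:
            continue
        weighting = select_weighting(curves)
        assessed[a.name] = assess_calibration(curves, a, weighting=weighting)
        per_run[a.name] = {
            pts[0].run_id: fit_weighted_ls(pts, weighting) for pts in curves
        }
        for run_id, model in per_run[a.name].items():
            model.analyte = a.name
            model.lloq = assessed[a.name].lloq
            model.uloq = assessed[a.name].uloq
    return assessed, per_run


def run_validation(
    records: Sequence[InjectionRecord], config: StudyConfig
) -> Dict[str, dict]:
    """Full validation pass: calibration assessment, QC accuracy/precision,
    dilution integrity, and stability, per analyte."""
    assessed, per_run = fit_study_calibrations(records, config)
    out: Dict[str, dict] = {}
    for a in config.analytes:
        if a.name not in assessed:
            continue
        models = per_run[a.name]
        entry = {
            "calibration": assessed[a.name],
            "qc": assess_qc_batch(records, models, a),
            "stability": stability_from_records(records, models, a),
        }
        try:
            entry["dilution"] = dilution_integrity_assess(
                records, assessed[a.name], a
            )
        except Exception:
            entry["dilution"] = None
        out[a.name] = entry
    return out


def matrix_effect_summary(
    records: Sequence[InjectionRecord], config: StudyConfig
) -> Dict[str, MatrixFactorSet]:
    """Matrix factors, IS-corrected factors, and IS assignment per analyte."""
    return assign_internal_standards(
        records,
        {a.name: (a.candidate_is or [a.assigned_is]) for a in config.analytes},
    )


def quantify_study(
    records: Sequence[InjectionRecord],
    models: Mapping[str, CalibrationModel],
    config: StudyConfig,
) -> Dict[str, List[QuantResult]]:
    """Quantify every study-role sample against the assessed models."""
    out: Dict[str, List[QuantResult]] = {}
    for a in config.analytes:
        if a.name not in models:
            continue
        istd = a.assigned_is or a.candidate_is[0]
        results = []
        for r, ratio in response_ratios(records, a.name, istd, roles=[Role.STUDY]):
            results.append(quantify_sample(r, models[a.name], ratio))
        if results:
            out[a.name] = results
    return out
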