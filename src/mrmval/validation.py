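"""Validation-suite rule engines: accuracy/precision of QC batches, run
acceptance, selectivity/carry-over interference limits, dilution integrity,
stability, and method-development recovery comparisons.

All acceptance predicates follow the standard bioanalytical bounds: accuracy
within +/-15 points of 100 % of nominal, precision (CV) at or below 15 %, and
— for routine runs — at least 3 of the 4 bracketing QC samples within
+/-15 %. Carry-over and selectivity share the same interference limits: a
blank may carry at most 20 % of the analyte response at the LLOQ and at most
5 % of the internal-standard response.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from ._log import log_decision
from .calibration import CalibrationModel, back_calculate
from .config import AnalyteConfig
from .matrix_effect import cv_percent
from .pairing import response_ratios
from .records import InjectionRecord, Role

#: Accuracy window (percent of nominal) and CV ceiling used throughout.
ACCURACY_WINDOW = (85.0, 115.0)
CV_MAX = 15.0

#: Stability study conditions keyed by the timepoint label on the records.
STABILITY_CONDITIONS = {
    "24h": "autosampler_24h",
    "30d": "frozen_30d",
    "12m": "frozen_12m",
}


class DesignError(ValueError):
    """The records do not match the experiment's design (wrong counts,
    missing runs or timepoints)."""


@dataclass
class QCAssessment:
    analyte: str
    level: str  # "low" | "high"
    nominal: float
    intra_accuracy: float
    intra_cv: float
    inter_accuracy: float
    inter_cv: float
    passed: bool
    n_intra: int = 0
    n_inter: int = 0

    def to_row(self) -> dict:
        return {
            "analyte": self.analyte,
            "level": self.level,
            "nominal": self.nominal,
            "intra_accuracy": self.intra_accuracy,
            "intra_cv": self.intra_cv,
            "inter_accuracy": self.inter_accuracy,
            "inter_cv": self.inter_cv,
            "passed": self.passed,
        }


@dataclass
class StabilityVerdict:
    analyte: str
    condition: str  # autosampler_24h | frozen_30d | frozen_12m
    level: str
    nominal: float
    accuracy: float
    cv: float
    stable: bool
    n: int = 0
    t0_accuracy: Optional[float] = None

    def to_row(self) -> dict:
        return {
            "analyte": self.analyte,
            "condition": self.condition,
            "level": self.level,
            "nominal": self.nominal,
            "accuracy": self.accuracy,
            "cv": self.cv,
            "n": self.n,
            "stable": self.stable,
        }


@dataclass
class RecoveryComparison:
    condition_label: str
    recoveries: List[float]
    reference_mean: float
    mean_recovery: float
    t_statistic: float
    p_value: float
    significant: bool
    alpha: float = 0.05
    degenerate: bool = False


@dataclass
class InterferenceCheck:
    analyte_fraction: float
    is_fraction: float
    passed: bool
    analyte_limit: float = 0.20
    is_limit: float = 0.05


@dataclass
class DilutionVerdict:
    analyte: str
    nominal: float
    dilution_factor: float
    accuracy: float
    cv: float
    passed: bool
    in_curve: bool
    n: int = 0


def accuracy_percent(measured: Sequence[float], nominal: float) -> float:
    """100 x mean(measured) / nominal."""
    if nominal <= 0:
        raise ValueError("nominal concentration must be positive")
    if len(measured) == 0:
        raise ValueError("need at least one measurement")
    return float(100.0 * np.mean(measured) / nominal)


def _within_accuracy(acc: float) -> bool:
    return ACCURACY_WINDOW[0] <= acc <= ACCURACY_WINDOW[1]


def assess_qc_batch(
    records: Sequence[InjectionRecord],
    models_by_run: Mapping[str, CalibrationModel],
    config: AnalyteConfig,
    intra_run: Optional[str] = None,
) -> List[QCAssessment]:
    """Accuracy and precision of QC samples at the low and high level.

    Concentrations come from back-calculation against each record's own run's
    model. Intra-run metrics use a single designated run (the first run in
    sorted order unless ``intra_run`` is given); inter-run metrics pool every
    run. Pass requires all four metrics inside the acceptance bounds.
    """
    if config.assigned_is is None:
        raise DesignError(f"{config.name!r} has no assigned internal standard")
    ratios = response_ratios(
        records, config.name, config.assigned_is, roles=[Role.QC_LOW, Role.QC_HIGH]
    )
    out: List[QCAssessment] = []
    for level, role in (("low", Role.QC_LOW), ("high", Role.QC_HIGH)):
        level_pairs = [(r, ratio) for r, ratio in ratios if r.role is role]
        if not level_pairs:
            continue
        nominal = level_pairs[0][0].nominal_conc
        runs = sorted({r.run_id for r, _ in level_pairs})
        for r, _ in level_pairs:
            if r.run_id not in models_by_run:
                raise DesignError(f"no calibration model for run {r.run_id!r}")
        concs_by_run: Dict[str, List[float]] = {run: [] for run in runs}
        for r, ratio in level_pairs:
            concs_by_run[r.run_id].append(
                back_calculate(models_by_run[r.run_id], ratio, r.dilution_factor)
            )
        designated = intra_run if intra_run is not None else runs[0]
        if designated not in concs_by_run:
            raise DesignError(f"designated intra-run {designated!r} has no QC records")
        intra = concs_by_run[designated]
        inter = [c for run in runs for c in concs_by_run[run]]
        qc = QCAssessment(
            analyte=config.name,
            level=level,
            nominal=nominal,
            intra_accuracy=accuracy_percent(intra, nominal),
            intra_cv=cv_percent(intra) if len(intra) > 1 else 0.0,
            inter_accuracy=accuracy_percent(inter, nominal),
            inter_cv=cv_percent(inter) if len(inter) > 1 else 0.0,
            passed=False,
            n_intra=len(intra),
            n_inter=len(inter),
        )
        qc.passed = (
            _within_accuracy(qc.intra_accuracy)
            and _within_accuracy(qc.inter_accuracy)
            and qc.intra_cv <= CV_MAX
            and qc.inter_cv <= CV_MAX
        )
        log_decision(
            "QC accuracy/precision",
            f"accuracy in [{ACCURACY_WINDOW[0]}, {ACCURACY_WINDOW[1]}]%, CV <= {CV_MAX}%",
            f"intra {qc.intra_accuracy:.0f}%/{qc.intra_cv:.0f}%, "
            f"inter {qc.inter_accuracy:.0f}%/{qc.inter_cv:.0f}%",
            qc.passed,
            context=f"{config.name} {level.upper()}QC",
        )
        out.append(qc)
    return out


def run_acceptance(qc_accuracies: Sequence[float]) -> bool:
    """Routine-run rule: of the 4 bracketing QC accuracies (2 LQC + 2 HQC),
    at least 3 must fall within +/-15 % of nominal."""
    if len(qc_accuracies) != 4:
        raise DesignError(
            f"run acceptance expects exactly 4 QC accuracies, got {len(qc_accuracies)}"
        )
    n_ok = sum(1 for a in qc_accuracies if _within_accuracy(a))
    accepted = n_ok >= 3
    log_decision(
        "run acceptance", ">= 3 of 4 QCs within +/-15%", f"{n_ok} of 4", accepted
    )
    return accepted


def blank_interference_check(
    blank_response: float,
    lloq_response: float,
    is_blank_response: float,
    is_nominal_response: float,
    analyte_limit: float = 0.20,
    is_limit: float = 0.05,
) -> InterferenceCheck:
    """Selectivity / carry-over rule: blank interference at most 20 % of the
    LLOQ-level analyte response and at most 5 % of the IS response."""
    if lloq_response <= 0 or is_nominal_response <= 0:
        raise ValueError("reference responses must be positive")
    analyte_fraction = blank_response / lloq_response
    is_fraction = is_blank_response / is_nominal_response
    passed = analyte_fraction <= analyte_limit and is_fraction <= is_limit
    log_decision(
        "blank interference",
        f"analyte <= {analyte_limit:.0%} of LLOQ, IS <= {is_limit:.0%}",
        f"analyte {analyte_fraction:.2%}, IS {is_fraction:.2%}",
        passed,
    )
    return InterferenceCheck(
        analyte_fraction=analyte_fraction,
        is_fraction=is_fraction,
        passed=passed,
        analyte_limit=analyte_limit,
        is_limit=is_limit,
    )


def dilution_integrity_assess(
    records: Sequence[InjectionRecord],
    model: CalibrationModel,
    config: AnalyteConfig,
) -> DilutionVerdict:
    """Above-range samples diluted into the curve must read back accurately
    once re-multiplied by the dilution factor (QC accuracy/CV rules). The
    pre-dilution response must itself fall inside the calibration range."""
    if config.assigned_is is None:
        raise DesignError(f"{config.name!r} has no assigned internal standard")
    pairs = response_ratios(
        records, config.name, config.assigned_is, roles=[Role.DILUTION_QC]
    )
    if not pairs:
        raise DesignError(f"no dilution-QC records for {config.name!r}")
    nominal = pairs[0][0].nominal_conc
    factor = pairs[0][0].dilution_factor
    concs = [back_calculate(model, ratio, r.dilution_factor) for r, ratio in pairs]
    undiluted = [back_calculate(model, ratio) for _, ratio in pairs]
    # the diluted response must sit inside the calibration range; the
    # accuracy tolerance applies because the design targets the ULOQ exactly
    tol = config.level_acceptance_pct / 100.0
    in_curve = all(
        (model.lloq is None or c >= model.lloq * (1 - tol))
        and (model.uloq is None or c <= model.uloq * (1 + tol))
        for c in undiluted
    )
    acc = accuracy_percent(concs, nominal)
    cv = cv_percent(concs) if len(concs) > 1 else 0.0
    passed = _within_accuracy(acc) and cv <= CV_MAX and in_curve
    log_decision(
        "dilution integrity",
        f"accuracy +/-15%, CV <= {CV_MAX}%, diluted response in curve",
        f"accuracy {acc:.0f}%, CV {cv:.0f}%, in_curve={in_curve}",
        passed,
        context=config.name,
    )
    return DilutionVerdict(
        analyte=config.name,
        nominal=nominal,
        dilution_factor=factor,
        accuracy=acc,
        cv=cv,
        passed=passed,
        in_curve=in_curve,
        n=len(concs),
    )


def stability_assess(
    concentrations_t0: Sequence[float],
    concentrations_later: Sequence[float],
    nominal: float,
    condition: str,
    level: str = "",
    analyte: str = "",
) -> StabilityVerdict:
    """Stability under a storage condition: accuracy at the later timepoint
    versus nominal within 85-115 % and CV at most 15 %. t0 accuracy is
    reported for context only."""
    if len(concentrations_later) < 3:
        raise DesignError("stability assessment needs >= 3 replicates")
    if not concentrations_t0:
        raise DesignError("missing t0 replicates")
    acc = accuracy_percent(concentrations_later, nominal)
    cv = cv_percent(concentrations_later)
    stable = _within_accuracy(acc) and cv <= CV_MAX
    log_decision(
        "stability",
        f"accuracy in [85, 115]%, CV <= {CV_MAX}%",
        f"accuracy {acc:.0f}%, CV {cv:.0f}%",
        stable,
        context=f"{analyte} {condition} {level}",
    )
    return StabilityVerdict(
        analyte=analyte,
        condition=condition,
        level=level,
        nominal=nominal,
        accuracy=acc,
        cv=cv,
        stable=stable,
        n=len(concentrations_later),
        t0_accuracy=accuracy_percent(concentrations_t0, nominal),
    )


def stability_from_records(
    records: Sequence[InjectionRecord],
    models_by_run: Mapping[str, CalibrationModel],
    config: AnalyteConfig,
) -> List[StabilityVerdict]:
    """Run the stability rule for every (condition, level) present among the
    stability-QC records of an analyte."""
    if config.assigned_is is None:
        raise DesignError(f"{config.name!r} has no assigned internal standard")
    pairs = response_ratios(
        records, config.name, config.assigned_is, roles=[Role.STABILITY_QC]
    )
    by_key: Dict[tuple, List[float]] = {}
    for r, ratio in pairs:
        if r.run_id not in models_by_run:
            raise DesignError(f"no calibration model for run {r.run_id!r}")
        conc = back_calculate(models_by_run[r.run_id], ratio, r.dilution_factor)
        by_key.setdefault((r.timepoint, r.nominal_conc), []).append(conc)
    nominals = sorted({nom for (_, nom) in by_key})
    level_of = {nom: ("low" if i == 0 else "high") for i, nom in enumerate(nominals)}
    if len(nominals) > 2:
        raise DesignError("expected at most two stability QC levels")
    out: List[StabilityVerdict] = []
    for tp, condition in STABILITY_CONDITIONS.items():
        for nom in nominals:
            later = by_key.get((tp, nom))
            if later is None:
                continue
            t0 = by_key.get(("t0", nom))
            if t0 is None:
                raise DesignError(f"missing t0 replicates at nominal {nom}")
            out.append(
                stability_assess(
                    t0, later, nom, condition, level_of[nom], config.name
                )
            )
    return out


def recovery_percent(observed: Sequence[float], reference_mean: float) -> float:
    """100 x mean(observed) / reference mean (the unfiltered / unextracted
    reference defines 100 % recovery)."""
    if reference_mean <= 0:
        raise ValueError("reference mean must be positive")
    return float(100.0 * np.mean(observed) / reference_mean)


def compare_recovery_ttest(
    group_a: Sequence[float],
    group_b: Sequence[float],
    alpha: float = 0.05,
    equal_var: bool = True,
    condition_label: str = "",
) -> RecoveryComparison:
    """Two-sided two-sample t-test between recovery groups (pooled-variance
    Student by default; Welch via ``equal_var=False``)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two values per group")
    degenerate = a.std(ddof=1) == 0 and b.std(ddof=1) == 0
    if degenerate and a.mean() == b.mean():
        t_stat, p_val = 0.0, 1.0
    else:
        t_stat, p_val = stats.ttest_ind(a, b, equal_var=equal_var)
        t_stat, p_val = float(t_stat), float(p_val)
        degenerate = not np.isfinite(t_stat)
        if degenerate:
            t_stat, p_val = 0.0, 1.0
    ref = float(b.mean())
    return RecoveryComparison(
        condition_label=condition_label,
        recoveries=[float(x) for x in a],
        reference_mean=ref,
        mean_recovery=recovery_percent(a, ref) if ref > 0 else float("nan"),
        t_statistic=t_stat,
        p_value=p_val,
        significant=(p_val < alpha) and not degenerate,
        alpha=alpha,
        degenerate=degenerate,
    )
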