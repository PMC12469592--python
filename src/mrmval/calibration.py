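"""Matrix-matched internal calibration.

The response model is a straight line through analyte/IS response ratios,
``y = a*x + b``, fitted by weighted least squares with the weighting schemes
customary in bioanalysis (equal weights, 1/x, or 1/x^2). Back-calculated
calibrator accuracy drives acceptance: the lowest level must read back within
+/-20 % of nominal, every other level within +/-15 %, with at least 75 % of
replicates passing per level. The lower limit of quantification (LLOQ) is the
lowest passing level from which every higher level also passes, and the upper
limit (ULOQ) is the top configured level.

Curve fitting goes through :mod:`statsmodels` WLS; the coefficient of
determination is the weighted R^2 about the weighted mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import statsmodels.api as sm

from ._log import log_decision
from .config import AnalyteConfig

#: Supported weighting schemes, ordered lightest to heaviest.
WEIGHTINGS = ("none", "1/x", "1/x2")


class SingularDesignError(ValueError):
    """All calibration levels identical; the line is not identifiable."""


class DegenerateModelError(ValueError):
    """Zero slope; concentrations cannot be back-calculated."""


@dataclass(frozen=True)
class CalibrationPoint:
    level_conc: float  # pg/mL
    response_ratio: float  # analyte area / IS area
    run_id: str = ""

    def __post_init__(self) -> None:
        if self.level_conc <= 0:
            raise ValueError("calibrator level_conc must be positive")
        if self.response_ratio < 0:
            raise ValueError("response_ratio must be nonnegative")


@dataclass
class LevelAssessment:
    level_conc: float
    accuracies: List[float]  # back-calculated / nominal x 100, per replicate
    tolerance_pct: float
    pass_fraction: float
    passed: bool


@dataclass
class CalibrationModel:
    slope: float
    intercept: float
    weighting: str
    r_squared: float
    level_assessments: List[LevelAssessment] = field(default_factory=list)
    lloq: Optional[float] = None
    uloq: Optional[float] = None
    acceptable: bool = True
    no_valid_range: bool = False
    analyte: str = ""

    def predict(self, conc: float) -> float:
        return self.slope * conc + self.intercept

    def to_row(self) -> dict:
        return {
            "analyte": self.analyte,
            "slope": self.slope,
            "intercept": self.intercept,
            "curve_fit": "Linear",
            "weighting": self.weighting,
            "r_squared": self.r_squared,
            "lloq": self.lloq,
            "uloq": self.uloq,
            "acceptable": self.acceptable,
        }


def _weights(x: np.ndarray, weighting: str) -> np.ndarray:
    if weighting == "none":
        return np.ones_like(x)
    if weighting == "1/x":
        return 1.0 / x
    if weighting == "1/x2":
        return 1.0 / x**2
    raise ValueError(f"unknown weighting {weighting!r}; expected one of {WEIGHTINGS}")


def fit_weighted_ls(
    points: Sequence[CalibrationPoint], weighting: str = "1/x"
) -> CalibrationModel:
    """Fit ``ratio = a*conc + b`` minimizing ``sum w_i (y_i - a x_i - b)^2``."""
    x = np.asarray([p.level_conc for p in points], dtype=float)
    y = np.asarray([p.response_ratio for p in points], dtype=float)
    if np.unique(x).size < 2:
        raise SingularDesignError(
            "need at least two distinct calibration levels to fit a line"
        )
    w = _weights(x, weighting)
    fit = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    intercept, slope = fit.params
    return CalibrationModel(
        slope=float(slope),
        intercept=float(intercept),
        weighting=weighting,
        r_squared=float(fit.rsquared),
    )


def back_calculate(
    model: CalibrationModel, response_ratio: float, dilution_factor: float = 1.0
) -> float:
    """Invert the calibration line; negative results are preserved (callers
    decide censoring). ``dilution_factor`` re-multiplies diluted samples."""
    if model.slope == 0:
        raise DegenerateModelError("slope is zero; model cannot be inverted")
    return dilution_factor * (response_ratio - model.intercept) / model.slope


def _mean_abs_rel_backcalc_error(
    curves: Sequence[Sequence[CalibrationPoint]], weighting: str
) -> float:
    errors: List[float] = []
    for points in curves:
        model = fit_weighted_ls(points, weighting)
        for p in points:
            bc = back_calculate(model, p.response_ratio)
            errors.append(abs(bc - p.level_conc) / p.level_conc)
    return float(np.mean(errors))


def select_weighting(curves: Sequence[Sequence[CalibrationPoint]]) -> str:
    """Pick the weighting minimizing mean |relative back-calculation error|
    across all standards of all replicate curves; ties break toward the
    heavier weighting (1/x2 over 1/x over none)."""
    scores = {w: _mean_abs_rel_backcalc_error(curves, w) for w in WEIGHTINGS}
    best = min(scores.values())
    # iterate heaviest first so a tie resolves to the heavier scheme
    for w in reversed(WEIGHTINGS):
        if scores[w] <= best * (1 + 1e-12):
            return w
    raise AssertionError("unreachable")


def assess_levels(
    accuracies_by_level: Dict[float, List[float]], config: AnalyteConfig
) -> tuple:
    """Apply the level-acceptance and LLOQ rules to back-calculated
    accuracies (percent of nominal) per level.

    The lowest level is judged against ``lloq_acceptance_pct`` (+/-20 % by
    default), all others against ``level_acceptance_pct`` (+/-15 %); a level
    passes when at least ``min_level_pass_fraction`` of its replicates are
    inside the window. Returns ``(assessments, lloq)`` where the LLOQ is the
    lowest passing level from which every higher level also passes (``None``
    when no such level exists).
    """
    levels = sorted(lvl for lvl, acc in accuracies_by_level.items() if acc)
    lowest = levels[0] if levels else None
    assessments: List[LevelAssessment] = []
    for lvl in levels:
        acc = accuracies_by_level[lvl]
        tol = (
            config.lloq_acceptance_pct if lvl == lowest else config.level_acceptance_pct
        )
        n_pass = sum(1 for a in acc if abs(a - 100.0) <= tol)
        frac = n_pass / len(acc)
        passed = frac >= config.min_level_pass_fraction
        log_decision(
            "calibration level accuracy",
            f"+/-{tol}% in >= {config.min_level_pass_fraction:.0%} of replicates",
            f"pass_fraction={frac:.2f}",
            passed,
            context=f"{config.name} level {lvl} pg/mL",
        )
        assessments.append(
            LevelAssessment(
                level_conc=lvl,
                accuracies=list(acc),
                tolerance_pct=tol,
                pass_fraction=frac,
                passed=passed,
            )
        )
    lloq = None
    for i, a in enumerate(assessments):
        if all(b.passed for b in assessments[i:]):
            lloq = a.level_conc
            break
    return assessments, lloq


def assess_calibration(
    curves: Sequence[Sequence[CalibrationPoint]],
    config: AnalyteConfig,
    weighting: Optional[str] = None,
) -> CalibrationModel:
    """Fit replicate curves, assess back-calculated accuracy per level, and
    determine the LLOQ.

    Each replicate curve is fitted on its own run; every calibrator is
    back-calculated against its own run's model. The reported coefficients and
    R^2 come from a pooled fit over all points. The LLOQ is the lowest level
    that passes with all higher levels also passing; if no level passes the
    model carries ``no_valid_range=True`` and ``lloq=None``.
    """
    if weighting is None:
        weighting = select_weighting(curves)
    per_run_models = [fit_weighted_ls(points, weighting) for points in curves]
    pooled = fit_weighted_ls([p for pts in curves for p in pts], weighting)
    pooled.weighting = weighting
    pooled.analyte = config.name

    accuracies_by_level: Dict[float, List[float]] = {
        lvl: [] for lvl in config.calibration_levels
    }
    for model, points in zip(per_run_models, curves):
        for p in points:
            if p.level_conc not in accuracies_by_level:
                accuracies_by_level[p.level_conc] = []
            bc = back_calculate(model, p.response_ratio)
            accuracies_by_level[p.level_conc].append(100.0 * bc / p.level_conc)

    assessments, lloq = assess_levels(accuracies_by_level, config)
    pooled.level_assessments = assessments
    pooled.uloq = assessments[-1].level_conc if assessments else None
    if lloq is None:
        pooled.no_valid_range = True
    pooled.lloq = lloq

    r2_ok = pooled.r_squared >= config.r2_min
    log_decision(
        "calibration linearity",
        f"R^2 >= {config.r2_min}",
        f"{pooled.r_squared:.4f}",
        r2_ok,
        context=config.name,
    )
    pooled.acceptable = r2_ok and lloq is not None
    return pooled
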