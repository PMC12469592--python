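"""Study-sample quantitation and censoring-aware cohort summaries.

Back-calculated study concentrations are censored against the calibration
range: below the LLOQ they are reported as "< LLOQ" (non-detects), above the
ULOQ — after dilution handling — as "> ULOQ". Urinary dilution is normalized
by specific gravity (SG): ``C_adj = C * (SG_ref - 1) / (SG_sample - 1)``,
with the cohort median SG as the default reference.

Cohort summaries follow human-biomonitoring reporting conventions for
left-censored data: non-detects rank as zeros in the empirical percentiles
(averaged inverted-CDF convention, so at exactly 50 % detection the median is
the arithmetic mean of zero and the first quantified result), censored-high
values propagate as "> ULOQ", and the geometric mean substitutes non-detects
by a configurable policy (LLOQ/2 by default; the "zero" policy suppresses the
GM whenever a non-detect is present, since log 0 is undefined).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .calibration import CalibrationModel, back_calculate
from .config import StudyConfig
from .records import InjectionRecord

#: Rendered form of a right-censored summary statistic.
ABOVE_ULOQ = ">ULOQ"

SummaryValue = Union[float, str, None]  # number, ">ULOQ", or absent


class Censor(str, Enum):
    NONE = "none"
    BELOW_LLOQ = "below_lloq"
    ABOVE_ULOQ = "above_uloq"


class MissingDataError(ValueError):
    pass


@dataclass
class QuantResult:
    sample_id: str
    analyte: str
    conc_raw: float  # numeric back-calculated value, kept even when censored
    censor: Censor
    lloq: float
    uloq: float
    sg: Optional[float] = None
    conc_sg: Optional[float] = None
    sg_factor: Optional[float] = None  # (sg_ref - 1) / (sg_sample - 1)

    @property
    def detected(self) -> bool:
        return self.censor is not Censor.BELOW_LLOQ


@dataclass
class CohortSummary:
    analyte: str
    n: int
    detection_rate: float  # %
    gm: SummaryValue
    p25: SummaryValue
    p50: SummaryValue
    p75: SummaryValue
    p95: SummaryValue
    max: SummaryValue
    adjusted: bool
    gm_policy: str = "half_lloq"

    def to_row(self) -> dict:
        return {
            "analyte": self.analyte,
            "n": self.n,
            "adjusted": self.adjusted,
            "detection_rate": self.detection_rate,
            "gm": self.gm,
            "p25": self.p25,
            "p50": self.p50,
            "p75": self.p75,
            "p95": self.p95,
            "max": self.max,
        }


def quantify_sample(
    record: InjectionRecord,
    model: CalibrationModel,
    response_ratio: float,
) -> QuantResult:
    """Back-calculate one study sample and censor against the calibration
    range. A value exactly at the LLOQ (or ULOQ) is quantifiable, not
    censored."""
    if model.lloq is None or model.uloq is None:
        raise MissingDataError(
            f"calibration model for {record.analyte!r} has no quantifiable range"
        )
    conc = back_calculate(model, response_ratio, record.dilution_factor)
    if conc < model.lloq:
        censor = Censor.BELOW_LLOQ
    elif conc > model.uloq * record.dilution_factor:
        censor = Censor.ABOVE_ULOQ
    else:
        censor = Censor.NONE
    return QuantResult(
        sample_id=record.sample_id,
        analyte=record.analyte,
        conc_raw=conc,
        censor=censor,
        lloq=model.lloq,
        uloq=model.uloq,
    )


def sg_adjust(conc: float, sg_sample: float, sg_reference: float) -> float:
    """Specific-gravity dilution normalization:
    ``conc * (sg_reference - 1) / (sg_sample - 1)``."""
    if sg_sample <= 1:
        raise ValueError(f"sg_sample must exceed 1, got {sg_sample}")
    if sg_reference <= 1:
        raise ValueError(f"sg_reference must exceed 1, got {sg_reference}")
    return conc * (sg_reference - 1.0) / (sg_sample - 1.0)


def apply_sg_adjustment(
    results: Sequence[QuantResult],
    sg_by_sample: Mapping[str, float],
    sg_reference: Union[float, str] = "cohort_median",
) -> float:
    """Attach SG and SG-adjusted concentrations to results in place; returns
    the reference SG used. ``"cohort_median"`` resolves to the median SG over
    the distinct samples present."""
    missing = sorted({r.sample_id for r in results} - set(sg_by_sample))
    if missing:
        raise MissingDataError(f"no specific gravity for samples: {missing}")
    if sg_reference == "cohort_median":
        sgs = {r.sample_id: sg_by_sample[r.sample_id] for r in results}
        ref = float(np.median(list(sgs.values())))
    else:
        ref = float(sg_reference)
    for r in results:
        r.sg = sg_by_sample[r.sample_id]
        r.conc_sg = sg_adjust(r.conc_raw, r.sg, ref)
        r.sg_factor = (ref - 1.0) / (r.sg - 1.0)
    return ref


def detection_rate(results: Sequence[QuantResult]) -> float:
    """Percent of results quantifiable at or above the LLOQ."""
    if not results:
        raise MissingDataError("empty result list")
    return 100.0 * sum(r.detected for r in results) / len(results)


def _numeric_values(results: Sequence[QuantResult], adjusted: bool) -> np.ndarray:
    """Ranking values: non-detects as 0, censored-high as +inf."""
    vals = []
    for r in results:
        if r.censor is Censor.BELOW_LLOQ:
            vals.append(0.0)
        elif r.censor is Censor.ABOVE_ULOQ:
            vals.append(math.inf)
        else:
            v = r.conc_sg if adjusted else r.conc_raw
            if adjusted and v is None:
                raise MissingDataError(f"sample {r.sample_id!r} lacks SG adjustment")
            vals.append(float(v))
    return np.asarray(vals, dtype=float)


def censored_percentiles(
    results: Sequence[QuantResult],
    levels: Sequence[float],
    adjusted: bool = False,
) -> List[SummaryValue]:
    """Empirical percentiles under the averaged inverted-CDF convention with
    non-detects ranked as zeros. A percentile landing on a censored-high
    value propagates as ">ULOQ"."""
    if not results:
        raise MissingDataError("empty result list")
    vals = np.sort(_numeric_values(results, adjusted))
    n = vals.size
    out: List[SummaryValue] = []
    for lv in levels:
        # averaged inverted CDF: at an integer rank boundary average the two
        # bracketing order statistics, otherwise take the next one up
        h = lv / 100.0 * n
        k = round(h)
        if abs(h - k) < 1e-9 * max(n, 1) and 1 <= k < n:
            q = (vals[k - 1] + vals[k]) / 2.0
        else:
            k = min(max(math.ceil(h - 1e-12), 1), n)
            q = vals[k - 1]
        q = float(q)
        out.append(ABOVE_ULOQ if math.isinf(q) else q)
    return out


def geometric_mean(
    results: Sequence[QuantResult],
    substitution: str = "half_lloq",
    adjusted: bool = False,
) -> Optional[float]:
    """exp(mean(log x)) with non-detects substituted per policy. Policy
    ``"zero"`` reports the GM as absent whenever a non-detect is present;
    censored-high values contribute their (possibly SG-adjusted) ULOQ, a
    downward-biased stand-in."""
    if not results:
        raise MissingDataError("empty result list")
    logs: List[float] = []
    for r in results:
        if r.censor is Censor.BELOW_LLOQ:
            if substitution == "zero":
                return None
            sub = r.lloq / 2.0 if substitution == "half_lloq" else r.lloq / math.sqrt(2)
            if adjusted:
                if r.sg_factor is None:
                    raise MissingDataError(
                        f"sample {r.sample_id!r} lacks SG adjustment"
                    )
                sub *= r.sg_factor
            logs.append(math.log(sub))
        elif r.censor is Censor.ABOVE_ULOQ:
            v = r.uloq
            if adjusted:
                if r.sg_factor is None:
                    raise MissingDataError(
                        f"sample {r.sample_id!r} lacks SG adjustment"
                    )
                v *= r.sg_factor
            logs.append(math.log(v))
        else:
            v = r.conc_sg if adjusted else r.conc_raw
            if v is None or v <= 0:
                return None
            logs.append(math.log(v))
    return float(math.exp(np.mean(logs)))


def _cohort_max(results: Sequence[QuantResult], adjusted: bool) -> SummaryValue:
    vals = _numeric_values(results, adjusted)
    top = float(vals.max())
    if math.isinf(top):
        return ABOVE_ULOQ
    return top if top > 0 else None


def summarize_cohort(
    results: Sequence[QuantResult],
    config: StudyConfig,
    adjusted: bool = False,
    gm_floor_pct: float = 50.0,
    p95_floor_pct: float = 18.0,
) -> CohortSummary:
    """Detection rate plus GM and P25/P50/P75/P95/Max for one analyte.

    Reporting floors mirror biomonitoring practice: the GM and the quartiles
    are suppressed below ``gm_floor_pct`` detection, P95 below
    ``p95_floor_pct``; the maximum is shown whenever anything was detected.
    Quartiles that land in the non-detect mass (value 0) are reported absent,
    except the exactly-50 %-detection median, which is the mean of zero and
    the first quantified result by the ranking convention.
    """
    if not results:
        raise MissingDataError("empty result list")
    analyte = results[0].analyte
    rate = detection_rate(results)
    p25, p50, p75, p95 = censored_percentiles(results, [25, 50, 75, 95], adjusted)

    def floor(value: SummaryValue, min_rate: float) -> SummaryValue:
        if rate < min_rate:
            return None
        if isinstance(value, float) and value <= 0:
            return None
        return value

    gm = geometric_mean(results, config.nondetect_substitution, adjusted)
    return CohortSummary(
        analyte=analyte,
        n=len(results),
        detection_rate=rate,
        gm=(gm if rate >= gm_floor_pct else None),
        p25=floor(p25, gm_floor_pct),
        p50=floor(p50, gm_floor_pct),
        p75=floor(p75, gm_floor_pct),
        p95=floor(p95, p95_floor_pct),
        max=_cohort_max(results, adjusted),
        adjusted=adjusted,
        gm_policy=config.nondetect_substitution,
    )


def summarize_study(
    results_by_analyte: Mapping[str, Sequence[QuantResult]],
    config: StudyConfig,
    sg_by_sample: Optional[Mapping[str, float]] = None,
) -> Tuple[List[CohortSummary], List[CohortSummary]]:
    """Raw and SG-adjusted summaries for every analyte of a study."""
    raw: List[CohortSummary] = []
    adj: List[CohortSummary] = []
    for name, results in results_by_analyte.items():
        results = list(results)
        raw.append(summarize_cohort(results, config, adjusted=False))
        if sg_by_sample is not None:
            apply_sg_adjustment(results, sg_by_sample, config.sg_reference)
            adj.append(summarize_cohort(results, config, adjusted=True))
    return raw, adj
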