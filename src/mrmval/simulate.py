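"""Synthetic MRM-response generator.

Emits injection-level datasets with the statistical structure the validation
and application analyses assume, so every pipeline stage runs without any
instrument data:

* a straight-line response per analyte (``area = slope*conc + intercept``),
* per-urine-lot multiplicative signal suppression (matrix factors roughly
  0.02-0.9, decreasing with specific gravity plus lot-specific jitter — the
  pattern seen when concentrated urine extracts suppress electrospray
  ionization),
* internal standards whose suppression shares a configurable fraction of the
  analyte's lot suppression (``is_correlation``: 1 makes IS correction
  perfect, 0 makes it useless),
* multiplicative log-normal injection noise (areas stay positive; CVs are
  scale-free, matching the CV-based acceptance rules),
* a study cohort with specific gravities spanning the configured range and
  left-censored log-normal concentration distributions (a point mass at zero
  for non-exposed subjects).

The validation-suite design mirrors standard bioanalytical practice: four
replicate calibration curves over the configured levels, 5 within-run plus
15 between-run QC replicates at two levels, post-extraction spikes in seven
urine lots in triplicate plus solvent triplicates, blank/zero samples per
run, a ULOQ-then-blank carry-over pair, five 8x-ULOQ dilution-integrity
replicates, and stability sets at t0 / 24 h / 30 d / 12 m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .config import StudyConfig
from .panel import MATRIX_LOT_SGS, PANEL
from .records import InjectionRecord, Role

#: Validation-design constants (replicate structure of each experiment).
N_CAL_RUNS = 4
N_QC_RUNS = 3
N_QC_REPS = 5
N_ME_LOTS = 7
N_ME_REPS = 3
N_ME_SOLVENT = 3
N_DILUTION_REPS = 5
DILUTION_FACTOR = 8.0
STABILITY_TIMEPOINTS = ("t0", "24h", "30d", "12m")
N_STABILITY_REPS = 3

#: Calibration/QC pool lot id (single-source blank matrix).
POOL_LOT = "pool"


@dataclass(frozen=True)
class TrueConcSpec:
    """Cohort truth distribution for one analyte: log-normal (median, GSD)
    with a point mass at zero for the non-exposed fraction."""

    median: float
    gsd: float
    exposed_fraction: float

    def __post_init__(self) -> None:
        if self.median < 0 or self.gsd < 1:
            raise ValueError("median must be >= 0 and GSD >= 1")
        if not (0 <= self.exposed_fraction <= 1):
            raise ValueError("exposed_fraction must lie in [0, 1]")


@dataclass
class SimulationParams:
    slope_per_analyte: Dict[str, float]
    intercept_per_analyte: Dict[str, float]
    lot_matrix_factor: Dict[str, Dict[str, float]]  # lot -> name -> factor
    lot_sg: Dict[str, float]
    is_for_analyte: Dict[str, str]  # analyte -> internal standard
    is_response: Dict[str, float] = field(default_factory=dict)  # IS area scale
    true_conc_distribution: Dict[str, TrueConcSpec] = field(default_factory=dict)
    is_correlation: float = 0.9
    injection_cv: float = 0.05
    heteroscedasticity_exponent: float = 1.0
    ref_conc: Dict[str, float] = field(default_factory=dict)  # ULOQ-like reference
    cohort_size: int = 28
    sg_range: Tuple[float, float] = (1.006, 1.031)
    carryover_fraction: float = 0.001
    stability_loss: Dict[Tuple[str, str], float] = field(default_factory=dict)
    # matrix-factor generator (log-factor linear in SG + jitter)
    mf_log_at_low_sg: float = math.log(0.60)
    mf_log_at_high_sg: float = math.log(0.15)
    analyte_susceptibility: Dict[str, float] = field(default_factory=dict)
    mf_jitter_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.injection_cv < 0:
            raise ValueError("injection_cv must be nonnegative")
        if not (0 <= self.is_correlation <= 1):
            raise ValueError("is_correlation must lie in [0, 1]")
        if not (0 <= self.heteroscedasticity_exponent <= 1):
            raise ValueError("heteroscedasticity_exponent must lie in [0, 1]")
        lo, hi = self.sg_range
        if not (1 < lo < hi):
            raise ValueError("sg_range must satisfy 1 < low < high")
        for lot, factors in self.lot_matrix_factor.items():
            for name, f in factors.items():
                if not (0 < f <= 1.5):
                    raise ValueError(
                        f"lot factor for {name!r} in {lot!r} must lie in (0, 1.5]"
                    )

    # -- factory -----------------------------------------------------------

    @classmethod
    def from_config(
        cls,
        config: StudyConfig,
        seed: int = 0,
        is_correlation: float = 0.9,
        injection_cv: float = 0.05,
        **overrides,
    ) -> "SimulationParams":
        """Default parameters for a study configuration.

        Slopes/intercepts come from the reference panel where the analyte
        name matches, else unit slope / zero intercept. Lot matrix factors
        decrease log-linearly with SG with per-analyte susceptibility and
        per-lot jitter, spanning roughly 0.02-0.9 across the panel.
        """
        rng = np.random.default_rng(seed)
        names = [a.name for a in config.analytes]
        istds = config.internal_standards
        slopes, intercepts, ref, is_map = {}, {}, {}, {}
        for a in config.analytes:
            if a.name in PANEL:
                _, _, slope, intercept, _, istd, _, _ = PANEL[a.name]
            else:
                slope, intercept, istd = 1.0, 0.0, None
            slopes[a.name] = slope
            intercepts[a.name] = intercept
            ref[a.name] = a.uloq
            is_map[a.name] = a.assigned_is or istd or (
                a.candidate_is[0] if a.candidate_is else f"{a.name}-IS"
            )
        all_is = sorted(set(is_map.values()) | set(istds))
        susceptibility = {
            name: float(np.exp(rng.uniform(math.log(0.08), math.log(1.4))))
            for name in names + all_is
        }
        params = cls(
            slope_per_analyte=slopes,
            intercept_per_analyte=intercepts,
            lot_matrix_factor={},
            lot_sg={},
            is_for_analyte=is_map,
            is_response={istd: 1.0 for istd in all_is},
            true_conc_distribution={
                a.name: TrueConcSpec(
                    median=3.0 * a.calibration_levels[0],
                    gsd=3.0,
                    exposed_fraction=0.75,
                )
                for a in config.analytes
            },
            is_correlation=is_correlation,
            injection_cv=injection_cv,
            ref_conc=ref,
            analyte_susceptibility=susceptibility,
            seed=seed,
        )
        for key, value in overrides.items():
            if not hasattr(params, key):
                raise TypeError(f"unknown simulation parameter {key!r}")
            setattr(params, key, value)
        # matrix-effect lots plus the calibration/QC pool
        for sg in MATRIX_LOT_SGS:
            lot = f"lot_{sg:.3f}"
            params.lot_sg[lot] = sg
            params.lot_matrix_factor[lot] = params.draw_lot_factors(sg, rng)
        params.lot_sg[POOL_LOT] = 1.015
        params.lot_matrix_factor[POOL_LOT] = params.draw_lot_factors(1.015, rng)
        params.__post_init__()
        return params

    def draw_lot_factors(self, sg: float, rng: np.random.Generator) -> Dict[str, float]:
        """Matrix factors for one lot at the given SG: log-linear base trend
        in SG times per-analyte susceptibility times log-normal jitter,
        clipped into (0, 1.5]."""
        lo, hi = self.sg_range
        t = (sg - lo) / (hi - lo)
        base = self.mf_log_at_low_sg + t * (self.mf_log_at_high_sg - self.mf_log_at_low_sg)
        out: Dict[str, float] = {}
        for name, sus in self.analyte_susceptibility.items():
            jitter = rng.normal(0.0, self.mf_jitter_sd) if self.mf_jitter_sd > 0 else 0.0
            out[name] = float(np.clip(math.exp(base + jitter) * sus, 1e-3, 1.5))
        return out


@dataclass
class SimulatedStudy:
    records: List[InjectionRecord]
    truth: Dict[Tuple[str, str], float] = field(default_factory=dict)
    lot_truth: Dict[str, Dict[str, float]] = field(default_factory=dict)
    sg_by_sample: Dict[str, float] = field(default_factory=dict)


# -- response model ---------------------------------------------------------


def _noise_factor(rng: np.random.Generator, cv: float) -> float:
    if cv <= 0:
        return 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return float(np.exp(rng.normal(0.0, sigma)))


def _effective_cv(params: SimulationParams, analyte: str, conc: float) -> float:
    """Relative noise level at a concentration. With exponent 1 the noise is
    purely multiplicative (constant CV); below 1 the relative noise grows
    toward low concentrations as (conc/ref)^(h-1), capped at 100 %."""
    cv = params.injection_cv
    h = params.heteroscedasticity_exponent
    if conc <= 0 or h == 1.0:
        return cv
    ref = params.ref_conc.get(analyte, conc)
    return min(cv * (conc / ref) ** (h - 1.0), 1.0)


def _lot_factor(params: SimulationParams, lot: Optional[str], name: str) -> float:
    if lot is None:
        return 1.0
    try:
        return params.lot_matrix_factor[lot][name]
    except KeyError as exc:
        raise KeyError(f"no matrix factor for {name!r} in lot {lot!r}") from exc


def simulate_response(
    conc: float,
    params: SimulationParams,
    analyte: str,
    lot: Optional[str],
    rng: np.random.Generator,
) -> Tuple[float, float]:
    """One injection: (analyte area, internal-standard area).

    ``analyte area = (slope*conc + intercept) * lot_factor * exp(noise)``;
    the IS area uses ``lot_factor^is_correlation * own_factor^(1-is_corr)``
    so IS correction spans perfect (1) to useless (0). ``lot=None`` means
    pure solvent (factor 1). Areas are clipped at zero from below.
    """
    if conc < 0:
        raise ValueError(f"concentration must be nonnegative, got {conc}")
    slope = params.slope_per_analyte[analyte]
    intercept = params.intercept_per_analyte.get(analyte, 0.0)
    f_analyte = _lot_factor(params, lot, analyte)
    mean = slope * conc + intercept
    if mean <= 0:
        area = 0.0
    else:
        area = mean * f_analyte * _noise_factor(
            rng, _effective_cv(params, analyte, conc)
        )
    istd = params.is_for_analyte[analyte]
    rho = params.is_correlation
    f_own = _lot_factor(params, lot, istd) if lot is not None else 1.0
    f_is = (f_analyte**rho) * (f_own ** (1.0 - rho)) if lot is not None else 1.0
    is_scale = params.is_response.get(istd, 1.0)
    is_area = is_scale * f_is * _noise_factor(rng, params.injection_cv)
    return area, is_area


# -- validation suite -------------------------------------------------------


def _check_uniform_levels(config: StudyConfig) -> int:
    counts = {len(a.calibration_levels) for a in config.analytes}
    if len(counts) != 1:
        raise ValueError(
            "all analytes must share the same number of calibration levels"
        )
    (n,) = counts
    if n < 2:
        raise ValueError("need at least two calibration levels")
    return n


def validation_design_counts(
    config: StudyConfig, params: Optional[SimulationParams] = None
) -> Dict[str, int]:
    """Deterministic record counts of the simulated validation design."""
    n_levels = _check_uniform_levels(config)
    n_analytes = len(config.analytes)
    if params is not None:
        n_is = len(set(params.is_for_analyte.values()))
    else:
        n_is = len(
            {a.assigned_is or (a.candidate_is[0] if a.candidate_is else f"{a.name}-IS")
             for a in config.analytes}
        )
    samples = (
        N_CAL_RUNS * n_levels  # calibrators
        + N_CAL_RUNS  # blanks
        + N_CAL_RUNS  # zeros
        + 2  # carry-over pair
        + N_QC_RUNS * 2 * N_QC_REPS  # LQC + HQC
        + N_DILUTION_REPS
        + N_ME_LOTS * N_ME_REPS + N_ME_SOLVENT
        + len(STABILITY_TIMEPOINTS) * 2 * N_STABILITY_REPS
    )
    blanks_without_is = N_CAL_RUNS  # per-run blanks carry no IS
    return {
        "samples": samples,
        "analyte_records": samples * n_analytes,
        "is_records": (samples - blanks_without_is) * n_is,
        "total_records": samples * n_analytes + (samples - blanks_without_is) * n_is,
    }


class _Emitter:
    """Accumulates records, writing one analyte row per analyte and one IS
    row per distinct internal standard for each physical sample."""

    def __init__(self, config: StudyConfig, params: SimulationParams,
                 rng: np.random.Generator) -> None:
        self.config = config
        self.params = params
        self.rng = rng
        self.records: List[InjectionRecord] = []
        # pairing analyte for each IS: first analyte in config order using it
        self.pair_analyte: Dict[str, str] = {}
        for a in config.analytes:
            istd = params.is_for_analyte[a.name]
            self.pair_analyte.setdefault(istd, a.name)

    def emit(
        self,
        sample_id: str,
        role: Role,
        run_id: str,
        conc_of,  # callable analyte name -> true concentration
        nominal_of=None,  # callable or None
        lot: Optional[str] = None,
        dilution_factor: float = 1.0,
        timepoint: Optional[str] = None,
        include_is: bool = True,
        analyte_area_override=None,  # callable name -> area, bypasses model
        is_scale: float = 1.0,  # residual IS fraction (carry-over blanks)
    ) -> None:
        params, rng = self.params, self.rng
        is_areas: Dict[str, float] = {}
        for a in self.config.analytes:
            conc = conc_of(a.name)
            if analyte_area_override is not None:
                area = analyte_area_override(a.name)
                _, is_area = simulate_response(0.0, params, a.name, lot, rng)
            else:
                area, is_area = simulate_response(conc, params, a.name, lot, rng)
            istd = params.is_for_analyte[a.name]
            if self.pair_analyte[istd] == a.name:
                is_areas[istd] = is_area * is_scale
            self.records.append(
                InjectionRecord(
                    sample_id=sample_id,
                    role=role,
                    analyte=a.name,
                    area=area,
                    run_id=run_id,
                    nominal_conc=None if nominal_of is None else nominal_of(a.name),
                    dilution_factor=dilution_factor,
                    urine_lot=lot,
                    timepoint=timepoint,
                )
            )
        if include_is:
            # IS rows share the sample's role; nominal 0 marks "not quantitated"
            for istd, is_area in is_areas.items():
                self.records.append(
                    InjectionRecord(
                        sample_id=sample_id,
                        role=role,
                        analyte=istd,
                        area=is_area,
                        run_id=run_id,
                        nominal_conc=0.0 if nominal_of is not None or role in
                        (Role.QC_LOW, Role.QC_HIGH, Role.DILUTION_QC,
                         Role.STABILITY_QC, Role.CALIBRATOR) else None,
                        dilution_factor=dilution_factor,
                        urine_lot=lot,
                        timepoint=timepoint,
                    )
                )


def simulate_validation_suite(
    params: SimulationParams, config: StudyConfig
) -> SimulatedStudy:
    """Generate the full validation dataset for a study configuration."""
    n_levels = _check_uniform_levels(config)
    rng = np.random.default_rng(params.seed)
    em = _Emitter(config, params, rng)
    level_of = {a.name: a.calibration_levels for a in config.analytes}
    uloq = {a.name: a.uloq for a in config.analytes}

    # four replicate calibration curves + per-run blank and zero
    for run in range(1, N_CAL_RUNS + 1):
        run_id = f"run{run}"
        for i in range(n_levels):
            em.emit(
                f"cal_{run_id}_L{i + 1:02d}",
                Role.CALIBRATOR,
                run_id,
                conc_of=lambda name, i=i: level_of[name][i],
                nominal_of=lambda name, i=i: level_of[name][i],
                lot=POOL_LOT,
            )
        em.emit(
            f"blank_{run_id}", Role.BLANK, run_id,
            conc_of=lambda name: 0.0, lot=POOL_LOT, include_is=False,
        )
        em.emit(
            f"zero_{run_id}", Role.ZERO, run_id,
            conc_of=lambda name: 0.0, lot=POOL_LOT,
        )

    # carry-over pair: ULOQ injection followed by a solvent blank
    em.emit(
        "carryover_uloq", Role.CALIBRATOR, "run1",
        conc_of=lambda name: uloq[name],
        nominal_of=lambda name: uloq[name],
        lot=POOL_LOT,
    )
    co = params.carryover_fraction
    em.emit(
        "carryover_blank", Role.BLANK, "run1",
        conc_of=lambda name: 0.0,
        analyte_area_override=lambda name: co
        * params.slope_per_analyte[name]
        * level_of[name][0]
        * _lot_factor(params, POOL_LOT, name),
        lot=POOL_LOT,
        is_scale=co,
    )

    # QC: 5 replicates per level per run over three runs
    for run in range(1, N_QC_RUNS + 1):
        run_id = f"run{run}"
        for level, role in (("low", Role.QC_LOW), ("high", Role.QC_HIGH)):
            for rep in range(1, N_QC_REPS + 1):
                em.emit(
                    f"qc_{level}_{run_id}_r{rep}", role, run_id,
                    conc_of=lambda name, level=level: config.analyte(name).qc_levels[level],
                    nominal_of=lambda name, level=level: config.analyte(name).qc_levels[level],
                    lot=POOL_LOT,
                )

    # dilution integrity: 8x ULOQ diluted eightfold before injection
    for rep in range(1, N_DILUTION_REPS + 1):
        em.emit(
            f"dilution_r{rep}", Role.DILUTION_QC, "run1",
            conc_of=lambda name: uloq[name],  # injected (post-dilution) level
            nominal_of=lambda name: DILUTION_FACTOR * uloq[name],
            lot=POOL_LOT,
            dilution_factor=DILUTION_FACTOR,
        )

    # matrix effect: post-extraction spikes in each lot + solvent replicates
    me_lots = [lot for lot in params.lot_sg if lot != POOL_LOT]
    spike = {a.name: a.qc_levels.get("high", a.uloq / 4.0) for a in config.analytes}
    for lot in me_lots:
        for rep in range(1, N_ME_REPS + 1):
            em.emit(
                f"me_{lot}_r{rep}", Role.POST_EXTRACTION_SPIKE, "me_run",
                conc_of=lambda name: spike[name],
                nominal_of=lambda name: spike[name],
                lot=lot,
            )
    for rep in range(1, N_ME_SOLVENT + 1):
        em.emit(
            f"me_solvent_r{rep}", Role.SOLVENT, "me_run",
            conc_of=lambda name: spike[name],
            nominal_of=lambda name: spike[name],
            lot=None,
        )

    # stability: t0 and three storage conditions, two levels, triplicates
    for tp in STABILITY_TIMEPOINTS:
        for level in ("low", "high"):
            for rep in range(1, N_STABILITY_REPS + 1):
                em.emit(
                    f"stab_{tp}_{level}_r{rep}", Role.STABILITY_QC, "run1",
                    conc_of=lambda name, tp=tp, level=level: (
                        config.analyte(name).qc_levels[level]
                        * params.stability_loss.get((name, tp), 1.0)
                    ),
                    nominal_of=lambda name, level=level: config.analyte(name).qc_levels[level],
                    lot=POOL_LOT,
                    timepoint=tp,
                )

    lot_truth = {
        lot: dict(params.lot_matrix_factor[lot]) for lot in params.lot_matrix_factor
    }
    return SimulatedStudy(records=em.records, lot_truth=lot_truth)


# -- application cohort -----------------------------------------------------


def simulate_application_cohort(
    params: SimulationParams, n: Optional[int] = None, config: Optional[StudyConfig] = None
) -> SimulatedStudy:
    """Generate ``n`` study samples with per-sample SG, per-sample matrix
    factors, and left-censored true concentrations; the truth map is kept."""
    if n is None:
        n = params.cohort_size
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    rng = np.random.default_rng(params.seed + 1 if params.seed < 2**31 - 1 else 0)
    analytes = list(params.slope_per_analyte)
    if config is not None:
        analytes = [a.name for a in config.analytes]
    truth: Dict[Tuple[str, str], float] = {}
    sg_by_sample: Dict[str, float] = {}
    lot_truth: Dict[str, Dict[str, float]] = {}
    records: List[InjectionRecord] = []
    lo, hi = params.sg_range
    for i in range(1, n + 1):
        sample_id = f"s{i:03d}"
        sg = float(rng.uniform(lo, hi))
        sg_by_sample[sample_id] = sg
        lot = f"cohort_{sample_id}"
        params.lot_matrix_factor[lot] = params.draw_lot_factors(sg, rng)
        params.lot_sg[lot] = sg
        lot_truth[lot] = dict(params.lot_matrix_factor[lot])
        is_areas: Dict[str, float] = {}
        pair: Dict[str, str] = {}
        for name in analytes:
            pair.setdefault(params.is_for_analyte[name], name)
        for name in analytes:
            spec = params.true_conc_distribution.get(name)
            if spec is None:
                spec = TrueConcSpec(median=1.0, gsd=3.0, exposed_fraction=0.75)
            exposed = rng.random() < spec.exposed_fraction
            conc = (
                float(spec.median * np.exp(rng.normal(0.0, math.log(spec.gsd))))
                if exposed and spec.median > 0
                else 0.0
            )
            truth[(sample_id, name)] = conc
            area, is_area = simulate_response(conc, params, name, lot, rng)
            istd = params.is_for_analyte[name]
            if pair[istd] == name:
                is_areas[istd] = is_area
            records.append(
                InjectionRecord(
                    sample_id=sample_id,
                    role=Role.STUDY,
                    analyte=name,
                    area=area,
                    run_id="study",
                    urine_lot=lot,
                )
            )
        for istd, is_area in is_areas.items():
            records.append(
                InjectionRecord(
                    sample_id=sample_id,
                    role=Role.STUDY,
                    analyte=istd,
                    area=is_area,
                    run_id="study",
                    urine_lot=lot,
                )
            )
    return SimulatedStudy(
        records=records, truth=truth, lot_truth=lot_truth, sg_by_sample=sg_by_sample
    )
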