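"""Study configuration: analytes, internal-standard candidates, calibration
and QC levels, acceptance thresholds, and cohort-summary policies.

Configuration files are YAML. Defaults follow common bioanalytical practice:
back-calculated calibrator accuracy within +/-20 % at the lowest level and
+/-15 % elsewhere, at least 75 % of replicates passing per level, and a
minimum weighted R^2 of 0.9900.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Union

import yaml


class ConfigError(ValueError):
    """Invalid or inconsistent study configuration."""


@dataclass
class AnalyteConfig:
    name: str
    candidate_is: List[str] = field(default_factory=list)
    assigned_is: Optional[str] = None
    calibration_levels: List[float] = field(default_factory=list)
    qc_levels: Dict[str, float] = field(default_factory=dict)  # {"low": .., "high": ..}
    lloq_acceptance_pct: float = 20.0
    level_acceptance_pct: float = 15.0
    min_level_pass_fraction: float = 0.75
    r2_min: float = 0.9900

    def __post_init__(self) -> None:
        levels = list(self.calibration_levels)
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise ConfigError(
                f"calibration_levels for {self.name!r} must be strictly increasing"
            )
        for attr in ("lloq_acceptance_pct", "level_acceptance_pct"):
            v = getattr(self, attr)
            if not (0 < v <= 100):
                raise ConfigError(f"{attr} for {self.name!r} must lie in (0, 100]")
        if not (0 < self.min_level_pass_fraction <= 1):
            raise ConfigError(
                f"min_level_pass_fraction for {self.name!r} must lie in (0, 1]"
            )
        if self.assigned_is is not None and self.candidate_is:
            if self.assigned_is not in self.candidate_is:
                raise ConfigError(
                    f"assigned internal standard {self.assigned_is!r} for "
                    f"{self.name!r} is not among its candidates {self.candidate_is!r}"
                )

    @property
    def uloq(self) -> float:
        if not self.calibration_levels:
            raise ConfigError(f"{self.name!r} has no calibration levels")
        return self.calibration_levels[-1]


#: Policies for substituting non-detects when computing a geometric mean.
NONDETECT_POLICIES = ("zero", "half_lloq", "lloq_over_sqrt2")


@dataclass
class StudyConfig:
    analytes: List[AnalyteConfig]
    sg_reference: Union[float, str] = "cohort_median"
    nondetect_substitution: str = "half_lloq"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.analytes:
            raise ConfigError("analyte list must not be empty")
        if isinstance(self.sg_reference, (int, float)):
            if self.sg_reference <= 1:
                raise ConfigError("numeric sg_reference must exceed 1")
        elif self.sg_reference != "cohort_median":
            raise ConfigError(
                f"sg_reference must be numeric or 'cohort_median', got "
                f"{self.sg_reference!r}"
            )
        if self.nondetect_substitution not in NONDETECT_POLICIES:
            raise ConfigError(
                f"nondetect_substitution must be one of {NONDETECT_POLICIES}"
            )
        names = {a.name for a in self.analytes}
        all_is = set()
        for a in self.analytes:
            all_is.update(a.candidate_is)
            if a.assigned_is is not None:
                all_is.add(a.assigned_is)
        clash = names & all_is
        if clash:
            raise ConfigError(
                f"names used both as analyte and internal standard: {sorted(clash)}"
            )

    def analyte(self, name: str) -> AnalyteConfig:
        for a in self.analytes:
            if a.name == name:
                return a
        raise ConfigError(f"unknown analyte {name!r}")

    @property
    def internal_standards(self) -> List[str]:
        seen: List[str] = []
        for a in self.analytes:
            for cand in a.candidate_is:
                if cand not in seen:
                    seen.append(cand)
        return seen


def _analyte_from_mapping(m: dict) -> AnalyteConfig:
    known = {
        "name", "candidate_is", "assigned_is", "calibration_levels", "qc_levels",
        "lloq_acceptance_pct", "level_acceptance_pct", "min_level_pass_fraction",
        "r2_min",
    }
    unknown = set(m) - known
    if unknown:
        raise ConfigError(f"unknown analyte config keys: {sorted(unknown)}")
    if "name" not in m:
        raise ConfigError("analyte entry lacks a name")
    qc = {str(k): float(v) for k, v in (m.get("qc_levels") or {}).items()}
    for k in qc:
        if k not in ("low", "high"):
            raise ConfigError(f"qc_levels keys must be 'low'/'high', got {k!r}")
    return AnalyteConfig(
        name=str(m["name"]),
        candidate_is=[str(x) for x in m.get("candidate_is", [])],
        assigned_is=(None if m.get("assigned_is") is None else str(m["assigned_is"])),
        calibration_levels=[float(x) for x in m.get("calibration_levels", [])],
        qc_levels=qc,
        lloq_acceptance_pct=float(m.get("lloq_acceptance_pct", 20.0)),
        level_acceptance_pct=float(m.get("level_acceptance_pct", 15.0)),
        min_level_pass_fraction=float(m.get("min_level_pass_fraction", 0.75)),
        r2_min=float(m.get("r2_min", 0.9900)),
    )


def config_from_mapping(data: dict) -> StudyConfig:
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    analytes = [_analyte_from_mapping(a) for a in data.get("analytes", [])]
    sg_ref = data.get("sg_reference", "cohort_median")
    if isinstance(sg_ref, str) and sg_ref != "cohort_median":
        try:
            sg_ref = float(sg_ref)
        except ValueError:
            pass
    return StudyConfig(
        analytes=analytes,
        sg_reference=sg_ref,
        nondetect_substitution=str(data.get("nondetect_substitution", "half_lloq")),
        seed=int(data.get("seed", 0)),
    )


def read_config(path) -> StudyConfig:
    """Read and validate a YAML study configuration."""
    with open(path, "r") as fh:
        data = yaml.safe_load(fh)
    return config_from_mapping(data or {})


def write_config(config: StudyConfig, path) -> None:
    data = {
        "analytes": [
            {
                "name": a.name,
                "candidate_is": a.candidate_is,
                "assigned_is": a.assigned_is,
                "calibration_levels": a.calibration_levels,
                "qc_levels": a.qc_levels,
                "lloq_acceptance_pct": a.lloq_acceptance_pct,
                "level_acceptance_pct": a.level_acceptance_pct,
                "min_level_pass_fraction": a.min_level_pass_fraction,
                "r2_min": a.r2_min,
            }
            for a in config.analytes
        ],
        "sg_reference": config.sg_reference,
        "nondetect_substitution": config.nondetect_substitution,
        "seed": config.seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
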