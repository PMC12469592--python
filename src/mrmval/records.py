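"""Injection-level data model.

One :class:`InjectionRecord` is a single measured MRM peak area together with
the metadata needed to route it through the validation and quantitation
stages: its role in the run design, the analyte (or internal standard) it
belongs to, the run it was acquired in, and — where applicable — the nominal
spiked concentration, the dilution factor, the urine lot, and the stability
timepoint.

Internal-standard signals are ordinary records whose ``analyte`` field holds
the internal-standard name, mirroring how MRM exports list one transition per
row. Pairing of analyte and IS rows happens downstream via the study
configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class Role(str, Enum):
    """Role of an injection in the validation / study design."""

    SOLVENT = "solvent"
    BLANK = "blank"
    ZERO = "zero"
    CALIBRATOR = "calibrator"
    QC_LOW = "qc_low"
    QC_HIGH = "qc_high"
    DILUTION_QC = "dilution_qc"
    STABILITY_QC = "stability_qc"
    STUDY = "study"
    POST_EXTRACTION_SPIKE = "post_extraction_spike"


#: Roles that must carry a nominal concentration.
_NOMINAL_REQUIRED = frozenset(
    {Role.CALIBRATOR, Role.QC_LOW, Role.QC_HIGH, Role.DILUTION_QC, Role.STABILITY_QC}
)


class RecordValidationError(ValueError):
    """An injection record violates a structural invariant."""


@dataclass(frozen=True)
class InjectionRecord:
    sample_id: str
    role: Role
    analyte: str
    area: float
    run_id: str
    nominal_conc: Optional[float] = None
    dilution_factor: float = 1.0
    urine_lot: Optional[str] = None
    timepoint: Optional[str] = None
    # provenance for error messages; not part of equality semantics
    source_line: Optional[int] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.area < 0:
            raise RecordValidationError(
                f"negative peak area {self.area!r} for sample {self.sample_id!r}"
                + (f" (line {self.source_line})" if self.source_line else "")
            )
        if self.dilution_factor < 1:
            raise RecordValidationError(
                f"dilution_factor must be >= 1, got {self.dilution_factor!r}"
            )
        if self.role in _NOMINAL_REQUIRED and self.nominal_conc is None:
            raise RecordValidationError(
                f"role {self.role.value!r} requires nominal_conc"
                f" (sample {self.sample_id!r}"
                + (f", line {self.source_line})" if self.source_line else ")")
            )
        if self.nominal_conc is not None and self.nominal_conc < 0:
            raise RecordValidationError(
                f"nominal_conc must be nonnegative, got {self.nominal_conc!r}"
            )
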