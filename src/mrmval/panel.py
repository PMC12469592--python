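"""Reference urinalysis panel: the 16-analyte SPE-LC-MS/MS assay this
package was built around.

Each entry records the validated assay conditions for one analyte: the
quantifiable range (LLOQ-ULOQ, pg/mL), the response-ratio regression
coefficients, the curve weighting, the assigned isotope-labeled (or
surrogate) internal standard, and the low/high QC nominal levels. These are
configuration data for the pipeline and the defaults of the synthetic-data
generator; the wet-lab conditions behind them (SPE protocol, MRM transitions)
are out of scope here.
"""

from __future__ import annotations

from typing import Dict, List

from .config import AnalyteConfig, StudyConfig

#: name -> (lloq, uloq, slope, intercept, weighting, internal standard,
#:          lqc nominal, hqc nominal)
PANEL: Dict[str, tuple] = {
    "IMI-OH": (1000.0, 200000.0, 0.0853, 0.0065, "1/x", "IMI-D4", 3000.0, 50000.0),
    "IMI": (100.0, 20000.0, 1.5555, 0.0017, "1/x", "IMI-D4", 300.0, 5000.0),
    "BPS": (50.0, 5000.0, 0.2526, 0.0056, "1/x", "BPS-D8", 75.0, 1250.0),
    "BOS-OH": (1000.0, 200000.0, 0.0138, 0.0020, "1/x", "BPS-D8", 3000.0, 50000.0),
    "4OH3PBA": (2000.0, 200000.0, 0.0185, -0.0018, "1/x", "FIP-dtfms-13C2-15N2", 3000.0, 50000.0),
    "DPhP": (100.0, 5000.0, 0.0668, 0.0238, "1/x", "FIP-13C4", 150.0, 2500.0),
    "DEET": (10.0, 2000.0, 0.8049, 0.0604, "1/x", "FIP-13C4", 30.0, 500.0),
    "FIP-dtfms": (200.0, 40000.0, 0.8586, -0.0021, "1/x", "FIP-dtfms-13C2-15N2", 600.0, 10000.0),
    "FIP-amide": (50.0, 5000.0, 0.2650, -0.0004, "1/x", "FIP-dtfms-13C2-15N2", 150.0, 2500.0),
    "TEB-OH": (100.0, 20000.0, 0.0499, 0.0096, "1/x", "FIP-13C4", 300.0, 5000.0),
    "4F3PBA": (100.0, 10000.0, 3.8030, 0.0050, "1/x2", "3PBA-13C4", 150.0, 2500.0),
    "FIP-desulfinyl": (5.0, 1000.0, 0.9155, 0.0027, "1/x", "FIP-13C4", 15.0, 250.0),
    "FIP": (1.0, 200.0, 1.2291, 0.0013, "1/x", "FIP-13C4", 3.0, 50.0),
    "FIP-sulfide": (1.0, 200.0, 0.8579, 0.0007, "1/x", "FIP-13C4", 3.0, 50.0),
    "FIP-sulfone": (0.5, 100.0, 1.3612, 0.0053, "1/x", "FIP-13C4", 1.5, 25.0),
    "CPhCA": (500.0, 100000.0, 0.0012, 0.0015, "1/x", "FIP-13C4", 1500.0, 25000.0),
}

#: Specific gravities of the seven urine lots used in matrix-effect testing.
MATRIX_LOT_SGS: List[float] = [1.006, 1.010, 1.011, 1.017, 1.026, 1.028, 1.031]


def _levels(lloq: float, uloq: float, n: int = 10) -> List[float]:
    """Ten log-spaced calibration levels from LLOQ to ULOQ."""
    import numpy as np

    return [float(x) for x in np.geomspace(lloq, uloq, n)]


def panel_study_config(names=None, seed: int = 0) -> StudyConfig:
    """Study configuration for the reference panel (optionally a subset)."""
    selected = list(PANEL) if names is None else list(names)
    analytes = []
    for name in selected:
        lloq, uloq, _, _, _, istd, lqc, hqc = PANEL[name]
        analytes.append(
            AnalyteConfig(
                name=name,
                candidate_is=[istd],
                assigned_is=istd,
                calibration_levels=_levels(lloq, uloq),
                qc_levels={"low": lqc, "high": hqc},
            )
        )
    return StudyConfig(analytes=analytes, seed=seed)
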