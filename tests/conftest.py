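import numpy as np
import pytest
from hypothesis import settings

from mrmval.config import AnalyteConfig, StudyConfig

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


def make_study_config(n_analytes: int = 2, n_levels: int = 10) -> StudyConfig:
    """Small study configuration with a dedicated internal standard per
    analyte (so IS correction can be exact when the simulated correlation
    is 1)."""
    analytes = []
    for i in range(n_analytes):
        name = f"A{i + 1}"
        lloq, uloq = 10.0 * (i + 1), 10000.0 * (i + 1)
        analytes.append(
            AnalyteConfig(
                name=name,
                candidate_is=[f"{name}-IS"],
                assigned_is=f"{name}-IS",
                calibration_levels=[float(x) for x in np.geomspace(lloq, uloq, n_levels)],
                qc_levels={"low": 3.0 * lloq, "high": uloq / 4.0},
            )
        )
    return StudyConfig(analytes=analytes)


@pytest.fixture
def small_config() -> StudyConfig:
    return make_study_config(2)


@pytest.fixture
def single_analyte_config() -> StudyConfig:
    return make_study_config(1)
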