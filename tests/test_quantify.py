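"""Quantitation, censoring, SG adjustment, and cohort summaries."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mrmval.calibration import CalibrationModel
from mrmval.config import StudyConfig
from mrmval.quantify import (
    ABOVE_ULOQ,
    Censor,
    MissingDataError,
    QuantResult,
    apply_sg_adjustment,
    censored_percentiles,
    detection_rate,
    geometric_mean,
    quantify_sample,
    sg_adjust,
    summarize_cohort,
)
from mrmval.records import InjectionRecord, Role
from mrmval.rounding import round_half_up
from tests.conftest import make_study_config


def model(lloq=10.0, uloq=100.0):
    return CalibrationModel(slope=1.0, intercept=0.0, weighting="none",
                            r_squared=1.0, lloq=lloq, uloq=uloq)


def study_record(dilution=1.0, sample="s1"):
    return InjectionRecord(sample, Role.STUDY, "A", 1.0, "study",
                           dilution_factor=dilution)


def result(value, censor=Censor.NONE, lloq=1.0, uloq=1000.0, sample="s1"):
    return QuantResult(sample_id=sample, analyte="A", conc_raw=value,
                       censor=censor, lloq=lloq, uloq=uloq)


def make_results(values, lloq=1.0, uloq=1000.0):
    """values: floats, or "ND" (non-detect), or ">" (above ULOQ)."""
    out = []
    for i, v in enumerate(values):
        if v == "ND":
            out.append(result(0.0, Censor.BELOW_LLOQ, lloq, uloq, f"s{i}"))
        elif v == ">":
            out.append(result(uloq * 2, Censor.ABOVE_ULOQ, lloq, uloq, f"s{i}"))
        else:
            out.append(result(float(v), Censor.NONE, lloq, uloq, f"s{i}"))
    return out


class TestQuantifySample:
    def test_boundary_values_not_censored(self):
        m = model()
        assert quantify_sample(study_record(), m, 10.0).censor is Censor.NONE
        assert quantify_sample(study_record(), m, 100.0).censor is Censor.NONE

    def test_below_lloq_censored(self):
        r = quantify_sample(study_record(), model(), 9.99)
        assert r.censor is Censor.BELOW_LLOQ
        assert r.conc_raw == pytest.approx(9.99)  # numeric value preserved

    def test_above_uloq_censored(self):
        assert quantify_sample(study_record(), model(), 101.0).censor is Censor.ABOVE_ULOQ

    def test_dilution_extends_upper_range(self):
        # an 8x-diluted sample reading at the ULOQ reports 8x ULOQ, in range
        r = quantify_sample(study_record(dilution=8.0), model(), 100.0)
        assert r.conc_raw == pytest.approx(800.0)
        assert r.censor is Censor.NONE

    def test_model_without_range_rejected(self):
        m = CalibrationModel(slope=1.0, intercept=0.0, weighting="none", r_squared=1.0)
        with pytest.raises(MissingDataError):
            quantify_sample(study_record(), m, 5.0)


class TestSgAdjust:
    def test_reference_equals_sample_is_identity(self):
        assert sg_adjust(123.4, 1.02, 1.02) == pytest.approx(123.4)

    def test_exact_ratio(self):
        assert sg_adjust(100.0, 1.012, 1.024) == pytest.approx(200.0)

    def test_sg_of_one_rejected(self):
        with pytest.raises(ValueError):
            sg_adjust(100.0, 1.0, 1.02)

    def test_cohort_median_reference(self):
        results = [result(10.0, sample="a"), result(20.0, sample="b"),
                   result(30.0, sample="c")]
        ref = apply_sg_adjustment(results, {"a": 1.01, "b": 1.02, "c": 1.03})
        assert ref == pytest.approx(1.02)
        assert results[0].conc_sg == pytest.approx(20.0)  # (0.02/0.01) * 10
        assert results[1].conc_sg == pytest.approx(20.0)

    def test_missing_sg_lists_samples(self):
        with pytest.raises(MissingDataError, match="s1"):
            apply_sg_adjustment([result(1.0)], {})


class TestDetectionRate:
    def test_half_detected(self):
        assert detection_rate(make_results(["ND", "ND", 5, 7])) == pytest.approx(50.0)

    def test_all_detected(self):
        assert detection_rate(make_results([1, 2, 3])) == pytest.approx(100.0)

    def test_reporting_rounding_of_20_of_28(self):
        rate = detection_rate(make_results([5] * 20 + ["ND"] * 8))
        assert rate == pytest.approx(100 * 20 / 28)
        assert round_half_up(rate) == 71

    def test_above_uloq_counts_as_detected(self):
        assert detection_rate(make_results([">", "ND"])) == pytest.approx(50.0)


class TestCensoredPercentiles:
    def test_median_at_exactly_half_detection(self):
        # mean of zero and the first quantified result
        (p50,) = censored_percentiles(make_results(["ND", "ND", 5, 7]), [50])
        assert p50 == pytest.approx(2.5)

    def test_all_nondetect_gives_zero(self):
        vals = censored_percentiles(make_results(["ND"] * 4), [25, 50, 95])
        assert vals == [0.0, 0.0, 0.0]

    def test_high_percentile_propagates_censored_high(self):
        results = make_results([1, 2, 3, ">"])
        (p95,) = censored_percentiles(results, [95])
        assert p95 == ABOVE_ULOQ

    @given(st.lists(
        st.one_of(st.floats(0.1, 1e4), st.just("ND"), st.just(">")),
        min_size=1, max_size=30,
    ))
    def test_nondecreasing_in_level(self, values):
        results = make_results(values)
        out = censored_percentiles(results, [5, 25, 50, 75, 95])
        numeric = [math.inf if v == ABOVE_ULOQ else v for v in out]
        assert numeric == sorted(numeric)


class TestGeometricMean:
    def test_constant_values(self):
        assert geometric_mean(make_results([7, 7, 7])) == pytest.approx(7.0)

    def test_exact_two_point(self):
        assert geometric_mean(make_results([1, 100])) == pytest.approx(10.0)

    def test_zero_policy_suppresses_gm_with_nondetects(self):
        assert geometric_mean(make_results(["ND", 5]), "zero") is None

    def test_half_lloq_substitution(self):
        results = make_results(["ND", 40], lloq=10.0)
        assert geometric_mean(results, "half_lloq") == pytest.approx(
            math.sqrt(5.0 * 40.0)
        )

    def test_lloq_over_sqrt2_substitution(self):
        results = make_results(["ND"], lloq=10.0)
        assert geometric_mean(results, "lloq_over_sqrt2") == pytest.approx(
            10.0 / math.sqrt(2)
        )

    def test_censored_high_contributes_uloq(self):
        results = make_results([">"], uloq=500.0)
        assert geometric_mean(results) == pytest.approx(500.0)


class TestSummarizeCohort:
    def make_config(self):
        return make_study_config(1)

    def test_no_detection_suppresses_all_statistics(self):
        s = summarize_cohort(make_results(["ND"] * 10), self.make_config())
        assert s.detection_rate == 0.0
        assert s.gm is None and s.p50 is None and s.p95 is None and s.max is None

    def test_quartile_in_nondetect_mass_reported_absent(self):
        # 68 % detection but P25 sits inside the non-detect region
        values = ["ND"] * 9 + list(range(1, 20))
        s = summarize_cohort(make_results(values), self.make_config())
        assert s.p25 is None
        assert s.p50 is not None

    def test_max_shown_at_low_detection(self):
        values = ["ND"] * 27 + [101.0]
        s = summarize_cohort(make_results(values), self.make_config())
        assert s.gm is None and s.p95 is None
        assert s.max == pytest.approx(101.0)

    def test_detection_rate_invariant_under_adjustment(self):
        results = make_results(["ND", 5, 7, ">"])
        sg = {r.sample_id: 1.01 + 0.002 * i for i, r in enumerate(results)}
        raw = summarize_cohort(results, self.make_config(), adjusted=False)
        apply_sg_adjustment(results, sg)
        adj = summarize_cohort(results, self.make_config(), adjusted=True)
        assert raw.detection_rate == adj.detection_rate

    def test_sg_adjustment_preserves_within_sample_order(self):
        # the SG factor is one positive scalar per sample
        results = make_results([5, 7])
        apply_sg_adjustment(results, {"s0": 1.01, "s1": 1.01}, 1.03)
        assert results[0].conc_sg < results[1].conc_sg
        assert results[0].conc_sg == pytest.approx(15.0)


class TestParameterRecovery:
    def _cohort(self, injection_cv, n):
        from mrmval.pipeline import fit_study_calibrations, quantify_study
        from mrmval.simulate import (
            SimulationParams,
            TrueConcSpec,
            simulate_application_cohort,
            simulate_validation_suite,
        )

        config = make_study_config(1)
        params = SimulationParams.from_config(
            config, seed=9, injection_cv=injection_cv, is_correlation=1.0
        )
        # fully exposed cohort well inside the quantifiable range
        a = config.analytes[0]
        params.true_conc_distribution["A1"] = TrueConcSpec(
            median=30 * a.calibration_levels[0], gsd=2.0, exposed_fraction=1.0
        )
        suite = simulate_validation_suite(params, config)
        cohort = simulate_application_cohort(params, n, config)
        assessed, _ = fit_study_calibrations(suite.records, config)
        results = quantify_study(cohort.records, assessed, config)["A1"]
        truth = [cohort.truth[(r.sample_id, "A1")] for r in results]
        return results, truth

    def test_noise_free_gm_equals_truth(self):
        results, truth = self._cohort(injection_cv=0.0, n=50)
        est = [r.conc_raw for r in results if r.censor is Censor.NONE]
        tru = [t for r, t in zip(results, truth) if r.censor is Censor.NONE]
        gm_est = math.exp(np.mean(np.log(est)))
        gm_tru = math.exp(np.mean(np.log(tru)))
        assert gm_est == pytest.approx(gm_tru, rel=1e-9)

    def test_gm_and_median_recovered_at_five_percent_noise(self):
        results, truth = self._cohort(injection_cv=0.05, n=500)
        est = np.array([r.conc_raw for r in results])
        tru = np.array(truth)
        gm_est = math.exp(np.mean(np.log(est)))
        gm_tru = math.exp(np.mean(np.log(tru)))
        assert gm_est == pytest.approx(gm_tru, rel=0.03)
        assert np.median(est) == pytest.approx(np.median(tru), rel=0.05)
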