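"""QC accuracy/precision, run acceptance, interference limits, dilution
integrity, stability, and recovery comparisons."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from mrmval.calibration import CalibrationModel, fit_weighted_ls, CalibrationPoint
from mrmval.records import InjectionRecord, Role
from mrmval.validation import (
    DesignError,
    accuracy_percent,
    assess_qc_batch,
    blank_interference_check,
    compare_recovery_ttest,
    dilution_integrity_assess,
    recovery_percent,
    run_acceptance,
    stability_assess,
)
from tests.conftest import make_study_config


def identity_model(lloq=None, uloq=None):
    return CalibrationModel(slope=1.0, intercept=0.0, weighting="none",
                            r_squared=1.0, lloq=lloq, uloq=uloq)


class TestAccuracyPercent:
    def test_examples(self):
        assert accuracy_percent([97.0], 100.0) == pytest.approx(97.0)
        assert accuracy_percent([50.0, 50.0, 50.0], 50.0) == pytest.approx(100.0)

    def test_nonpositive_nominal_rejected(self):
        with pytest.raises(ValueError):
            accuracy_percent([1.0], 0.0)


class TestRunAcceptance:
    @pytest.mark.parametrize("accs,expected", [
        ([100.0, 100.0, 100.0, 100.0], True),
        ([84.0, 100.0, 100.0, 100.0], True),   # 3 of 4 inside
        ([84.0, 116.0, 100.0, 100.0], False),  # only 2 of 4 inside
        ([85.0, 115.0, 100.0, 100.0], True),   # boundary inclusive
    ])
    def test_three_of_four_rule(self, accs, expected):
        assert run_acceptance(accs) is expected

    def test_wrong_count_rejected(self):
        with pytest.raises(DesignError):
            run_acceptance([100.0, 100.0, 100.0])

    @given(
        st.lists(st.floats(50, 150), min_size=4, max_size=4),
        st.integers(0, 3),
        st.floats(1, 50),
    )
    def test_monotone_worsening_never_rescues(self, accs, idx, delta):
        """Pushing any single QC accuracy farther from 100 % can only keep
        or lose acceptance, never gain it."""
        before = run_acceptance(accs)
        worse = list(accs)
        worse[idx] += delta if worse[idx] >= 100 else -delta
        after = run_acceptance(worse)
        assert before or not after


class TestBlankInterference:
    @pytest.mark.parametrize("frac_a,frac_is,expected", [
        (0.10, 0.01, True),
        (0.25, 0.01, False),  # analyte rule
        (0.10, 0.06, False),  # IS rule
        (0.20, 0.05, True),   # boundaries inclusive
    ])
    def test_fraction_rules(self, frac_a, frac_is, expected):
        chk = blank_interference_check(
            blank_response=frac_a * 100.0, lloq_response=100.0,
            is_blank_response=frac_is * 1000.0, is_nominal_response=1000.0,
        )
        assert chk.passed is expected
        assert chk.analyte_fraction == pytest.approx(frac_a)
        assert chk.is_fraction == pytest.approx(frac_is)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            blank_interference_check(1.0, 0.0, 1.0, 1.0)


def qc_records(concs_by_run, level="low", nominal=30.0, analyte="A1"):
    role = Role.QC_LOW if level == "low" else Role.QC_HIGH
    recs = []
    for run, concs in concs_by_run.items():
        for i, conc in enumerate(concs):
            sid = f"qc_{level}_{run}_r{i}"
            recs.append(InjectionRecord(sid, role, analyte, conc, run,
                                        nominal_conc=nominal))
            recs.append(InjectionRecord(sid, role, f"{analyte}-IS", 1.0, run,
                                        nominal_conc=0.0))
    return recs


class TestAssessQCBatch:
    def setup_method(self):
        self.config = make_study_config(1).analytes[0]

    def test_perfect_qcs_pass(self):
        recs = qc_records({"run1": [30.0] * 5, "run2": [30.0] * 5, "run3": [30.0] * 5})
        models = {r: identity_model() for r in ("run1", "run2", "run3")}
        (qc,) = assess_qc_batch(recs, models, self.config)
        assert qc.intra_accuracy == pytest.approx(100.0)
        assert qc.inter_cv == pytest.approx(0.0)
        assert qc.n_intra == 5 and qc.n_inter == 15
        assert qc.passed

    def test_one_outlier_breaks_cv_rule(self):
        # 100/100/100/100/160 % of nominal: accuracy 112 %, CV ~ 24 %
        recs = qc_records({"run1": [30.0, 30.0, 30.0, 30.0, 48.0]})
        (qc,) = assess_qc_batch(recs, {"run1": identity_model()}, self.config)
        assert qc.intra_accuracy == pytest.approx(112.0)
        assert qc.intra_cv == pytest.approx(23.96, abs=0.01)
        assert not qc.passed

    def test_single_run_intra_equals_inter(self):
        rng = np.random.default_rng(3)
        recs = qc_records({"run1": list(30.0 + rng.normal(0, 2, 5))})
        (qc,) = assess_qc_batch(recs, {"run1": identity_model()}, self.config)
        assert qc.intra_accuracy == qc.inter_accuracy
        assert qc.intra_cv == qc.inter_cv

    def test_missing_run_model_rejected(self):
        recs = qc_records({"run1": [30.0] * 5})
        with pytest.raises(DesignError, match="run"):
            assess_qc_batch(recs, {}, self.config)

    def test_simulated_qc_pass_rate_at_default_noise(self):
        """At 5 % injection noise the QC batch should pass in at least 95 %
        of simulated studies."""
        from mrmval.pipeline import fit_study_calibrations
        from mrmval.simulate import SimulationParams, simulate_validation_suite

        config = make_study_config(1)
        a = config.analytes[0]
        passed = total = 0
        for seed in range(50):
            params = SimulationParams.from_config(config, seed=seed,
                                                  injection_cv=0.05)
            suite = simulate_validation_suite(params, config)
            _, per_run = fit_study_calibrations(suite.records, config)
            for qc in assess_qc_batch(suite.records, per_run[a.name], a):
                total += 1
                passed += qc.passed
        assert passed / total >= 0.95


class TestDilutionIntegrity:
    def setup_method(self):
        self.config = make_study_config(1).analytes[0]

    def dilution_records(self, diluted_concs, nominal=800.0, factor=8.0):
        recs = []
        for i, conc in enumerate(diluted_concs):
            sid = f"dil_r{i}"
            recs.append(InjectionRecord(sid, Role.DILUTION_QC, "A1", conc,
                                        "run1", nominal_conc=nominal,
                                        dilution_factor=factor))
            recs.append(InjectionRecord(sid, Role.DILUTION_QC, "A1-IS", 1.0,
                                        "run1", nominal_conc=0.0,
                                        dilution_factor=factor))
        return recs

    def test_perfect_responses_pass(self):
        model = identity_model(lloq=10.0, uloq=100.0)
        v = dilution_integrity_assess(self.dilution_records([100.0] * 5),
                                      model, self.config)
        assert v.accuracy == pytest.approx(100.0)
        assert v.cv == pytest.approx(0.0)
        assert v.in_curve and v.passed

    def test_dilution_factor_remultiplies(self):
        # measured diluted concentration 100 with factor 8 reports as 800
        model = identity_model(lloq=10.0, uloq=100.0)
        v = dilution_integrity_assess(self.dilution_records([100.0]),
                                      model, self.config)
        assert v.nominal == pytest.approx(800.0)
        assert v.accuracy == pytest.approx(100.0)
        assert v.dilution_factor == 8.0

    def test_out_of_curve_response_flagged(self):
        model = identity_model(lloq=10.0, uloq=50.0)  # 100 is far above range
        v = dilution_integrity_assess(self.dilution_records([100.0] * 5),
                                      model, self.config)
        assert not v.in_curve
        assert not v.passed


class TestStability:
    @pytest.mark.parametrize("later,expected_acc,stable", [
        ([41.0, 46.0, 51.0], 46.0, False),   # long-term degradation
        ([100.0, 100.0, 100.0], 100.0, True),
        ([84.0, 100.0, 116.0], 100.0, False),  # CV 16 % breaks precision
    ])
    def test_accuracy_and_precision_rules(self, later, expected_acc, stable):
        v = stability_assess([100.0] * 3, later, 100.0, "frozen_12m", "low", "A")
        assert v.accuracy == pytest.approx(expected_acc)
        assert v.stable is stable

    def test_too_few_replicates_rejected(self):
        with pytest.raises(DesignError):
            stability_assess([100.0] * 3, [100.0] * 2, 100.0, "frozen_30d")

    def test_missing_t0_rejected(self):
        with pytest.raises(DesignError):
            stability_assess([], [100.0] * 3, 100.0, "frozen_30d")


class TestRecovery:
    def test_recovery_percent_examples(self):
        assert recovery_percent([100.0, 100.0], 100.0) == pytest.approx(100.0)
        assert recovery_percent([81.0, 81.0, 81.0], 100.0) == pytest.approx(81.0)
        assert recovery_percent([0.0, 0.0], 100.0) == pytest.approx(0.0)

    def test_identical_groups_not_significant(self):
        cmp = compare_recovery_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert cmp.t_statistic == pytest.approx(0.0)
        assert cmp.p_value == pytest.approx(1.0)
        assert not cmp.significant

    def test_pooled_t_against_closed_form_oracle(self):
        a, b = [96.0, 100.0, 104.0], [80.0, 84.0, 88.0]
        cmp = compare_recovery_ttest(a, b)
        # independent closed form: pooled sample variance + t distribution
        sp2 = (np.var(a, ddof=1) * 2 + np.var(b, ddof=1) * 2) / 4
        t = (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        assert cmp.t_statistic == pytest.approx(t, rel=1e-12)
        assert cmp.t_statistic == pytest.approx(4.89898, abs=1e-5)
        assert cmp.p_value == pytest.approx(2 * stats.t.sf(t, 4), rel=1e-12)
        assert cmp.p_value == pytest.approx(0.00805, abs=1e-5)
        assert cmp.significant

    def test_significance_at_alpha(self):
        # a p-value of 0.0168 is significant at alpha = 0.05
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = list(rng.normal(100, 5, 3))
            b = list(rng.normal(90, 5, 3))
            cmp = compare_recovery_ttest(a, b, alpha=0.05)
            assert cmp.significant == (cmp.p_value < 0.05)

    def test_symmetric_under_group_swap(self):
        a, b = [96.0, 100.0, 104.0], [80.0, 84.0, 88.0]
        fwd = compare_recovery_ttest(a, b)
        rev = compare_recovery_ttest(b, a)
        assert fwd.t_statistic == pytest.approx(-rev.t_statistic)
        assert fwd.p_value == pytest.approx(rev.p_value)

    def test_degenerate_constant_groups(self):
        cmp = compare_recovery_ttest([5.0, 5.0], [5.0, 5.0])
        assert cmp.degenerate
        assert cmp.p_value == 1.0
        assert not cmp.significant

    def test_type_one_error_near_nominal(self):
        """Under the null (same normal distribution, n = 3 per arm) the
        empirical rejection rate at alpha = 0.05 stays within 3 binomial SEs
        of 0.05 over 10,000 simulated pairs."""
        rng = np.random.default_rng(123)
        n_sim = 10_000
        a = rng.normal(100, 5, (n_sim, 3))
        b = rng.normal(100, 5, (n_sim, 3))
        _, p = stats.ttest_ind(a, b, axis=1)
        rate = float(np.mean(p < 0.05))
        se = np.sqrt(0.05 * 0.95 / n_sim)
        assert abs(rate - 0.05) <= 3 * se
        # spot-check that the vectorized null matches compare_recovery_ttest
        cmp = compare_recovery_ttest(list(a[0]), list(b[0]))
        assert cmp.p_value == pytest.approx(float(p[0]), rel=1e-9)
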