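"""Individual rule evaluations: demographics, flags, HIL, ranges, QC, consistency."""

import datetime as dt

import pytest

import autoval as av
from autoval.engine import (
    evaluate_av_range,
    evaluate_consistency,
    evaluate_critical,
    evaluate_demographics,
    evaluate_flags,
    evaluate_hil,
    evaluate_qc,
)
from autoval.outcomes import Status

WHEN = dt.datetime(2025, 6, 1, 9, 0)


@pytest.fixture()
def glu(example_config):
    return example_config.tests["GLU"]


class TestDemographics:
    def test_adult_with_dob_and_sex_passes(self, make_record, glu):
        assert evaluate_demographics(make_record(), glu).status is Status.PASS

    def test_unknown_sex_holds(self, make_record, glu):
        p = av.PatientInfo(patient_id="p", date_of_birth=dt.date(1980, 1, 1),
                           sex=av.Sex.unknown)
        out = evaluate_demographics(make_record(patient=p), glu)
        assert (out.status, out.reason_code) == (Status.HOLD, "missing_sex")

    def test_missing_dob_holds(self, make_record, glu):
        p = av.PatientInfo(patient_id="p", sex=av.Sex.male)
        out = evaluate_demographics(make_record(patient=p), glu)
        assert (out.status, out.reason_code) == (Status.HOLD, "missing_age")

    def test_neonate_excluded_from_adult_age_groups(self, make_record, glu):
        p = av.PatientInfo(patient_id="p", sex=av.Sex.male,
                           date_of_birth=WHEN.date() - dt.timedelta(days=10))
        out = evaluate_demographics(make_record(patient=p), glu)
        assert (out.status, out.reason_code) == (Status.HOLD, "age_excluded")


class TestFlags:
    def test_no_flags_pass(self, make_record, glu):
        assert evaluate_flags(make_record(), glu).status is Status.PASS

    def test_blocking_flag_holds_and_is_listed(self, make_record, glu):
        out = evaluate_flags(make_record(flags=["SAMPLE_CLOT"]), glu)
        assert out.status is Status.HOLD
        assert "SAMPLE_CLOT" in out.detail

    def test_informational_flag_passes_but_is_logged(self, make_record, glu):
        out = evaluate_flags(make_record(flags=["INFO_ONLY"]), glu)
        assert out.status is Status.PASS
        assert "INFO_ONLY" in out.detail

    def test_excluded_analyzer_holds(self, make_record, glu):
        restricted = glu.model_copy(update={"analyzers_included": {"A1"}})
        out = evaluate_flags(make_record(analyzer="A2"), restricted)
        assert (out.status, out.reason_code) == (Status.HOLD, "analyzer_excluded")
        assert evaluate_flags(make_record(analyzer="A1"), restricted).status is Status.PASS


class TestHIL:
    def test_zero_index_passes(self, make_record, glu):
        assert evaluate_hil(make_record(), glu).status is Status.PASS

    def test_index_above_threshold_holds(self, make_record, glu):
        hil = av.HILIndices(hemolysis=glu.hil_thresholds["hemolysis"] + 1,
                            icterus=0.0, lipemia=0.0)
        out = evaluate_hil(make_record(hil=hil), glu)
        assert (out.status, out.reason_code) == (Status.HOLD, "hemolysis_exceeded")

    def test_index_exactly_at_threshold_passes(self, make_record, glu):
        hil = av.HILIndices(hemolysis=glu.hil_thresholds["hemolysis"],
                            icterus=0.0, lipemia=0.0)
        assert evaluate_hil(make_record(hil=hil), glu).status is Status.PASS

    def test_configured_but_unmeasured_index_holds(self, make_record, glu):
        out = evaluate_hil(make_record(hil=av.HILIndices()), glu)
        assert (out.status, out.reason_code) == (Status.HOLD, "hil_missing")

    def test_no_thresholds_configured_skips(self, make_record, glu):
        bare = glu.model_copy(update={"hil_thresholds": {}})
        assert evaluate_hil(make_record(), bare).status is Status.SKIP


class TestAVRange:
    # GLU AV range is [3.0, 11.0] mmol/L
    @pytest.mark.parametrize("value,status,reason", [
        (11.0, Status.PASS, ""),
        (3.0, Status.PASS, ""),
        (11.1, Status.HOLD, "above_av_range"),
        (2.9, Status.HOLD, "below_av_range"),
        (None, Status.HOLD, "missing_result"),
    ])
    def test_inclusive_boundaries(self, make_record, glu, value, status, reason):
        out = evaluate_av_range(make_record(value=value), glu)
        assert (out.status, out.reason_code) == (status, reason)


class TestCritical:
    # GLU critical limits are [2.5, 25.0]
    @pytest.mark.parametrize("value,held", [
        (5.5, False), (2.6, False), (24.9, False),
        (25.0, True), (2.5, True), (30.0, True), (1.0, True),
    ])
    def test_at_or_beyond_limit_is_critical(self, make_record, glu, value, held):
        out = evaluate_critical(make_record(value=value), glu)
        assert (out.status is Status.HOLD) == held

    def test_missing_value_skips_here(self, make_record, glu):
        assert evaluate_critical(make_record(value=None), glu).status is Status.SKIP

    def test_critical_dominates_av_range(self, make_record, example_config):
        # potassium: AV range [3, 6] but critical low 2.8 < high 6.2; a value
        # inside a hypothetical AV range yet at a critical limit must be HELD
        k = example_config.tests["K"]
        wide = k.model_copy(update={"av_range": av.Interval(low=2.0, high=7.0)})
        rec = make_record(value=6.2, test_code="K", unit="mmol/L")
        assert evaluate_av_range(rec, wide).status is Status.PASS
        assert evaluate_critical(rec, wide).status is Status.HOLD
        d = av.validate_record(rec, example_config.model_copy(
            update={"tests": {**example_config.tests, "K": wide}}))
        assert d.decision is av.Decision.HELD
        assert d.critical_alert


class TestConsistency:
    def _pair(self, make_record, num, den, nv, dv):
        return [
            make_record(value=nv, test_code=num, sample_id="SC"),
            make_record(value=dv, test_code=den, sample_id="SC"),
        ]

    @pytest.mark.parametrize("ast,alt,held", [
        (100, 100, False),   # ratio 1.0 inside [0.25, 4]
        (100, 25, False),    # ratio 4 at the band edge is inclusive-pass
        (125, 25, True),     # ratio 5 outside
        (25, 100, False),    # ratio 0.25 at the low edge
        (20, 100, True),     # ratio 0.2 below 0.25
    ])
    def test_ast_alt_band(self, make_record, example_config, ast, alt, held):
        rules = [r for r in example_config.consistency_rules if r.rule_id == "ast_alt"]
        sample = self._pair(make_record, "AST", "ALT", ast, alt)
        out = evaluate_consistency(sample, rules)
        for code in ("AST", "ALT"):
            statuses = [o.status for o in out[code]]
            assert (Status.HOLD in statuses) == held

    def test_violation_marks_both_results(self, make_record, example_config):
        rules = [r for r in example_config.consistency_rules if r.rule_id == "ast_alt"]
        sample = self._pair(make_record, "AST", "ALT", 500, 100)
        out = evaluate_consistency(sample, rules)
        assert all(out[c][0].status is Status.HOLD for c in ("AST", "ALT"))

    def test_conjugated_over_total_bilirubin_above_one_holds(
            self, make_record, example_config):
        rules = [r for r in example_config.consistency_rules
                 if r.rule_id == "conj_total_bili"]
        sample = self._pair(make_record, "DBIL", "TBIL", 60, 50)  # ratio 1.2
        out = evaluate_consistency(sample, rules)
        assert out["DBIL"][0].status is Status.HOLD
        assert out["TBIL"][0].status is Status.HOLD

    def test_missing_partner_skips(self, make_record, example_config):
        rules = [r for r in example_config.consistency_rules if r.rule_id == "ast_alt"]
        sample = [make_record(value=100, test_code="AST", sample_id="SC")]
        out = evaluate_consistency(sample, rules)
        assert out["AST"][0].status is Status.SKIP

    def test_zero_denominator_holds_with_ratio_undefined(
            self, make_record, example_config):
        rules = [r for r in example_config.consistency_rules if r.rule_id == "ast_alt"]
        sample = self._pair(make_record, "AST", "ALT", 100, 0)
        out = evaluate_consistency(sample, rules)
        assert out["AST"][0].reason_code == "ratio_undefined"
        assert out["ALT"][0].status is Status.HOLD


class TestQC:
    def _policy(self, in_control=True, hours_ago=1.0, max_age=24.0):
        return av.QCPolicy(test_code="GLU", in_control=in_control,
                           last_pass_time=WHEN - dt.timedelta(hours=hours_ago),
                           max_age_hours=max_age)

    def test_recent_pass_passes(self, glu):
        assert evaluate_qc(glu, self._policy(), WHEN).status is Status.PASS

    def test_out_of_control_holds(self, glu):
        out = evaluate_qc(glu, self._policy(in_control=False), WHEN)
        assert (out.status, out.reason_code) == (Status.HOLD, "qc_failed")

    def test_stale_pass_expires(self, glu):
        out = evaluate_qc(glu, self._policy(hours_ago=25.0), WHEN)
        assert (out.status, out.reason_code) == (Status.HOLD, "qc_expired")

    def test_no_policy_skips(self, glu):
        assert evaluate_qc(glu, None, WHEN).status is Status.SKIP
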