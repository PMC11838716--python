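"""Phase I/II verification: coverage, self-consistency, mutations, no release."""

import datetime as dt

import pytest

import autoval as av
from autoval.engine import evaluate_av_range, evaluate_critical, evaluate_flags
from autoval.outcomes import RuleId, RuleOutcome, Status
from autoval.verification import (
    SentinelChannel,
    VerificationReleaseError,
    export_table4,
    generate_phase1_cases,
    run_phase1,
    run_phase2,
)

WHEN = dt.datetime(2025, 6, 1, 9, 0)


@pytest.fixture(scope="module")
def glu_cases(example_config):
    return generate_phase1_cases(example_config.tests["GLU"], example_config)


class TestCaseGeneration:
    def test_av_boundary_cases_have_expected_labels(self, glu_cases):
        # AV range [3, 11]: at-limit YES (inclusive pass), epsilon outside NO
        by_desc = {c.description: c.expected for c in glu_cases}
        assert by_desc["value 3"] == "YES"
        assert by_desc["value 11"] == "YES"
        assert by_desc["value 2.9"] == "NO"
        assert by_desc["value 11.1"] == "NO"

    def test_absurd_age_and_sex_expected_no(self, glu_cases):
        labels = {c.description: c.expected for c in glu_cases}
        assert labels["age 130 y"] == "NO"
        assert labels["sex unknown"] == "NO"
        assert labels["date of birth missing"] == "NO"

    def test_informational_flag_expected_yes(self, glu_cases):
        case = next(c for c in glu_cases if "INFO_ONLY" in c.description)
        assert case.expected == "YES"

    def test_critical_at_limit_expected_no(self, glu_cases):
        at_cases = [c for c in glu_cases if c.rule_label.startswith("Result at critical")]
        assert at_cases and all(c.expected == "NO" for c in at_cases)

    def test_delta_window_case_expected_yes(self, glu_cases):
        case = next(c for c in glu_cases
                    if "out of delta check time interval" in c.rule_label)
        assert case.expected == "YES"

    def test_coverage_every_enabled_rule_has_yes_and_no_cases(
            self, example_config):
        """For each rule enabled on a test there is at least one expected-YES
        and one expected-NO case in its generated set."""
        rule_keys = {
            "gender": ("Patient gender",),
            "age": ("Patient age", "Age group"),
            "missing": ("Missing result",),
            "flags": ("Data alarms",),
            "hil": ("hemolysis index", "icterus index", "lipemia index"),
            "av": ("AV range", "limit of AV range"),
            "critical": ("critical",),
            "delta": ("delta check",),
            "consistency": ("additional rule",),
            "qc": ("IQC",),
        }
        for code, testdef in example_config.tests.items():
            cases = generate_phase1_cases(testdef, example_config)
            enabled = {"gender", "age", "missing", "av"}
            if testdef.flags_blocking:
                enabled.add("flags")
            if testdef.hil_thresholds:
                enabled.add("hil")
            if testdef.critical_limits.low is not None or \
                    testdef.critical_limits.high is not None:
                enabled.add("critical")
            if testdef.delta is not None:
                enabled.add("delta")
            if any(code in (r.numerator_test, r.denominator_test)
                   for r in example_config.consistency_rules):
                enabled.add("consistency")
            if code in example_config.qc_policies:
                enabled.add("qc")
            yes = {c.rule_label for c in cases if c.expected == "YES"}
            no = {c.rule_label for c in cases if c.expected == "NO"}
            assert any(c.expected == "YES" for c in cases)
            for key in enabled:
                touches_no = [l for l in no
                              if any(k in l for k in rule_keys[key])]
                assert touches_no or key in ("missing",) and any(
                    "Missing" in l for l in no), (code, key)
            # and the case list is non-trivial
            assert len(cases) >= 10


class TestPhase1Execution:
    def test_correct_engine_scores_100_percent_concordance(
            self, example_config):
        for code in example_config.tests:
            cases = generate_phase1_cases(example_config.tests[code], example_config)
            report = run_phase1(cases, example_config)
            assert report.percent_concordant == 100.0, (code, report.discordances)
            assert report.released_results == 0

    def test_empty_case_list(self, example_config):
        report = run_phase1([], example_config)
        assert report.n_cases == 0
        assert report.percent_concordant is None

    @pytest.mark.parametrize("name,mutant,touch", [
        # exclusive AV boundaries: at-limit cases flip
        ("av_exclusive",
         {"av_range": lambda r, t: (
             RuleOutcome(RuleId.av_range, Status.HOLD, "strict_bound", "mutant")
             if r.value is not None and (r.value <= t.av_range.low
                                         or r.value >= t.av_range.high)
             else evaluate_av_range(r, t))},
         "limit of AV range"),
        # flags rule ignores blocking flags entirely
        ("flags_ignored",
         {"flags": lambda r, t: RuleOutcome(RuleId.flags, Status.PASS, "", "mutant")},
         "Data alarms"),
        # HIL threshold applied off by a factor of two
        ("hil_doubled",
         {"hil": lambda r, t: _hil_doubled(r, t)},
         "index limits"),
        # demographics rule accepts unknown sex
        ("sex_ignored",
         {"demographics": lambda r, t: _demographics_sex_blind(r, t)},
         "gender"),
        # delta rule inverts its exceedance test
        ("delta_inverted",
         {"delta": lambda record, history, cfg, testdef: _delta_inverted(
             record, history, cfg, testdef)},
         "delta"),
    ])
    def test_each_single_rule_mutation_produces_discordance(
            self, example_config, name, mutant, touch):
        """>=5 deliberate single-rule mutations each yield >=1 discordance,
        localized to the mutated rule's cases."""
        total_disc = []
        for code in example_config.tests:
            cases = generate_phase1_cases(example_config.tests[code], example_config)
            report = run_phase1(cases, example_config, ruleset=mutant)
            total_disc.extend(report.discordances)
            assert report.released_results == 0
        assert total_disc, name
        assert any(touch.lower() in d.lower() for d in total_disc), (name, total_disc)

    def test_critical_boundary_mutation_flips_at_limit_cases(self):
        """With critical limits inside the AV range (critical dominates), an
        engine mutated to exclusive critical boundaries discords exactly at
        the at-critical-limit cases."""
        cfg = av.load_config({
            "schema_version": 1,
            "tests": [{
                "test_code": "T", "precision": 0,
                "av_range": {"low": 0, "high": 100},
                "critical_limits": {"low": 10, "high": 90},
            }],
        })
        cases = generate_phase1_cases(cfg.tests["T"], cfg)
        assert run_phase1(cases, cfg).percent_concordant == 100.0

        def critical_exclusive(r, t):
            if r.value is not None and r.value in (t.critical_limits.low,
                                                   t.critical_limits.high):
                return RuleOutcome(RuleId.critical, Status.PASS, "", "mutant")
            return evaluate_critical(r, t)

        report = run_phase1(cases, cfg, ruleset={"critical": critical_exclusive})
        flipped = {d.split(" ")[0] for d in report.discordances}
        at_limit = {c.case_id for c in cases
                    if c.rule_label.startswith("Result at critical")}
        assert flipped == at_limit
        assert len(flipped) == 2

    def test_sentinel_channel_raises_and_counts_on_release_attempt(
            self, make_record, example_config):
        sentinel = SentinelChannel()
        with pytest.raises(VerificationReleaseError):
            av.validate_record(make_record(), example_config,
                               release_channel=sentinel)
        assert sentinel.attempts == 1


def _hil_doubled(r, t):
    from autoval.engine import evaluate_hil
    doubled = t.model_copy(update={
        "hil_thresholds": {k: v * 2 for k, v in t.hil_thresholds.items()}})
    return evaluate_hil(r, doubled)


def _demographics_sex_blind(r, t):
    from autoval.engine import evaluate_demographics
    if r.patient.sex is av.Sex.unknown:
        fixed = r.patient.model_copy(update={"sex": av.Sex.female})
        return evaluate_demographics(r.model_copy(update={"patient": fixed}), t)
    return evaluate_demographics(r, t)


def _delta_inverted(record, history, cfg, testdef):
    from autoval.delta import evaluate_delta
    out, res = evaluate_delta(record, history, cfg, testdef)
    if res is None:
        return out, res
    if out.status is Status.HOLD:
        return RuleOutcome(RuleId.delta, Status.PASS, "", "mutant"), res
    return RuleOutcome(RuleId.delta, Status.HOLD, "mutant_hold", "mutant"), res


class TestPhase2:
    def _decision(self, make_record, example_config, value, sid):
        return av.validate_record(make_record(value=value, sample_id=sid),
                                  example_config)

    def test_all_held_all_rejected_is_full_concordance(
            self, make_record, example_config):
        ds = [self._decision(make_record, example_config, None, f"S{i}")
              for i in range(4)]
        labels = {f"S{i}/GLU": "reject" for i in range(4)}
        rep = run_phase2(ds, labels)
        assert rep.percent_autovalidated == 0.0
        assert rep.percent_concordant == 100.0
        assert rep.critical_discordances == []

    def test_ten_records_eight_auto_one_rejected(self, make_record, example_config):
        ds = [self._decision(make_record, example_config, 5.5, f"S{i}")
              for i in range(8)]
        ds += [self._decision(make_record, example_config, None, f"S{i}")
               for i in range(8, 10)]
        labels = {f"S{i}/GLU": "accept" for i in range(10)}
        labels["S3/GLU"] = "reject"  # autovalidated but manually rejected
        labels["S8/GLU"] = "reject"
        rep = run_phase2(ds, labels, target_percent=70.0)
        assert rep.percent_autovalidated == pytest.approx(80.0)
        assert rep.critical_discordances == ["S3/GLU"]
        assert rep.concordance_table["auto_yes/manual_reject"] == 1
        assert rep.target_met is True

    def test_held_but_accepted_is_benign_not_critical(
            self, make_record, example_config):
        ds = [self._decision(make_record, example_config, None, "S0")]
        rep = run_phase2(ds, {"S0/GLU": "accept"})
        assert rep.critical_discordances == []
        assert rep.discordances == ["S0/GLU"]
        assert rep.notes

    def test_unmatched_record_ids_error_lists_them(self, make_record, example_config):
        ds = [self._decision(make_record, example_config, 5.5, "S0")]
        with pytest.raises(ValueError, match="S0/GLU"):
            run_phase2(ds, {})


class TestExport:
    def test_phase1_report_has_one_row_per_case(self, glu_cases, example_config,
                                                tmp_path):
        run_phase1(glu_cases, example_config)
        out = export_table4(glu_cases, example_config, tmp_path / "b.csv",
                            which="B", test_code="GLU")
        text = out.read_text().splitlines()
        data_rows = [l for l in text if l.startswith(
            ("Patient", "Missing", "Data alarms", "Result", "Age group",
             "Multiple", "IQC"))]
        assert len([l for l in data_rows if not l.startswith("Result with expected")]) \
            == len(glu_cases)

    def test_b_layout_covers_hil_av_delta_age_rows(self, glu_cases,
                                                   example_config, tmp_path):
        out = export_table4(glu_cases, example_config, tmp_path / "b.csv", which="B")
        text = out.read_text()
        for needle in ("hemolysis index limits", "AV range", "delta check limits",
                       "Age group included in the AV", "Institution:"):
            assert needle in text

    def test_a_layout_restricts_to_cross_test_rows(self, glu_cases,
                                                   example_config, tmp_path):
        out = export_table4(glu_cases, example_config, tmp_path / "a.csv", which="A")
        text = out.read_text()
        assert "Patient gender absurd value" in text
        assert "hemolysis index limits" not in text

    def test_empty_report_is_header_only(self, example_config, tmp_path):
        out = export_table4([], example_config, tmp_path / "e.csv", which="B",
                            test_code="GLU")
        text = out.read_text()
        assert "AV rule" in text
        assert "VERIF-S" not in text
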