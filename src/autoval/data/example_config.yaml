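# Example autovalidation configuration for a small chemistry panel.
# Ranges and cutoffs illustrate the schema; every laboratory must derive,
# document and approve its own limits before routine use.
schema_version: 1
mode: manual_trigger
kill_switch: false
metadata:
  institution: Example General Hospital
  department: Clinical Chemistry
  instrument: Analyzer-01
  lis_version: LIS 9.2
  verifier: A. Verifier
tests:
  - test_code: GLU
    name: Glucose
    unit: mmol/L
    precision: 1
    av_range: {low: 3.0, high: 11.0}        # 11 mmol/L: clinical DM cutoff
    critical_limits: {low: 2.5, high: 25.0}
    hil_thresholds: {hemolysis: 100, icterus: 40, lipemia: 200}
    delta: {mode: percent, limit: 20, window_days: 3}
    biovar: {cvi: 4.6, cvg: 8.1}
    age_groups_included: [[18, 120]]        # neonates/children excluded
    flags_blocking: [SAMPLE_CLOT, SAMPLE_SHORT, PROZONE]
  - test_code: CREA
    name: Creatinine
    unit: umol/L
    precision: 0
    av_range: {low: 40, high: 300}
    critical_limits: {high: 1000}
    hil_thresholds: {hemolysis: 200}
    delta: {mode: rcv, window_days: 3, z_value: 1.96, cv_analytical: 2.0}
    biovar: {cvi: 4.4, cvg: 16.2}
    age_groups_included: [[18, 120]]
    flags_blocking: [SAMPLE_CLOT, SAMPLE_SHORT]
  - test_code: K
    name: Potassium
    unit: mmol/L
    precision: 1
    av_range: {low: 3.0, high: 6.0}
    critical_limits: {low: 2.8, high: 6.2}
    hil_thresholds: {hemolysis: 50}         # hemolysis falsely raises K
    delta: {mode: absolute, limit: 1.0, window_days: 3}
    biovar: {cvi: 3.9, cvg: 5.3}
    age_groups_included: [[18, 120]]
    flags_blocking: [SAMPLE_CLOT, SAMPLE_SHORT]
  - test_code: AST
    name: Aspartate aminotransferase
    unit: U/L
    precision: 0
    av_range: {low: 5, high: 200}
    critical_limits: {high: 1000}
    hil_thresholds: {hemolysis: 100}
    age_groups_included: [[18, 120]]
    flags_blocking: [SAMPLE_CLOT]
  - test_code: ALT
    name: Alanine aminotransferase
    unit: U/L
    precision: 0
    av_range: {low: 5, high: 200}
    critical_limits: {high: 1000}
    age_groups_included: [[18, 120]]
    flags_blocking: [SAMPLE_CLOT]
  - test_code: TBIL
    name: Bilirubin, total
    unit: umol/L
    precision: 0
    av_range: {low: 2, high: 100}
    critical_limits: {high: 300}
    age_groups_included: [[18, 120]]
    flags_blocking: [SAMPLE_CLOT]
  - test_code: DBIL
    name: Bilirubin, conjugated
    unit: umol/L
    precision: 0
    av_range: {low: 0.5, high: 80}
    age_groups_included: [[18, 120]]
    flags_blocking: [SAMPLE_CLOT]
  - test_code: ALB
    name: Albumin
    unit: g/L
    precision: 0
    av_range: {low: 20, high: 55}
    age_groups_included: [[18, 120]]
    flags_blocking: [SAMPLE_CLOT]
  - test_code: TP
    name: Protein, total
    unit: g/L
    precision: 0
    av_range: {low: 45, high: 90}
    age_groups_included: [[18, 120]]
    flags_blocking: [SAMPLE_CLOT]
consistency_rules:
  - rule_id: ast_alt
    numerator_test: AST
    denominator_test: ALT
    limits: {low: 0.25, high: 4}
  - rule_id: conj_total_bili
    numerator_test: DBIL
    denominator_test: TBIL
    limits: {high: 1}
  - rule_id: alb_tp
    numerator_test: ALB
    denominator_test: TP
    limits: {low: 0.25, high: 1}
qc_policies:
  - test_code: GLU
    in_control: true
    last_pass_time: 2025-06-01 06:00:00
    max_age_hours: 24
  - test_code: K
    in_control: true
    last_pass_time: 2025-06-01 06:00:00
    max_age_hours: 24
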