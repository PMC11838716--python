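# Methods and design notes

This note records the scientific model behind `autoval`, the conventions
that had to be fixed for the engine to be verifiable, and the choices
made where the design was genuinely open.

## The decision model

A result is autovalidated iff the conjunction of all configured rules
passes. Three consequences are deliberate:

1. **No short-circuit.** Every rule is evaluated even after the first
   hold, so a held result carries its complete list of violated rules.
   Discordance investigation during verification, and routine review of
   held results, both need the full reason list, and the cost of
   evaluating a handful of extra rules per result is negligible.
2. **Order-invariant verdict.** Because the verdict is a pure
   conjunction over rule outcomes, it cannot depend on the order in
   which rules run. The engine still uses a fixed order (kill switch,
   demographics, flags, HIL, critical, AV range, delta, consistency,
   QC) so that audit logs are stable, but the property tests assert the
   verdict is invariant under permutation.
3. **SKIP is not a pass-with-asterisk.** A rule whose preconditions are
   unmet (no delta prior in the window, no HIL thresholds configured, no
   QC policy) reports SKIP and does not block release. In particular, a
   result whose only irregularity is a prior outside the delta window is
   autovalidated when all other rules pass.

### Boundary conventions

Decision-point behavior must be fixed before it can be verified with
cases at, just below and just above each limit. The conventions are:

- autovalidation range, HIL thresholds, consistency bands: **inclusive
  pass** (a value exactly at the limit is released);
- critical limits: **inclusive hold** (`x ≤ c_low` or `x ≥ c_high` is
  critical) — at the decision point, the safe verdict wins;
- delta limits: **strict exceedance holds** (`|Δ| > limit`); equality
  passes, consistent with the inclusive-pass convention above;
- critical limits dominate the autovalidation range: a critical result
  is held and alerted even when it lies inside the range. The usual
  configuration puts critical limits outside the AV range so this
  dominance is latent, but it matters whenever a laboratory sets a wide
  AV range.

### Rule specifics

- **Demographics.** Unknown sex is treated as missing and holds the
  result; age is computed at the result timestamp (not evaluation time)
  so decisions are reproducible. Ages are exact fractional calendar
  years: whole years by anniversary, fraction as days since the last
  anniversary over the length of the current anniversary year (Feb-29
  births fall on Mar 1 in common years).
- **Flags.** Flags are split into result-affecting (blocking) and
  informational; unknown flags are non-blocking but echoed into the
  audit detail. Results from analyzers excluded from autovalidation are
  held under this rule (`analyzer_excluded`), since the analyzer
  include/exclude decision belongs to the same instrument-trust family
  as analyzer messages.
- **HIL.** A configured-but-unmeasured index holds the result
  (`hil_missing`): the threshold exists because interference matters for
  the test, so an absent measurement cannot be treated as clean.
- **Missing values.** A missing result holds under the AV-range rule
  (`missing_result`); the critical rule skips, because a missing value
  is not a critical value — the record is still held overall.
- **Consistency.** A violated ratio band holds *both* participating
  results: the error could sit in either measurement. A zero denominator
  holds both with `ratio_undefined`.
- **Kill switch.** Honored unconditionally and first; rule outcomes are
  still computed and reported so the audit trail stays complete.
- **Modes.** Manually triggered and real-time operation share the
  identical decision path; only the invocation differs (batch command vs
  per-record callback with an attached release channel). This keeps a
  later upgrade from manual to real-time a pure wiring change.
- **Extension point.** Repeat testing, reflex testing, PBRTQC and
  clinical-diagnosis rules are out of scope; `register_extension_rule`
  is the named hook where such rules can be added without touching the
  engine.

## Delta check

Four difference forms are supported: absolute (units), percent, rate
(units/hour) and RCV-limited percent. The percent denominator is the
**prior** value — change relative to the patient's previous state —
which makes the percent delta asymmetric (documented and tested).

The reference change value uses the classical form
`RCV = √2 · z · √(CVa² + CVi²)` with a two-sided default `z = 1.96`.
The log-normal RCV variant exists in the literature; the classical form
was chosen as the default because it is the one in common laboratory
use, and `z` and `CVa` are per-test configuration.

Candidate selection uses the index of individuality `II = CVi/CVg` with
the conventional threshold 0.6 (strictly below qualifies). The packaged
21-measurand biological-variation table is a fixture for exactly this
computation; CVi/CVg values are otherwise user-supplied — no online
biological-variation database lookup is performed.

The eligible prior is the most recent same-patient, same-test result
older than the current one and inside the look-back window. The shipped
example configuration uses a 3-day window for hospital chemistry, in the
2–5-day range appropriate for inpatient populations; primary-care
settings would configure longer windows.

## Limit derivation

Percentiles use linear interpolation between order statistics
(`h = (n−1)p/100`, interpolate between the two bracketing order
statistics), stated explicitly so that derived limits are
bit-reproducible; the tests check it against an independent
sort-and-interpolate oracle. Data-derived methods require ≥ 20 values.
Two readings existed for two catalogued approaches and were fixed as:
midpoint = midpoints between the reference-interval median and each
critical limit; TEa widening = `low − TEa`, `high + TEa` with TEa
accepted on either an absolute or a percent scale, chosen explicitly by
the caller. All derivations return advisory `LimitProposal` artifacts;
nothing is ever written into an `EngineConfig` automatically, because
rule criteria must be reviewed and approved before routine use.

## Verification

Phase I generates, per test: absurd age/sex cases, a missing-result
case, one case per blocking flag plus an informational-flag case, and —
for every bounded decision point (AV low/high, each HIL threshold, each
critical limit, the delta limit) — cases at, just below and just above
the point, with ε = one unit in the test's last reported decimal place
(`precision` in the test definition). Delta-window, consistency, QC and
combined multi-rule cases complete the set; unbounded limits are skipped
with a note.

Expected yes/no labels are computed by an independent plain-boolean
restatement of the conventions above (always as the full conjunction —
e.g. a "just inside critical" value that lies outside the AV range is
still expected NO). Keeping this restatement separate from the engine is
what makes Phase I a real cross-check: the test suite mutates single
rule functions (exclusive AV boundaries, ignored flags, doubled HIL
thresholds, sex-blind demographics, inverted delta) and asserts each
mutation produces discordances at the affected cases.

During verification the engine is never attached to a release channel;
`SentinelChannel` raises and counts if anything tries, and every report
records `released_results = 0`. Phase II compares automatic decisions
with manual accept/reject labels: autovalidated-but-rejected results are
the critical discordances flagged for team review;
held-but-accepted ones are reported as benign. The expected percentage
of autovalidated results is a user-set target recorded in the report,
not a built-in constant.

## Synthetic data

The simulator emulates stationary homeostasis: patient `i`'s set-point
for a test is `mean · exp(N(−σg²/2, σg²))` and each serial result
multiplies it by `exp(N(−σw²/2, σw²))`, with `σ = √ln(1 + cv²)` mapping
percent CVs to the log scale (`σg` from CVg, `σw` from `√(CVi²+CVa²)`)
and the −σ²/2 shift preserving the population mean. Log-normality was
chosen because analyte concentrations are positive; for the CV ranges in
the packaged table the shape is near-normal. Inter-draw intervals are
exponential with a configurable mean, floored at 30 minutes; timestamps
are strictly increasing per patient. Everything is deterministic under a
fixed seed.

Error injection covers the preanalytical failure modes a delta check and
an HIL rule are meant to catch: value swaps between patients
(misidentification — sample ids and timestamps stay put, only values
move, both partners labeled), dilution by a factor in (0, 1), and
hemolysis (index set above threshold). Errors are mutually exclusive per
record so ground truth is unambiguous.

What the simulator does **not** model: disease trajectories, therapy
effects, circadian rhythm, analytical drift or shifts, or correlated
multi-analyte errors. Passing the detection study therefore shows that
the delta-check machinery behaves as the biological-variation model
predicts — it does not certify clinical sensitivity on real streams,
where non-error variation is richer.

## Study sizes and numerical checks

The swap-detection study uses Table-style CVi/CVg values with CVa = 2%
and RCV limits at z = 1.96: four low-II measurands (MCV, creatinine,
ALP, PSA; II ≤ 0.3) against four high-II measurands (chloride, total
bilirubin, potassium, total protein; II ≥ 0.7), 800 patients × 2 draws
each with a 50% swap rate (≥ 1000 checked swaps per group). The
clean-data specificity check runs 4000 patients × 4 draws of a mid-CV
measurand (≥ 10⁴ delta comparisons) and compares the empirical hold
rate with the analytic two-sided exceedance of the log-normal model,
`P(|e^{√2·σw·Z} − 1| > RCV/100)` evaluated with the normal CDF, within
three binomial standard errors. These sizes give stable verdicts in a
few seconds on one CPU.

## Known limitations

- One autovalidation range per test: no sex/age stratification of the
  range itself (age groups can only include/exclude patients). The
  config schema leaves room for stratified ranges as an extension.
- Consistency rules are ratio bands only; joint two-sided rules ("both
  TSH and fT4 below reference") are not expressible yet.
- Timestamps are naive ISO-8601; a laboratory spanning time zones must
  normalize upstream.
- History is supplied as input (file or in-batch); there is no
  persistence layer or LIS connector by design.
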