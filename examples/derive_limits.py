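"""Derive autovalidation-range and delta-limit proposals from history.

Simulates two months of glucose results, then proposes (a) an
autovalidation range from the 5th and 95th percentiles of released
results and (b) delta limits from percentiles of observed same-patient
differences within 3 days.  Proposals are advisory: they are printed and
written to file, never applied to a configuration automatically.
"""

import datetime as dt

import autoval as av
from autoval.limits import propose_limits, delta_percentile_limits

spec = av.SimSpec(
    n_patients=200,
    tests=[av.TestSim(test_code="GLU", mean=5.5, cvg=8.1, cvi=4.6, cva=2.0,
                      unit="mmol/L")],
    draws_per_patient=5,
    mean_interval_hours=30.0,
    seed=7,
)
records, _ = av.simulate_population(spec)
values = [r.value for r in records]

proposal = propose_limits("GLU", "percentile", values=values, p_low=5, p_high=95)
print(f"AV range proposal (percentile, n={proposal.n_used}): "
      f"[{proposal.interval.low:.2f}, {proposal.interval.high:.2f}] mmol/L")

# paired same-patient differences within a 3-day window
by_patient: dict[str, list[av.ResultRecord]] = {}
for r in records:
    by_patient.setdefault(r.patient.patient_id, []).append(r)
diffs = []
window = dt.timedelta(days=3)
for series in by_patient.values():
    series.sort(key=lambda r: r.timestamp)
    for prev, cur in zip(series, series[1:]):
        if cur.timestamp - prev.timestamp <= window:
            diffs.append(cur.value - prev.value)

delta_iv = delta_percentile_limits(diffs, 5, 95)
print(f"delta limits proposal (5th-95th pct of {len(diffs)} paired "
      f"differences in 3 d): [{delta_iv.low:.2f}, {delta_iv.high:.2f}] mmol/L")

# The AV interval brackets ~90% of the simulated population's released
# results; the delta interval brackets ~90% of benign short-term changes,
# so a limit at these percentiles flags roughly the most extreme 10% of
# consecutive-result differences for review.
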