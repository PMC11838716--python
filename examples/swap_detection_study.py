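"""Why delta checks are configured for low-individuality measurands.

Simulates serial results for a low-II measurand (creatinine, II = 0.27)
and a high-II measurand (potassium, II = 0.74), injects sample swaps
between patients, and measures how often an RCV-limited delta check
(z = 1.96, CVa = 2%) catches the swapped results.
"""

import autoval as av
from autoval.delta import evaluate_delta
from autoval.outcomes import Status
from autoval.simulate import ErrorLabel, record_key

CVA, Z = 2.0, 1.96


def sensitivity(name, mean, cvi, cvg, seed):
    spec = av.SimSpec(
        n_patients=1000,
        tests=[av.TestSim(test_code="T", mean=mean, cvg=cvg, cvi=cvi, cva=CVA)],
        draws_per_patient=2, mean_interval_hours=12.0, seed=seed)
    records, truth = av.simulate_population(spec)
    records, truth = av.inject_swap(records, truth, rate=0.5, seed=seed + 1)
    by_patient = {}
    for r in records:
        by_patient.setdefault(r.patient.patient_id, []).append(r)
    cfg = av.DeltaConfig(mode="rcv", window_days=3, z_value=Z, cv_analytical=CVA)
    td = av.TestDefinition(test_code="T",
                           biovar=av.BiologicalVariation(cvi=cvi, cvg=cvg))
    n = held = 0
    for r in records:
        if truth.labels[record_key(r)] is not ErrorLabel.swapped:
            continue
        priors = [h for h in by_patient[r.patient.patient_id]
                  if h.timestamp < r.timestamp]
        if not priors:
            continue
        out, res = evaluate_delta(r, priors, cfg, td)
        if res is None:
            continue
        n += 1
        held += out.status is Status.HOLD
    ii = cvi / cvg
    print(f"{name:<12} II={ii:.2f}  swaps checked={n:4d}  "
          f"delta-check sensitivity={100 * held / n:5.1f}%")
    return held / n


s_low = sensitivity("creatinine", 80.0, cvi=4.4, cvg=16.2, seed=11)
s_high = sensitivity("potassium", 4.2, cvi=3.9, cvg=5.3, seed=22)

print(f"\nlow-II sensitivity exceeds high-II by "
      f"{100 * (s_low - s_high):.1f} percentage points")
# When between-subject variation dwarfs within-subject variation (low II),
# another patient's value is usually far outside the individual's own band
# and the delta check flags the misidentification; when II is high the
# populations overlap and swaps slip through — which is why delta-check
# candidates are chosen by II < 0.6.
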