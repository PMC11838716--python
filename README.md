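# autoval — rule-based autovalidation of clinical laboratory results

Autovalidation (autoverification) is the computerized release of
laboratory test results without manual review: every result passes
through a configured rule set and is released automatically only when
every rule passes. `autoval` implements such a post-analytical rule
engine for clinical laboratory informatics teams — the people who
design, verify and audit autovalidation algorithms in a LIS or
middleware — together with the mathematics and tooling the workflow
needs: delta-check calculations, limit derivation, a two-phase
verification harness, and a result-stream simulator so the whole system
can be exercised without any real patient data.

## The rule model

A result `x` for test `t` is **autovalidated iff every rule passes**
(rules are conjunctive and all are evaluated, so a held result reports
every violated rule):

- **demographics** — hold without usable age/sex, or age outside the
  included age groups (e.g. neonates excluded);
- **analyzer flags** — hold on any result-affecting flag (sample clot,
  short sample, prozone, ...); informational flags pass but are logged;
- **HIL indices** — hold when a hemolysis/icterus/lipemia interference
  index exceeds its per-test threshold;
- **critical limits** — hold (with an alert) when `x ≤ c_low` or
  `x ≥ c_high`; critical results are never autovalidated, even inside
  the autovalidation range;
- **autovalidation range** — hold when `x` falls outside the per-test
  acceptance interval `[a_low, a_high]` (boundaries pass);
- **delta check** — hold when the change from the patient's most recent
  prior result within a look-back window exceeds a limit, computed as an
  absolute difference, a percent difference `100·(x − x_prev)/x_prev`, a
  rate `(x − x_prev)/Δt`, or compared against the reference change value

  `RCV = √2 · z · √(CVa² + CVi²)`  (percent, two-sided, default z = 1.96),

  where `CVa` and `CVi` are the analytical and within-subject biological
  coefficients of variation. Delta-check candidates are chosen by the
  index of individuality `II = CVi/CVg < 0.6`;
- **consistency** — hold both results of a physiologically related pair
  when their ratio leaves its plausibility band (e.g. AST/ALT outside
  [0.25, 4], conjugated/total bilirubin > 1);
- **QC gating** — hold when internal QC is failed or stale;
- **kill switch** — a configuration flag that unconditionally stops all
  automatic release.

## Worked example

```python
import autoval as av
from importlib import resources

config = av.load_config(str(resources.files("autoval.data") / "example_config.yaml"))

table = av.load_biological_variation()          # 21 measurands, CVi/CVg in %
candidates = av.select_delta_candidates(table)  # II < 0.6
print(len(candidates), candidates[0])
```

```
13 ('PSA', 0.1619047619047619)
```

Of the 21 packaged measurands, 13 have an index of individuality below
0.6 and are worthwhile delta-check candidates; PSA is the strongest
(II = 0.16: a patient's own PSA band is very narrow compared to the
population, so a large jump most likely means a sample mix-up).

Running `python examples/validate_stream.py` (a simulated glucose stream
with a few hemolyzed samples injected) prints:

```
records evaluated : 50
autovalidated     : 45 (90.0%)

held results and their rule-level reasons:
  S00001-002 GLU value=5.44 -> hil:hemolysis_exceeded
  ...
```

90% of results were released automatically; the held ones each carry the
machine-readable rule/reason pair an auditor needs. The other scripts in
`examples/` demonstrate percentile-based limit derivation, Phase I
technical verification (boundary cases at/below/above every decision
point, 100% concordance on the shipped configuration, zero releases
during verification), and the swap-detection study showing why low-II
measurands make better delta-check candidates.

A thin CLI wraps the same library functions:

```bash
autoval validate --config cfg.yaml --records stream.csv --out decisions.csv
autoval verify --config cfg.yaml --phase 1 --out verif/
autoval derive-limits --history history.csv --test-code GLU --out proposal.json
autoval simulate --spec simspec.yaml --out sim/
```

## Layout

- `src/autoval/config.py` — domain types and YAML/JSON rule configuration
- `src/autoval/engine.py` — the conjunctive rule engine
- `src/autoval/delta.py` — delta-check mathematics (RCV, II, rule)
- `src/autoval/limits.py` — advisory limit derivation (percentiles, TEa, midpoint)
- `src/autoval/verification.py` — Phase I/II harness, spreadsheet export
- `src/autoval/simulate.py` — synthetic streams with ground-truth errors
- `src/autoval/io.py`, `src/autoval/cli.py` — file formats, manifests, CLI
- `docs/methods.md` — model assumptions, conventions and design choices
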