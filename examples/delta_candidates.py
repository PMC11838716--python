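"""Select delta-check candidate measurands by index of individuality.

Loads the packaged biological-variation table (within-subject CVi and
between-subject CVg, in %), computes II = CVi/CVg for each measurand,
and lists those with II < 0.6 — the tests for which a patient's own
results occupy a narrow band relative to the population, so a
consecutive-result comparison is informative.  Also shows the reference
change value each candidate would use as its delta limit.
"""

import autoval as av

table = av.load_biological_variation()
candidates = av.select_delta_candidates(table, threshold=0.6)

print(f"{len(table)} measurands, {len(candidates)} delta-check candidates "
      f"(II < 0.6), best first:\n")
print(f"{'measurand':<22}{'II':>6}{'RCV% (CVa=2, z=1.96)':>24}")
biovar = dict(table)
for name, ii in candidates:
    rcv = av.reference_change_value(2.0, biovar[name].cvi, 1.96)
    print(f"{name:<22}{ii:>6.2f}{rcv:>24.1f}")

# II is CVi/CVg: the lower it is, the more a significant change for the
# individual can hide inside the population reference interval, and the
# more a delta check adds.  RCV is the smallest percent change between two
# serial results exceeding analytical + within-subject variation at 95%
# confidence; it is the natural delta limit for these candidates.
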