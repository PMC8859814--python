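"""Per-bait local (elbow) filtering of globally significant calls.

A bait typically makes many contacts that clear a global significance
cutoff yet form an undifferentiated bulk; the handful of markedly stronger
contacts are the likely functional loops. The LF algorithm finds the elbow
of each bait's cumulative -log10(q) curve and keeps only the tail.
"""

import chicbench as cb
from chicbench.calls import CallSet

# worked example: five interactions of one bait
q_values = [0.04, 0.04, 0.03, 1e-3, 1e-6]
curve = cb.cumulative_significance_curve(q_values)
print("rounded -log10(q) levels:", [int(v) for v in curve.levels])
print("cumulative counts:       ", [int(c) for c in curve.cumulative])
print("slopes:                  ", [round(float(s), 3) for s in curve.slopes])
print("elbow threshold level:   ", cb.lf_threshold(curve))

calls = CallSet.from_records([(1, 10 + k, q) for k, q in enumerate(q_values)])
filtered, thresholds = cb.local_filter(calls)
print(f"retained {len(filtered)}/{len(calls)} calls at threshold {thresholds[1]}")
# The first slope (-2) is the only one steeper than 1 in magnitude, so the
# threshold lands at level 2: the two q = 0.04 bulk calls are dropped and
# the three stronger ones (q = 0.03, 1e-3, 1e-6) survive.
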