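# chicbench

A toolkit for calling and benchmarking promoter Capture Hi-C (CHi-C)
interactions at restriction-fragment resolution.

CHi-C enriches a Hi-C library for ligation products that involve
predefined *bait* fragments (typically promoters), so that
promoter–enhancer loops can be mapped at the resolution of single
restriction fragments. Different statistical callers (global-background
tests, distance-aware models, local-maxima methods) disagree wildly on how
many interactions are real, so any caller's output needs to be judged on
two axes: is an interaction *reproducible* across replicates, and does its
other end fall in *regulatory chromatin* (DHS, H3K27ac, H3K4me1, H3K4me3
peaks)? `chicbench` provides:

* **Fragment maps** — in-silico digestion of a genome (HindIII, MboI, or
  any enzyme given its recognition site and cut offset) into the
  rmap/baitmap coordinate system, plus the capture-probe eligibility rules
  (120-mer probes, 25–65% GC, ≤2 consecutive Ns, within 330 bp of a
  fragment terminus).
* **A random-ligation binomial caller** — under random ligation a fragment
  pair (i, j) is expected with probability p_ij = 2·r_i·r_j, where r_i is
  fragment i's share of all read ends (its *visibility*). A pair observed
  n_ij times out of N read pairs is scored by the upper binomial tail
  P(X ≥ n_ij), X ~ Binomial(N, p_ij), with Benjamini–Hochberg correction.
* **Per-bait local filtering (LF)** — for each bait, round the −log10
  q-values of its significant interactions to integer levels, count
  interactions at or above each level, and place the bait-specific
  threshold where the cumulative curve's absolute slope last exceeds 1.
  Only the tail of markedly stronger interactions survives.
* **Benchmark metrics** — replicate reproducibility (exact, or with other
  ends extended by 2.5 kb / 20 kb per side), joint mean-significance
  thresholding, threshold sweeps (q < 0.05/0.01/0.001, score ≥ 5/10/15),
  bait-bait vs bait-other classification, and overlap of other-end
  fragments with peak tracks.
* **A synthetic-data generator** — every input above, generated with known
  ground truth (planted cut sites, shared true loops with controlled
  per-replicate detection probability, distance decay, planted functional
  other ends), so recovery can be verified exactly.

Call tables from external callers are consumed through a generic 8-column
TSV; no caller is re-implemented beyond the binomial background model.

## Worked example: local filtering

```python
import chicbench as cb

q = [0.04, 0.04, 0.03, 1e-3, 1e-6]       # one bait's significant q-values
curve = cb.cumulative_significance_curve(q)
print([int(v) for v in curve.levels])     # [1, 2, 3, 6]
print([int(c) for c in curve.cumulative]) # [5, 3, 2, 1]
print(cb.lf_threshold(curve))             # 2.0
```

The rounded −log10(q) levels are {1, 2, 3, 6}; 5 interactions sit at level
≥ 1, 3 at ≥ 2, 2 at ≥ 3 and 1 at ≥ 6, giving slopes (−2, −1, −1/3). Only
the first slope is steeper than 1 in magnitude, so the bait's threshold is
level 2: the two bulk calls at q = 0.04 are discarded and the three
stronger calls are kept (`cb.local_filter` reports "3 of 5 retained").

The `examples/` directory holds one short script per capability
(digestion and probe design, the binomial caller, local filtering,
reproducibility, the full benchmark); each prints the numbers it computes
and a note on what they mean. The same operations are exposed on the
command line as `chicbench digest|call|lf|calls|reproducibility|functional|simulate|run`.

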