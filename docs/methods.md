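# Methods

## Coordinate system and digestion

All coordinates are 1-based inclusive internally; 0-based inputs (BED,
0-based digest profiles) are converted at the I/O boundary. An enzyme is a
recognition sequence plus a cut offset (HindIII: A^AGCTT, offset 1; MboI:
^GATC, offset 0). Digestion scans every position, so overlapping
recognition matches are all found; a match containing N never fires
(unknown sequence cannot assert a site); a cut that would create an empty
fragment (recognition at the very start of a chromosome with offset 0) is
dropped. Fragments tile each chromosome exactly — first start 1, each
start = previous end + 1, last end = chromosome length — and fragment ids
are assigned genome-wide in chromosome-then-coordinate order. Fill-in of
sticky ends is not modelled: the fragment boundary sits at
recognition-start + cut offset, which is the convention digest-profile
files use.

Capture-probe eligibility mirrors promoter-capture array design: a
fragment is baitable if at least one terminus admits a probe window
(default 120 bp) whose start (left end) or end (right end) lies within
330 bp of that terminus, with GC in [0.25, 0.65] and at most two
consecutive Ns. When several windows qualify the one closest to the
terminus wins — the field does not specify a rule, and closest-to-terminus
is deterministic and maximizes coverage of the ligation junction.
Fragments shorter than the probe are ineligible rather than an error,
because real digests contain many tiny fragments.

## Random-ligation binomial caller

Let n_ij be the read-pair count of unordered fragment pair (i, j),
N = Σ n_ij, c_i = Σ_j n_ij the read ends in fragment i, and
r_i = c_i / 2N its relative visibility. Under pure random ligation pair
(i, j) occurs with probability p_ij = 2·r_i·r_j, so the evidence against
random ligation is the upper tail P(X ≥ n_ij) for X ~ Binomial(N, p_ij).
Benjamini–Hochberg q-values are computed over all tested pairs
(statsmodels' step-up implementation), and the output is sorted by
(q, p, pair id) so reruns are byte-identical. Only observed pairs are
tested. With a bait map supplied, only bait-other pairs are scored:
pairs without a baited end are not captured by the protocol, and
bait-bait pairs have a different capture probability that requires a
dedicated model with a ligation control — deliberately out of scope; such
calls are consumed from external callers instead.

Because r is estimated from the same counts being tested, the caller is
slightly conservative; together with the discreteness of the binomial the
null p-value distribution is stochastically larger than uniform, which the
calibration test checks with a one-sided Kolmogorov–Smirnov statistic.

## Per-bait local filtering

For one bait with significant interactions q_1..q_n, levels are
round(−log10 q) (half away from zero, to integer levels by default;
`round_digits` is configurable). q = 0 is floored at 1e−300 before the
log so levels stay finite; q = 1 maps to level 0. C(v) counts
interactions with level ≥ v over the distinct levels v_1 < … < v_m, and
s_k = (C(v_{k+1}) − C(v_k)) / (v_{k+1} − v_k).

The elbow sentence — "set the threshold to the significance level where
the absolute slope is above 1" — admits two readings, and both are
implemented behind `rule=`:

* `last-steep` (default): T = v_{k*+1}, k* = max{k : |s_k| > 1}. The
  threshold sits just above the last steep segment, dropping the bulk.
* `first-shallow`: T = v_{k0}, k0 = min{k : |s_k| ≤ 1}.

Strictly "above 1" means |s| = 1 does not count as steep. A bait with no
slope above 1 (including single-level baits) keeps all its interactions —
no elbow, no evidence to split bulk from tail. Baits are filtered
independently, so the result is invariant to bait order.

## Benchmark metrics

**Reproducibility.** With pad = 0 two interactions match iff they share
(bait, other-end) fragment ids; with pad > 0 they match iff their
other-end fragments, extended by pad on both sides and clipped at
chromosome ends, overlap by ≥ 1 bp — bait identity must always match
exactly, since baits are fixed by the capture design. Support is
propagated within a bait by single linkage (any one-to-one matching would
be order-dependent). The headline fraction is the share of the union of
unique (bait, other-end) pairs supported by ≥ 2 replicates; a
`per-replicate-mean` denominator is also available since the union choice
is a convention. Bait-bait pairs are included by default (flag to
exclude). Reproducibility is provably non-decreasing in pad, and the test
suite asserts this on randomized benchmarks.

**Joint mean threshold.** A pair present in ≥ 2 replicate tables passes
jointly when the mean of its metric over the replicates containing it
clears the cutoff. The comparison statistic against the union of
individually significant pairs is non-negative by construction; indeed it
is exactly zero whenever the tables only contain each pair's own
significant values, because a mean clearing a one-sided cutoff forces at
least one replicate to clear it too. The statistic becomes informative
when full (unthresholded) result tables are supplied.

**Functional overlap.** The fraction of unique non-baited other-end
fragments (bait-other calls only; bait-bait ends are promoters by design)
whose interval, extended by pad and clipped, overlaps ≥ 1 significant peak
by ≥ 1 bp. Peaks come from BED/narrowPeak (0-based half-open, converted on
read); the narrowPeak q column is interpreted as −log10(q) per the ENCODE
convention (−1 = missing; `q_encoding="raw"` for files storing plain q),
and peaks with q ≥ 0.05 are dropped. Counting unique fragments rather than
interaction rows keeps a promiscuous bait from dominating the fraction.

## Synthetic data

The generator produces every input with known truth; all outputs are pure
functions of (config, seed).

* **Genome**: random ACGT scrubbed of accidental recognition sites, with
  sites planted at geometrically spaced intervals (mean fragment length
  4 kb HindIII-like, 400 bp MboI-like by default) — digestion therefore
  has an exact expected answer.
* **Baits**: a uniform sample of fragments passing the probe rules.
  Promoter identity is abstracted away; the metrics depend only on
  bait/non-bait status.
* **Call sets**: true loops drawn once (bait uniform; other end at a
  signed power-law distance, exponent 1.0 by default, snapped to a
  fragment) and included in each replicate independently with probability
  d; noise loops drawn fresh per replicate, unique within it and disjoint
  from the true-loop pairs. True-loop significance follows a bulk-plus-
  tail model, −log10 q = −log10(cutoff) + Exponential(mean 1.5), so an LF
  elbow exists; noise q-values are uniform just under the cutoff. The
  functional flag is assigned per unique other-end fragment (not per
  loop), so loops sharing an other end cannot disagree and the overlap of
  the true-loop subset is exactly Binomial(n, p_func + (1−p_func)·b).
* **Contact counts**: a multinomial draw of N pairs with probabilities
  ∝ w_i·w_j, w log-normal (σ = 0.5); planted pairs are up-weighted by a
  fold factor before renormalisation.
* **Peaks**: a significant peak inside every functional other-end
  fragment, background peaks elsewhere with per-fragment probability b,
  plus a configured fraction of decoy peaks with q ≥ 0.05 that the
  significance filter must remove.

What the generator does *not* emulate: read-level artefacts (mapping,
duplicates, capture efficiency, GC bias), trans-chromosomal loops
(cis-only by default), correlated noise between replicates, and realistic
chromatin domain structure. Passing tests therefore demonstrate that the
algorithms are correct and calibrated under their stated models, not that
any particular caller is well-suited to real CHi-C libraries.

## Validation design and problem sizes

The statistical checks run at sizes chosen to keep the whole suite fast
while leaving the Monte-Carlo intervals tight: digestion equivalence on
1,000 random 10-kb sequences per enzyme; exact binomial enumeration on all
three-fragment tables with N ≤ 12; null calibration at N = 100,000 read
pairs; planted-pair recovery at 50-fold enrichment, N = 200,000; the
reproducibility recovery study on a 4 × 2 Mb genome (≈ 8,000 fragments,
600 baits) with 3 replicates, detection probability 0.6, 2,000 true and
2,000 noise loops per replicate; 200 randomized benchmarks for the
monotonicity sweeps. The reproducibility oracle simulates the generative
model directly — Bernoulli detection for true loops and noise pairs drawn
with the same bait/distance geometry, so cross-replicate noise collisions
(which raise the measured fraction by roughly one percentage point at
these sizes) are represented — without touching the support-table code
under test; the measured fraction must fall in the oracle's central 99%
interval.

## Known limitations

* The binomial caller ignores genomic distance entirely (as its global-
  background design intends), so at realistic depths it will call many
  short-range contacts that distance-aware models would discount; LF is
  the intended corrective for that behaviour, not a replacement for a
  distance-aware test.
* LF requires q-values; score-based callers must be benchmarked without
  it.
* The rounding granularity of LF levels (integer by default) is part of
  the algorithm's definition; finer rounding changes thresholds and is
  exposed but not swept in the tests.
* `read_calls` resolves coordinates by exact fragment-interval match and
  rejects anything else; sloppy caller output must be normalized to the
  fragment map first.
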