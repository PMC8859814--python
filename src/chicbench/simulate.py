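"""Synthetic Capture Hi-C inputs with known ground truth.

Real promoter CHi-C benchmarks need hundreds of millions of read pairs and
external callers; this module generates every file the toolkit consumes at
desk scale, with the planted truth recorded so recovery can be checked:

* a genome whose restriction sites are planted at geometrically spaced
  intervals (so in-silico digestion has an exact expected answer),
* a bait map sampled from fragments passing the capture-probe design rules,
* replicate call sets in which *true loops* are shared across replicates
  (each detected independently with probability ``detection_prob``) and
  *noise loops* are drawn fresh per replicate,
* contact-count tables following the random-ligation null with log-normal
  visibility bias and optional planted enriched pairs,
* peak tracks placed so a controlled fraction of loop other ends carries a
  significant peak.

Every output is a pure function of the config and its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .calls import CallSet, classify
from .fragment_map import (
    HINDIII,
    BaitDesignRules,
    BaitMap,
    Enzyme,
    FragmentMap,
    bait_eligible,
    digest_genome,
    find_cut_sites,
)
from .significance import ContactCounts

__all__ = [
    "GenomeConfig",
    "BaitConfig",
    "LoopConfig",
    "CountsConfig",
    "PeakConfig",
    "SimulationConfig",
    "GroundTruth",
    "simulate_genome",
    "simulate_baitmap",
    "simulate_replicate_callsets",
    "simulate_contact_counts",
    "simulate_peaks",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class GenomeConfig:
    """Synthetic genome shape; mean fragment length mimics a 6-cutter
    (~4 kb) by default, ~400 bp is MboI-like."""

    n_chroms: int = 2
    chrom_length: int = 500_000
    mean_fragment_length: int = 4_000


@dataclass(frozen=True)
class BaitConfig:
    n_baits: int = 100
    rules: BaitDesignRules = field(default_factory=BaitDesignRules)


@dataclass(frozen=True)
class LoopConfig:
    """True loops are drawn once and shared; noise loops are per-replicate.

    ``decay`` is the exponent of the power-law other-end placement
    density (probability ∝ distance^-decay over [min_distance,
    max_distance]). True-loop q-values follow a bulk-plus-tail model
    (−log10 q = −log10(cutoff) + Exponential(tail_mean)); noise q-values
    are uniform just under the cutoff.
    """

    n_true_loops: int = 500
    detection_prob: float = 0.8
    n_replicates: int = 3
    noise_loops_per_replicate: int = 200
    decay: float = 1.0
    min_distance: int = 5_000
    max_distance: int = 250_000
    q_cutoff: float = 0.05
    tail_mean: float = 1.5

    def __post_init__(self) -> None:
        if self.decay <= 0:
            raise ValueError("decay must be > 0")
        if not 0 <= self.detection_prob <= 1:
            raise ValueError("detection_prob must be in [0, 1]")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates")


@dataclass(frozen=True)
class CountsConfig:
    """Random-ligation contact counts with log-normal visibility bias."""

    total_pairs: int = 100_000
    visibility_sigma: float = 0.5
    enrichment_fold: float = 1.0
    n_enriched_pairs: int = 0

    def __post_init__(self) -> None:
        if self.enrichment_fold < 1:
            raise ValueError("enrichment_fold must be >= 1")


@dataclass(frozen=True)
class PeakConfig:
    """``p_func``: fraction of true-loop other ends carrying a peak;
    ``background_coverage``: chance any other fragment carries one."""

    p_func: float = 0.4
    background_coverage: float = 0.05
    peak_length: int = 500
    nonsig_fraction: float = 0.2  # decoy peaks with q >= 0.05, exercising the filter


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    baits: BaitConfig = field(default_factory=BaitConfig)
    loops: LoopConfig = field(default_factory=LoopConfig)
    counts: CountsConfig = field(default_factory=CountsConfig)
    peaks: PeakConfig = field(default_factory=PeakConfig)


@dataclass
class GroundTruth:
    """Planted truth: loops with per-replicate presence and functional
    flags, and contact pairs that were enriched."""

    true_loops: pd.DataFrame  # bait_id, oe_id, present_rep<k>..., functional
    enriched_pairs: list[tuple[int, int]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Genome


def _find_all(text: str, rec: str) -> list[int]:
    out = []
    i = text.find(rec)
    while i != -1:
        out.append(i)
        i = text.find(rec, i + 1)
    return out


def _random_sequence_without_site(n: int, enzyme: Enzyme, rng: np.random.Generator) -> np.ndarray:
    """Random ACGT array containing no recognition site.

    Accidental matches are destroyed by rewriting the middle base of each;
    passes repeat until the scan is clean (a rewrite can in principle
    create a new match with its neighbourhood).
    """
    rec = enzyme.recognition
    arr = _BASES[rng.integers(0, 4, size=n)]
    while True:
        text = arr.tobytes().decode()
        matches = _find_all(text, rec)
        if not matches:
            return arr
        for i in matches:
            mid = i + len(rec) // 2
            old = arr[mid].decode()
            new = "ACGT"[("ACGT".index(old) + 1 + int(rng.integers(0, 3))) % 4]
            arr[mid] = new.encode()


def simulate_genome(
    config: SimulationConfig, enzyme: Enzyme = HINDIII
) -> tuple[dict[str, str], dict[str, list[int]]]:
    """Random genome with planted, geometrically spaced recognition sites.

    Returns (name -> sequence, name -> 1-based cut positions), where the
    cut positions are exactly what digestion should recover. The
    background contains no accidental sites, so digestion is exact by
    construction.
    """
    g = config.genome
    rec = enzyme.recognition
    if g.chrom_length < g.mean_fragment_length:
        raise ValueError("chrom_length too small for one fragment")
    rng = np.random.default_rng([config.seed, 0x67656E])
    genome: dict[str, str] = {}
    truth: dict[str, list[int]] = {}
    for k in range(g.n_chroms):
        name = f"chr{k + 1}"
        seq = _random_sequence_without_site(g.chrom_length, enzyme, rng)
        # geometric fragment lengths -> site start positions
        positions: list[int] = []
        pos = 0
        while True:
            gap = int(rng.geometric(1.0 / g.mean_fragment_length))
            pos += max(gap, len(rec) + 1)
            if pos + len(rec) > g.chrom_length - len(rec):
                break
            positions.append(pos)  # 0-based recognition start
        for p in positions:
            seq[p : p + len(rec)] = np.frombuffer(rec.encode(), dtype="S1")
        text = seq.tobytes().decode()
        # planting may butt-join bases into a new site; verify and retry locally
        found = find_cut_sites(text, enzyme)
        expected = sorted(p + enzyme.cut_offset + 1 for p in positions)
        attempts = 0
        while found != expected and attempts < 50:
            extra = [c for c in found if c not in expected]
            arr = np.frombuffer(text.encode(), dtype="S1").copy()
            planted = set(expected)
            for c in extra:
                m = c - enzyme.cut_offset - 1  # 0-based match start
                # rewrite one base of the spurious site outside planted sites
                for off in range(len(rec)):
                    j = m + off
                    if all(abs(j - (pc - enzyme.cut_offset - 1)) >= len(rec) for pc in planted):
                        base = arr[j].decode()
                        arr[j] = "ACGT"[("ACGT".index(base) + 1) % 4].encode()
                        break
            text = arr.tobytes().decode()
            found = find_cut_sites(text, enzyme)
            attempts += 1
        if found != expected:
            raise RuntimeError("failed to plant clean recognition sites")
        genome[name] = text
        truth[name] = expected
    return genome, truth


# ---------------------------------------------------------------------------
# Baits


def simulate_baitmap(
    fragment_map: FragmentMap,
    genome: Mapping[str, str],
    config: SimulationConfig,
) -> BaitMap:
    """Sample ``n_baits`` uniformly from fragments passing the probe rules."""
    rules = config.baits.rules
    eligible = []
    for frag in fragment_map:
        seq = genome[frag.chrom][frag.start - 1 : frag.end]
        ok, _ = bait_eligible(frag, seq, rules)
        if ok:
            eligible.append(frag.frag_id)
    n = config.baits.n_baits
    if len(eligible) < n:
        raise ValueError(
            f"only {len(eligible)} eligible fragments for {n} baits"
        )
    rng = np.random.default_rng([config.seed, 0x62616974])
    chosen = rng.choice(np.array(eligible, dtype=np.int64), size=n, replace=False)
    return BaitMap({int(i): f"gene_{int(i)}" for i in sorted(chosen)})


# ---------------------------------------------------------------------------
# Replicate call sets


def _power_law_distances(
    rng: np.random.Generator, n: int, decay: float, lo: int, hi: int
) -> np.ndarray:
    """Signed distances with |d| ~ density ∝ d^-decay on [lo, hi]."""
    u = rng.random(n)
    if abs(decay - 1.0) < 1e-12:
        mag = lo * (hi / lo) ** u
    else:
        a = 1.0 - decay
        mag = (lo**a + u * (hi**a - lo**a)) ** (1.0 / a)
    sign = rng.choice([-1, 1], size=n)
    return (sign * mag).astype(np.int64)


def _snap_loop(
    fragment_map: FragmentMap,
    bait_id: int,
    distance: int,
) -> int | None:
    """Other-end fragment at a signed distance from the bait midpoint."""
    bait = fragment_map.fragment(bait_id)
    mid = (bait.start + bait.end) // 2
    pos = mid + int(distance)
    length = fragment_map.chrom_lengths[bait.chrom]
    if not 1 <= pos <= length:
        return None
    oe = fragment_map.locate(bait.chrom, pos)
    if oe.frag_id == bait_id:
        return None
    return oe.frag_id


def _draw_loops(
    fragment_map: FragmentMap,
    bait_ids: np.ndarray,
    n: int,
    cfg: LoopConfig,
    rng: np.random.Generator,
    forbid: set[tuple[int, int]] | None = None,
    unique: bool = True,
) -> list[tuple[int, int]]:
    """Draw n (bait, oe) loops with power-law distance placement."""
    out: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set(forbid or ())
    guard = 0
    while len(out) < n:
        guard += 1
        if guard > 200 * n + 1000:
            raise RuntimeError("could not place requested number of loops")
        b = int(rng.choice(bait_ids))
        d = int(_power_law_distances(rng, 1, cfg.decay, cfg.min_distance, cfg.max_distance)[0])
        oe = _snap_loop(fragment_map, b, d)
        if oe is None:
            continue
        key = (b, oe)
        if unique and key in seen:
            continue
        seen.add(key)
        out.append(key)
    return out


def _true_q(rng: np.random.Generator, n: int, cfg: LoopConfig) -> np.ndarray:
    level = -np.log10(cfg.q_cutoff) + rng.exponential(cfg.tail_mean, size=n)
    return np.minimum(10.0 ** (-level), cfg.q_cutoff * 0.999)


def _noise_q(rng: np.random.Generator, n: int, cfg: LoopConfig) -> np.ndarray:
    return rng.uniform(cfg.q_cutoff * 0.5, cfg.q_cutoff, size=n)


def simulate_replicate_callsets(
    fragment_map: FragmentMap,
    bait_map: BaitMap,
    config: SimulationConfig,
    tool: str = "synthetic",
) -> tuple[list[CallSet], GroundTruth]:
    """Replicate call sets with a controlled shared-loop fraction.

    True loops are drawn once (bait uniform, other end at a power-law
    distance) and enter each replicate independently with probability
    ``detection_prob``; noise loops are drawn fresh per replicate and are
    unique within it. The functional flag is assigned per unique
    other-end fragment so the truth is unambiguous at fragment level.
    """
    cfg = config.loops
    rng = np.random.default_rng([config.seed, 0x6C6F6F70])
    bait_ids = np.array(sorted(bait_map.frag_ids), dtype=np.int64)
    true_loops = _draw_loops(fragment_map, bait_ids, cfg.n_true_loops, cfg, rng)

    present = rng.random((cfg.n_true_loops, cfg.n_replicates)) < cfg.detection_prob

    # per-fragment functional flags (true-loop other ends)
    p = config.peaks
    oe_ids = sorted({oe for _, oe in true_loops})
    func_flag = {oe: bool(rng.random() < p.p_func) for oe in oe_ids}

    call_sets: list[CallSet] = []
    for r in range(cfg.n_replicates):
        records: list[tuple[int, int, float]] = []
        idx = np.nonzero(present[:, r])[0]
        qs = _true_q(rng, len(idx), cfg)
        for k, i in enumerate(idx):
            b, oe = true_loops[i]
            records.append((b, oe, float(qs[k])))
        noise = _draw_loops(
            fragment_map, bait_ids, cfg.noise_loops_per_replicate, cfg, rng,
            forbid=set(true_loops), unique=True,
        )
        nq = _noise_q(rng, len(noise), cfg)
        records.extend((b, oe, float(q)) for (b, oe), q in zip(noise, nq))
        cs = CallSet.from_records(
            records, tool=tool, replicate=f"rep{r + 1}", metric_kind="qvalue",
            fragment_map=fragment_map, bait_map=bait_map,
        )
        call_sets.append(classify(cs, bait_map))

    truth_df = pd.DataFrame(
        {
            "bait_id": [b for b, _ in true_loops],
            "oe_id": [oe for _, oe in true_loops],
            **{f"present_rep{r + 1}": present[:, r] for r in range(cfg.n_replicates)},
            "functional": [func_flag[oe] for _, oe in true_loops],
        }
    )
    return call_sets, GroundTruth(true_loops=truth_df)


# ---------------------------------------------------------------------------
# Contact counts


def simulate_contact_counts(
    fragment_map: FragmentMap,
    bait_map: BaitMap,
    config: SimulationConfig,
) -> tuple[ContactCounts, GroundTruth]:
    """Multinomial contact table under the random-ligation null.

    Pair probabilities are proportional to w_i·w_j with log-normal
    fragment weights; planted pairs (sampled among bait-other pairs) are
    up-weighted by ``enrichment_fold`` before renormalisation.
    """
    c = config.counts
    rng = np.random.default_rng([config.seed, 0x636E7473])
    ids = fragment_map.frag_ids
    F = len(ids)
    w = rng.lognormal(0.0, c.visibility_sigma, size=F)
    iu, ju = np.triu_indices(F, k=1)
    probs = w[iu] * w[ju]

    enriched: list[tuple[int, int]] = []
    if c.n_enriched_pairs > 0:
        bait_set = bait_map.frag_ids
        is_bait = np.isin(ids, np.array(sorted(bait_set), dtype=np.int64))
        bo_mask = is_bait[iu] != is_bait[ju]
        candidates = np.nonzero(bo_mask)[0]
        pick = rng.choice(candidates, size=c.n_enriched_pairs, replace=False)
        probs = probs.copy()
        probs[pick] *= c.enrichment_fold
        enriched = [(int(ids[iu[k]]), int(ids[ju[k]])) for k in pick]

    probs = probs / probs.sum()
    draws = rng.multinomial(c.total_pairs, probs)
    nz = np.nonzero(draws)[0]
    counts = ContactCounts(
        {(int(ids[iu[k]]), int(ids[ju[k]])): int(draws[k]) for k in nz}
    )
    truth = GroundTruth(true_loops=pd.DataFrame(), enriched_pairs=enriched)
    return counts, truth


# ---------------------------------------------------------------------------
# Peaks


def simulate_peaks(
    fragment_map: FragmentMap,
    ground_truth: GroundTruth,
    config: SimulationConfig,
    feature: str = "DHS",
) -> pd.DataFrame:
    """Peak track as a narrowPeak-style DataFrame (0-based half-open).

    A significant peak is placed inside every *functional* true-loop
    other-end fragment; every other fragment receives a background peak
    with probability ``background_coverage``. A configured fraction of
    additional decoy peaks carries q >= 0.05 so the significance filter
    is exercised; decoys are placed in fragments that already have no
    significant peak and are labelled by their q-value only.
    """
    p = config.peaks
    rng = np.random.default_rng([config.seed, 0x70656B73])
    truth = ground_truth.true_loops
    functional = set()
    if len(truth):
        functional = set(truth.loc[truth["functional"], "oe_id"].astype(int))

    rows = []  # chrom, start0, end0, qvalue (raw)
    peaked: set[int] = set()
    for frag in fragment_map:
        has_peak = False
        if frag.frag_id in functional:
            has_peak = True
        elif rng.random() < p.background_coverage:
            has_peak = True
        if not has_peak:
            continue
        peaked.add(frag.frag_id)
        length = min(p.peak_length, frag.length)
        lo = frag.start - 1  # 0-based
        hi = frag.end - length  # inclusive upper bound for 0-based start
        start0 = int(rng.integers(lo, max(lo, hi) + 1))
        q = float(10 ** -rng.uniform(2.0, 8.0))  # clearly significant
        rows.append((frag.chrom, start0, start0 + length, q))

    n_decoys = int(round(p.nonsig_fraction * len(rows)))
    unpeaked = [f for f in fragment_map if f.frag_id not in peaked]
    if unpeaked and n_decoys:
        pick = rng.choice(len(unpeaked), size=min(n_decoys, len(unpeaked)), replace=False)
        for k in pick:
            frag = unpeaked[int(k)]
            length = min(p.peak_length, frag.length)
            start0 = frag.start - 1
            q = float(rng.uniform(0.05, 0.5))  # fails the q < 0.05 filter
            rows.append((frag.chrom, start0, start0 + length, q))

    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "qvalue"])
    df["feature"] = feature
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def write_narrowpeak(path, peaks_df: pd.DataFrame) -> None:
    """Write a simulated peak table as narrowPeak (q stored as −log10)."""
    out = pd.DataFrame(
        {
            0: peaks_df["chrom"],
            1: peaks_df["start"].astype(int),
            2: peaks_df["end"].astype(int),
            3: [f"peak_{k}" for k in range(len(peaks_df))],
            4: 0,
            5: ".",
            6: 0.0,
            7: -1.0,
            8: -np.log10(peaks_df["qvalue"].astype(float)),
            9: -1,
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)
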