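"""Global-background interaction calling and per-bait local filtering.

Two layers of significance are implemented:

1. A self-contained random-ligation binomial caller. Under random ligation
   each fragment end participates in a ligation proportionally to its
   *visibility* r_i (its share of all read ends), so an unordered fragment
   pair (i, j) is expected with probability p_ij = 2·r_i·r_j. A pair
   observed n_ij times out of N total read pairs is scored by the upper
   binomial tail P(X >= n_ij), X ~ Binomial(N, p_ij), with
   Benjamini–Hochberg correction across all tested pairs. This flags
   contacts that cannot be explained by spurious ligation; it does not by
   itself separate functional loops from abundant-but-unremarkable contacts.

2. Per-bait local filtering (LF). For each bait, the −log10 q-values of
   its globally significant interactions are rounded to integer levels;
   the cumulative count of interactions at or above each level forms a
   decreasing curve whose initial steep segment is the bulk of the bait's
   contacts and whose shallow tail is the handful of markedly stronger
   ones. The bait-specific threshold is placed where the curve's absolute
   slope last exceeds 1, keeping only the tail.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .calls import CallSet
from .fragment_map import BaitMap

__all__ = [
    "ContactCounts",
    "VisibilityVector",
    "fragment_visibility",
    "binomial_interaction_test",
    "bh_adjust",
    "LFCurve",
    "cumulative_significance_curve",
    "lf_threshold",
    "local_filter",
    "read_contact_counts",
    "write_contact_counts",
]

ElbowRule = Literal["last-steep", "first-shallow"]


@dataclass
class ContactCounts:
    """Read-pair counts per unordered fragment pair (i, j), i != j."""

    counts: dict[tuple[int, int], int]

    def __post_init__(self) -> None:
        fixed: dict[tuple[int, int], int] = {}
        for (i, j), n in self.counts.items():
            if i == j:
                raise ValueError(f"self-pair ({i}, {i}) not allowed")
            if n < 1 or n != int(n):
                raise ValueError(f"count for pair ({i}, {j}) must be a positive integer")
            key = (min(i, j), max(i, j))
            fixed[key] = fixed.get(key, 0) + int(n)
        if not fixed:
            raise ValueError("empty contact table")
        self.counts = fixed

    @property
    def total(self) -> int:
        """Total number of read pairs N."""
        return sum(self.counts.values())

    def __len__(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class VisibilityVector:
    """Per-fragment end counts c_i and relative visibilities r_i = c_i/(2N)."""

    end_counts: dict[int, int]
    total_pairs: int

    @property
    def relative(self) -> dict[int, float]:
        denom = 2 * self.total_pairs
        return {i: c / denom for i, c in self.end_counts.items()}


def fragment_visibility(counts: ContactCounts) -> VisibilityVector:
    """Sum each fragment's read ends over all its pairs.

    Every read pair contributes one end to each of its two fragments, so
    sum(c_i) = 2N and the relative visibilities sum to 1.
    """
    ends: dict[int, int] = {}
    for (i, j), n in counts.counts.items():
        ends[i] = ends.get(i, 0) + n
        ends[j] = ends.get(j, 0) + n
    return VisibilityVector(ends, counts.total)


def bh_adjust(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in input order."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def binomial_interaction_test(
    counts: ContactCounts,
    bait_map: BaitMap | None = None,
) -> pd.DataFrame:
    """Score every observed pair against the random-ligation background.

    Returns a DataFrame (frag_i, frag_j, observed, expected_p, pvalue,
    qvalue) sorted by q-value, then p-value, then pair id. When a
    ``bait_map`` is given only bait-other pairs are tested: pairs without
    a baited end are never captured, and bait-bait pairs have a different
    capture probability and need a dedicated model.
    """
    vis = fragment_visibility(counts).relative
    N = counts.total
    keys = sorted(counts.counts)
    if bait_map is not None:
        keys = [
            (i, j) for (i, j) in keys
            if (i in bait_map) != (j in bait_map)  # exactly one baited end
        ]
        if not keys:
            raise ValueError("no bait-other pairs to test")
    n_obs = np.array([counts.counts[k] for k in keys], dtype=np.int64)
    p_exp = np.array([2.0 * vis[i] * vis[j] for i, j in keys], dtype=float)
    degenerate = p_exp >= 1.0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} pair(s) with expected probability >= 1; "
            "p-value set to 1",
            stacklevel=2,
        )
    pvals = np.where(degenerate, 1.0, stats.binom.sf(n_obs - 1, N, np.minimum(p_exp, 1.0)))
    out = pd.DataFrame(
        {
            "frag_i": [k[0] for k in keys],
            "frag_j": [k[1] for k in keys],
            "observed": n_obs,
            "expected_p": p_exp,
            "pvalue": pvals,
            "qvalue": bh_adjust(pvals),
        }
    )
    out = out.sort_values(
        ["qvalue", "pvalue", "frag_i", "frag_j"], kind="mergesort"
    ).reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# Per-bait local filtering


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


@dataclass(frozen=True)
class LFCurve:
    """Cumulative significance curve of one bait.

    ``levels`` are the distinct rounded −log10 q-values, ascending;
    ``cumulative[k]`` counts interactions with rounded level >= levels[k]
    (so it is non-increasing and starts at the bait's interaction count);
    ``slopes[k]`` is the finite difference between consecutive points.
    """

    levels: np.ndarray
    cumulative: np.ndarray
    slopes: np.ndarray


def cumulative_significance_curve(
    bait_qvalues: Iterable[float],
    round_digits: int = 0,
    q_floor: float = 1e-300,
) -> LFCurve:
    """Build the LF curve from one bait's q-values.

    q-values are floored at ``q_floor`` before taking −log10 (a q of
    exactly 0 would otherwise give an infinite level); −log10 q is rounded
    half away from zero to ``round_digits`` decimals (default integer
    levels; q = 1 maps to level 0).
    """
    q = np.asarray(list(bait_qvalues), dtype=float)
    if q.size == 0:
        raise ValueError("bait has no significant interactions")
    if np.any(q < 0) or np.any(q > 1):
        raise ValueError("q-values must lie in [0, 1]")
    q = np.maximum(q, q_floor)
    scale = 10.0 ** round_digits
    levels_all = _round_half_away(-np.log10(q) * scale) / scale
    levels, counts = np.unique(levels_all, return_counts=True)
    cumulative = counts[::-1].cumsum()[::-1]  # count at or above each level
    slopes = np.diff(cumulative) / np.diff(levels) if len(levels) > 1 else np.array([])
    return LFCurve(levels, cumulative.astype(np.int64), slopes)


def lf_threshold(curve: LFCurve, rule: ElbowRule = "last-steep") -> float:
    """Bait-specific significance level from the curve's elbow.

    ``last-steep`` (default): the threshold is the level just above the
    last segment whose absolute slope exceeds 1 — everything below the
    steep bulk is discarded. ``first-shallow``: the threshold is the level
    at which the absolute slope first drops to <= 1. With no slope above 1
    (including single-level curves) the lowest level is returned and the
    bait keeps all interactions.
    """
    v = curve.levels
    s = np.abs(curve.slopes)
    if s.size == 0 or not np.any(s > 1):
        return float(v[0])
    if rule == "last-steep":
        k_star = int(np.nonzero(s > 1)[0][-1])
        return float(v[k_star + 1])
    if rule == "first-shallow":
        shallow = np.nonzero(s <= 1)[0]
        if shallow.size == 0:  # steep throughout: only the top level survives
            return float(v[-1])
        return float(v[int(shallow[0])])
    raise ValueError(f"unknown elbow rule {rule!r}")


def local_filter(
    call_set: CallSet,
    rule: ElbowRule = "last-steep",
    round_digits: int = 0,
    q_floor: float = 1e-300,
) -> tuple[CallSet, dict[int, float]]:
    """Apply per-bait LF thresholds to a q-value call set.

    For each bait independently, interactions whose rounded −log10 q is
    at or above the bait's elbow threshold are retained. Returns the
    filtered subset and the per-bait thresholds (−log10 q scale).
    """
    if call_set.metric_kind != "qvalue":
        raise ValueError("local filtering is defined only for q-value call sets")
    df = call_set.df
    thresholds: dict[int, float] = {}
    keep = np.zeros(len(df), dtype=bool)
    scale = 10.0 ** round_digits
    for bait, idx in df.groupby("bait_id").groups.items():
        q = df.loc[idx, "metric_value"].to_numpy(dtype=float)
        curve = cumulative_significance_curve(q, round_digits, q_floor)
        t = lf_threshold(curve, rule)
        thresholds[int(bait)] = t
        levels = _round_half_away(-np.log10(np.maximum(q, q_floor)) * scale) / scale
        keep[df.index.get_indexer(idx)] = levels >= t
    filtered = replace(call_set, df=df.loc[keep].reset_index(drop=True))
    return filtered, thresholds


# ---------------------------------------------------------------------------
# Contact-count I/O


def read_contact_counts(path: str | Path) -> ContactCounts:
    """Read a 3-column TSV (frag_i, frag_j, count), no header."""
    df = pd.read_csv(path, sep="\t", header=None, names=["frag_i", "frag_j", "count"])
    return ContactCounts(
        {(int(r.frag_i), int(r.frag_j)): int(r.count) for r in df.itertuples(index=False)}
    )


def write_contact_counts(path: str | Path, counts: ContactCounts) -> None:
    rows = sorted(counts.counts.items())
    pd.DataFrame(
        [(i, j, n) for (i, j), n in rows]
    ).to_csv(path, sep="\t", header=False, index=False)
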