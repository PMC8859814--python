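"""Replicate reproducibility and functional-annotation metrics.

Significant interaction lists from any caller are compared across
replicates at restriction-fragment resolution: an interaction is
*reproducible* when the same bait contacts the same — or, under an
extension window, a nearby — other-end fragment in at least two
replicates. Other-end fragments may additionally be overlapped with
open-chromatin and histone-mark peak tracks (DHS, H3K27ac, H3K4me1,
H3K4me3) to estimate what fraction of calls touch putatively regulatory
sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .calls import CallSet, MetricSpec
from .fragment_map import FragmentMap

__all__ = [
    "Extension",
    "DEFAULT_PADS",
    "SupportTable",
    "support_table",
    "reproducibility_fraction",
    "joint_mean_pass",
    "PeakSet",
    "read_peaks",
    "functional_overlap_fraction",
]

DEFAULT_PADS = (0, 2500, 20000)


@dataclass(frozen=True)
class Extension:
    """Symmetric other-end extension in bases (0, 2500 or 20000 by default)."""

    pad: int = 0

    def __post_init__(self) -> None:
        if self.pad < 0:
            raise ValueError("pad must be >= 0")


@dataclass
class SupportTable:
    """Replicate support per unique (bait_id, oe_id) pair.

    ``support`` maps each pair in the union across replicates to the set
    of replicate labels containing a matching interaction under the
    extension used to build the table.
    """

    support: dict[tuple[int, int], frozenset[str]]
    replicates: tuple[str, ...]
    pad: int

    def __len__(self) -> int:
        return len(self.support)


def _extended_interval(
    frag_map: FragmentMap, frag_id: int, pad: int, chrom_lengths: Mapping[str, int]
) -> tuple[str, int, int]:
    f = frag_map.fragment(frag_id)
    return f.chrom, max(1, f.start - pad), min(chrom_lengths[f.chrom], f.end + pad)


def support_table(
    call_sets: Sequence[CallSet],
    pad: Extension | int,
    fragment_map: FragmentMap,
    include_bait_bait: bool = True,
) -> SupportTable:
    """Match interactions of the same bait across replicates.

    With pad = 0 two interactions match iff they share (bait_id, oe_id).
    With pad > 0 they match iff their other-end fragments, each extended
    by ``pad`` on both sides (clipped at chromosome ends), overlap by at
    least 1 bp. Support is propagated by single linkage within a bait:
    every member of a connected component of matching other ends is
    supported by all replicates present in the component. Replicate order
    is irrelevant.
    """
    pad = pad.pad if isinstance(pad, Extension) else int(pad)
    if len(call_sets) < 2:
        raise ValueError("need at least two replicates")
    maps = {id(cs.fragment_map) for cs in call_sets if cs.fragment_map is not None}
    if len(maps) > 1:
        raise ValueError("call sets reference different fragment maps")
    labels = tuple(cs.replicate for cs in call_sets)
    if len(set(labels)) != len(labels):
        raise ValueError("replicate labels must be unique")

    # rows: (bait, oe, replicate) — unique per replicate by CallSet invariant
    rows: list[tuple[int, int, str]] = []
    for cs in call_sets:
        df = cs.df
        if not include_bait_bait and (df["call_class"] == "bait-bait").any():
            df = df[df["call_class"] != "bait-bait"]
        rows.extend(
            (int(b), int(o), cs.replicate)
            for b, o in zip(df["bait_id"], df["oe_id"])
        )

    support: dict[tuple[int, int], set[str]] = {}
    if pad == 0:
        for b, o, rep in rows:
            support.setdefault((b, o), set()).add(rep)
    else:
        chrom_lengths = fragment_map.chrom_lengths
        by_bait: dict[int, list[tuple[int, str]]] = {}
        for b, o, rep in rows:
            by_bait.setdefault(b, []).append((o, rep))
        for bait, members in by_bait.items():
            comp = _single_linkage_components(
                members, fragment_map, pad, chrom_lengths
            )
            for oe_ids, reps in comp:
                for o in oe_ids:
                    support.setdefault((bait, o), set()).update(reps)
    return SupportTable(
        {k: frozenset(v) for k, v in support.items()}, labels, pad
    )


def _single_linkage_components(
    members: list[tuple[int, str]],
    fragment_map: FragmentMap,
    pad: int,
    chrom_lengths: Mapping[str, int],
) -> list[tuple[set[int], set[str]]]:
    """Union-find over extended other-end intervals of one bait.

    Because fragments are sorted and contiguous, overlapping extended
    intervals on one chromosome form runs in coordinate order, so a sweep
    over sorted intervals finds the single-linkage components in O(n log n).
    """
    uniq: dict[int, set[str]] = {}
    for o, rep in members:
        uniq.setdefault(o, set()).add(rep)
    ivs = []
    for o in uniq:
        chrom, s, e = _extended_interval(fragment_map, o, pad, chrom_lengths)
        ivs.append((chrom, s, e, o))
    ivs.sort()
    components: list[tuple[set[int], set[str]]] = []
    cur_ids: set[int] = set()
    cur_chrom, cur_end = None, -1
    for chrom, s, e, o in ivs:
        if chrom != cur_chrom or s > cur_end:  # touching (s == cur_end+?) requires >=1bp overlap
            if cur_ids:
                components.append((cur_ids, set().union(*(uniq[i] for i in cur_ids))))
            cur_ids, cur_chrom, cur_end = {o}, chrom, e
        else:
            cur_ids.add(o)
            cur_end = max(cur_end, e)
    if cur_ids:
        components.append((cur_ids, set().union(*(uniq[i] for i in cur_ids))))
    return components


def reproducibility_fraction(
    support: SupportTable,
    min_support: int = 2,
    denominator: Literal["union", "per-replicate-mean"] = "union",
) -> tuple[float, pd.DataFrame]:
    """Fraction of interactions supported by >= min_support replicates.

    With the default ``union`` denominator the fraction is over all unique
    (bait, other-end) pairs seen in any replicate; ``per-replicate-mean``
    divides the supported count by the mean per-replicate call count
    instead. Also returns per-bait fractions (union denominator).
    """
    if len(support) == 0:
        raise ValueError("empty support table")
    items = [(b, o, len(reps)) for (b, o), reps in support.support.items()]
    df = pd.DataFrame(items, columns=["bait_id", "oe_id", "n_support"])
    supported = df["n_support"] >= min_support
    if denominator == "union":
        overall = float(supported.mean())
    elif denominator == "per-replicate-mean":
        per_rep = [
            sum(1 for reps in support.support.values() if r in reps)
            for r in support.replicates
        ]
        overall = float(supported.sum() / np.mean(per_rep))
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    per_bait = (
        df.assign(supported=supported)
        .groupby("bait_id")["supported"]
        .agg(["mean", "size"])
        .rename(columns={"mean": "fraction", "size": "n_union"})
        .reset_index()
    )
    return overall, per_bait


def joint_mean_pass(
    full_tables: Sequence[pd.DataFrame],
    spec: MetricSpec,
    min_replicates: int = 2,
) -> tuple[pd.DataFrame, float]:
    """Joint mean-significance thresholding across replicates.

    ``full_tables`` are per-replicate *unthresholded* result tables with
    columns bait_id, oe_id, metric_value (every tested pair, not only the
    significant ones). A pair present in at least ``min_replicates``
    tables passes jointly when the mean of its metric over the replicates
    containing it satisfies ``spec``. Returns the joint-pass table and
    the relative increase of the joint-pass ∪ individually-significant
    union over the individually-significant union alone — undersampled
    interactions that sit just beyond the cutoff in single replicates are
    rescued when their replicate-mean clears it.
    """
    if len(full_tables) < 2:
        raise ValueError("need at least two replicate tables")
    frames = []
    for k, t in enumerate(full_tables):
        missing = {"bait_id", "oe_id", "metric_value"} - set(t.columns)
        if missing:
            raise ValueError(f"table {k} missing columns {sorted(missing)}")
        frames.append(t[["bait_id", "oe_id", "metric_value"]].assign(_rep=k))
    allt = pd.concat(frames, ignore_index=True)
    g = allt.groupby(["bait_id", "oe_id"])["metric_value"].agg(["mean", "size"])
    candidates = g[g["size"] >= min_replicates]
    passing = candidates[spec.passes(candidates["mean"].to_numpy())].reset_index()
    joint = set(zip(passing["bait_id"], passing["oe_id"]))

    indiv = allt[spec.passes(allt["metric_value"].to_numpy())]
    indiv_union = set(zip(indiv["bait_id"], indiv["oe_id"]))
    if not indiv_union:
        raise ValueError("no individually significant interactions under this cutoff")
    stat = (len(joint | indiv_union) - len(indiv_union)) / len(indiv_union)
    return passing.rename(columns={"mean": "mean_metric", "size": "n_replicates"}), stat


# ---------------------------------------------------------------------------
# Peaks


@dataclass
class PeakSet:
    """Chromatin feature intervals (1-based inclusive) with optional q-values."""

    feature: str
    df: pd.DataFrame = field(repr=False)  # chrom, start, end, qvalue (NaN if absent)
    _trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)

    def __len__(self) -> int:
        return len(self.df)

    def _tree(self, chrom: str) -> IntervalTree:
        if not self._trees:
            for c, g in self.df.groupby("chrom"):
                # IntervalTree is half-open; inclusive end -> +1
                self._trees[str(c)] = IntervalTree.from_tuples(
                    (int(s), int(e) + 1) for s, e in zip(g["start"], g["end"])
                )
        return self._trees.get(chrom, IntervalTree())

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """Any peak overlapping the 1-based inclusive interval by >= 1 bp."""
        return bool(self._tree(chrom).overlap(start, end + 1))


def read_peaks(
    path: str | Path,
    feature: str | None = None,
    q_cutoff: float = 0.05,
    q_encoding: Literal["neglog10", "raw"] = "neglog10",
) -> PeakSet:
    """Read a BED or narrowPeak file, keeping significant peaks.

    BED-family coordinates are 0-based half-open and converted to 1-based
    inclusive on read. narrowPeak stores the q-value in column 9 as
    −log10(q) with −1 meaning unavailable (``q_encoding="raw"`` reads it
    as a plain q-value instead). Peaks with q >= q_cutoff are dropped;
    when no q column exists all peaks are kept with a warning.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED needs at least 3 columns")
    starts = df[1].to_numpy()
    ends = df[2].to_numpy()
    if np.any(starts < 0) or np.any(ends <= starts):
        raise ValueError(f"{path}: malformed 0-based half-open coordinates")
    out = pd.DataFrame(
        {"chrom": df[0], "start": starts + 1, "end": ends, "qvalue": np.nan}
    )
    if df.shape[1] >= 9:  # narrowPeak: col 9 (index 8) is the q-value field
        col = df[8].to_numpy(dtype=float)
        q = np.where(col < 0, np.nan, col if q_encoding == "raw" else 10.0 ** (-col))
        out["qvalue"] = q
        keep = np.isnan(q) | (q < q_cutoff)
        if np.isnan(q).any():
            warnings.warn(f"{path}: peaks without q-value retained", stacklevel=2)
        out = out[keep].reset_index(drop=True)
    else:
        warnings.warn(f"{path}: no q-value column; all peaks retained", stacklevel=2)
    label = feature if feature is not None else path.stem
    return PeakSet(label, out)


def functional_overlap_fraction(
    call_set: CallSet,
    peaks: PeakSet | Sequence[PeakSet],
    pad: Extension | int,
    fragment_map: FragmentMap,
) -> tuple[float, pd.DataFrame]:
    """Fraction of unique non-baited other-end fragments touching a peak.

    Bait-other calls only (bait-bait ends are promoters by design and are
    excluded); each unique other-end fragment counts once, extended by
    ``pad`` on both sides and clipped at chromosome ends, overlapping by
    >= 1 bp. Returns the fraction for the first (or only) feature and a
    per-feature table.
    """
    pad = pad.pad if isinstance(pad, Extension) else int(pad)
    if len(call_set) == 0:
        raise ValueError("empty call set")
    peak_sets = [peaks] if isinstance(peaks, PeakSet) else list(peaks)
    df = call_set.df
    oe = sorted(set(df.loc[df["call_class"] == "bait-other", "oe_id"].astype(int)))
    chrom_lengths = fragment_map.chrom_lengths
    intervals = [_extended_interval(fragment_map, o, pad, chrom_lengths) for o in oe]
    rows = []
    for ps in peak_sets:
        hits = sum(ps.overlaps(c, s, e) for c, s, e in intervals)
        frac = hits / len(oe) if oe else 0.0
        rows.append((ps.feature, pad, len(oe), hits, frac))
    table = pd.DataFrame(
        rows, columns=["feature", "pad", "n_other_ends", "n_overlapping", "fraction"]
    )
    return float(table["fraction"].iloc[0]), table
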