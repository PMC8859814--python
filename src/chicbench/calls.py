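"""Per-replicate significant-interaction tables from any caller.

A :class:`CallSet` holds one tool's significant bait→other-end interactions
for one replicate, keyed by restriction-fragment pairs. Callers report
either q-values (pass if below a cutoff) or scores (pass if at or above a
cutoff); both are represented by :class:`MetricSpec`. Bait-bait pairs —
where the other end is itself a captured fragment — are stored unordered,
one record per pair, and are classified separately because both ends were
enriched by design.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .fragment_map import BaitMap, FragmentMap

__all__ = [
    "MetricSpec",
    "CallSet",
    "read_calls",
    "write_calls",
    "classify",
    "apply_threshold",
    "fraction_baits_with_interaction",
]

MetricKind = Literal["qvalue", "score"]

CALL_COLUMNS = ["bait_id", "oe_id", "metric_value", "call_class"]


@dataclass(frozen=True)
class MetricSpec:
    """Significance metric and cutoff: q-values pass if value < cutoff,
    scores pass if value >= cutoff."""

    kind: MetricKind
    cutoff: float

    def __post_init__(self) -> None:
        if self.kind == "qvalue":
            if not 0 < self.cutoff <= 1:
                raise ValueError(f"q-value cutoff must be in (0, 1], got {self.cutoff}")
        elif self.kind == "score":
            if self.cutoff < 0:
                raise ValueError(f"score cutoff must be >= 0, got {self.cutoff}")
        else:
            raise ValueError(f"unknown metric kind {self.kind!r}")

    def passes(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.kind == "qvalue":
            return values < self.cutoff
        return values >= self.cutoff

    def stricter_than(self, other: "MetricSpec") -> bool:
        if self.kind != other.kind:
            raise ValueError("cannot compare cutoffs of different metric kinds")
        return self.cutoff < other.cutoff if self.kind == "qvalue" else self.cutoff > other.cutoff


def _canonical_pairs(bait_id: np.ndarray, oe_id: np.ndarray, bait_ids: frozenset[int]):
    """Canonicalize bait-bait pairs to (min, max) so they are unordered."""
    bait_id = np.asarray(bait_id, dtype=np.int64)
    oe_id = np.asarray(oe_id, dtype=np.int64)
    oe_is_bait = np.isin(oe_id, np.fromiter(bait_ids, dtype=np.int64, count=len(bait_ids)))
    lo = np.minimum(bait_id, oe_id)
    hi = np.maximum(bait_id, oe_id)
    b = np.where(oe_is_bait, lo, bait_id)
    o = np.where(oe_is_bait, hi, oe_id)
    return b, o, oe_is_bait


@dataclass
class CallSet:
    """One tool's significant interactions for one replicate.

    ``df`` has columns bait_id, oe_id, metric_value, call_class
    ("bait-bait", "bait-other" or "" before classification); (bait_id,
    oe_id) is unique, with bait-bait pairs stored as (min, max).
    """

    tool: str
    replicate: str
    metric_kind: MetricKind
    df: pd.DataFrame = field(repr=False)
    fragment_map: FragmentMap | None = field(default=None, repr=False)
    bait_map: BaitMap | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in CALL_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"CallSet df missing columns {missing}")
        if self.metric_kind == "qvalue":
            v = self.df["metric_value"].to_numpy(dtype=float)
            if v.size and (v.min() < 0 or v.max() > 1):
                raise ValueError("q-values must lie in [0, 1]")
        if self.df.duplicated(["bait_id", "oe_id"]).any():
            raise ValueError("duplicate (bait_id, oe_id) pairs in CallSet")

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[int, int, float]],
        tool: str = "tool",
        replicate: str = "rep1",
        metric_kind: MetricKind = "qvalue",
        fragment_map: FragmentMap | None = None,
        bait_map: BaitMap | None = None,
    ) -> "CallSet":
        """Build a CallSet from (bait_id, oe_id, metric_value) triples,
        collapsing duplicates to the most significant value."""
        rows = list(records)
        df = pd.DataFrame(rows, columns=["bait_id", "oe_id", "metric_value"])
        df["bait_id"] = df["bait_id"].astype(np.int64)
        df["oe_id"] = df["oe_id"].astype(np.int64)
        df["call_class"] = ""
        cs = cls(tool, replicate, metric_kind, _dedupe(df, metric_kind),
                 fragment_map=fragment_map, bait_map=bait_map)
        if bait_map is not None:
            return classify(cs, bait_map)
        return cs

    def pairs(self) -> set[tuple[int, int]]:
        return set(zip(self.df["bait_id"].tolist(), self.df["oe_id"].tolist()))


def _dedupe(df: pd.DataFrame, metric_kind: MetricKind) -> pd.DataFrame:
    """Collapse duplicate pairs keeping the most significant value
    (min q-value / max score)."""
    keep_min = metric_kind == "qvalue"
    agg = "min" if keep_min else "max"
    out = (
        df.groupby(["bait_id", "oe_id"], as_index=False, sort=True)
        .agg(metric_value=("metric_value", agg), call_class=("call_class", "first"))
    )
    return out[CALL_COLUMNS].reset_index(drop=True)


def read_calls(
    path: str | Path,
    fragment_map: FragmentMap,
    bait_map: BaitMap,
    tool: str,
    replicate: str,
) -> CallSet:
    """Read a generic 8-column call TSV and resolve coordinates to fragments.

    Required header columns: bait_chrom, bait_start, bait_end, oe_chrom,
    oe_start, oe_end, metric_kind, metric_value (1-based inclusive
    coordinates). Every interval must match a fragment exactly; failures
    are reported with the offending row number. Duplicate pairs are
    collapsed keeping the most significant value.
    """
    df = pd.read_csv(path, sep="\t", dtype={"bait_chrom": str, "oe_chrom": str})
    required = [
        "bait_chrom", "bait_start", "bait_end",
        "oe_chrom", "oe_start", "oe_end", "metric_kind", "metric_value",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"call table {path} missing columns {missing}")
    kinds = set(df["metric_kind"].unique())
    if len(kinds) > 1:
        raise ValueError(f"mixed metric kinds in one file: {sorted(kinds)}")
    kind = kinds.pop() if kinds else "qvalue"
    if kind not in ("qvalue", "score"):
        raise ValueError(f"unknown metric kind {kind!r}")

    bait_ids, oe_ids = [], []
    for idx, r in enumerate(df.itertuples(index=False)):
        try:
            bid = fragment_map.resolve_exact(r.bait_chrom, int(r.bait_start), int(r.bait_end))
            oid = fragment_map.resolve_exact(r.oe_chrom, int(r.oe_start), int(r.oe_end))
        except KeyError as exc:
            raise ValueError(f"row {idx + 1} of {path}: {exc}") from None
        if bid not in bait_map:
            raise ValueError(f"row {idx + 1} of {path}: bait fragment {bid} is not baited")
        if bid == oid:
            raise ValueError(f"row {idx + 1} of {path}: bait and other end are the same fragment")
        bait_ids.append(bid)
        oe_ids.append(oid)

    out = pd.DataFrame(
        {
            "bait_id": np.array(bait_ids, dtype=np.int64),
            "oe_id": np.array(oe_ids, dtype=np.int64),
            "metric_value": df["metric_value"].to_numpy(dtype=float),
            "call_class": "",
        }
    )
    b, o, _ = _canonical_pairs(out["bait_id"], out["oe_id"], bait_map.frag_ids)
    out["bait_id"], out["oe_id"] = b, o
    cs = CallSet(tool, replicate, kind, _dedupe(out, kind),
                 fragment_map=fragment_map, bait_map=bait_map)
    return classify(cs, bait_map)


def write_calls(path: str | Path, call_set: CallSet, fragment_map: FragmentMap) -> None:
    """Write the generic 8-column call TSV (canonical pair order)."""
    rows = []
    for r in call_set.df.sort_values(["bait_id", "oe_id"]).itertuples(index=False):
        b = fragment_map.fragment(int(r.bait_id))
        o = fragment_map.fragment(int(r.oe_id))
        rows.append(
            (b.chrom, b.start, b.end, o.chrom, o.start, o.end,
             call_set.metric_kind, r.metric_value)
        )
    pd.DataFrame(
        rows,
        columns=[
            "bait_chrom", "bait_start", "bait_end",
            "oe_chrom", "oe_start", "oe_end", "metric_kind", "metric_value",
        ],
    ).to_csv(path, sep="\t", index=False)


def classify(call_set: CallSet, bait_map: BaitMap) -> CallSet:
    """Fill call_class: bait-bait iff the other end is baited, else
    bait-other; bait-bait pairs are canonicalized to unordered (min, max)
    and collapsed. Idempotent and order-independent."""
    df = call_set.df.copy()
    b, o, oe_is_bait = _canonical_pairs(
        df["bait_id"].to_numpy(), df["oe_id"].to_numpy(), bait_map.frag_ids
    )
    df["bait_id"], df["oe_id"] = b, o
    df["call_class"] = np.where(oe_is_bait, "bait-bait", "bait-other")
    df = _dedupe(df, call_set.metric_kind)
    # _dedupe keeps the first class label within a group; recompute for safety
    oe_is_bait2 = df["oe_id"].isin(list(bait_map.frag_ids))
    df["call_class"] = np.where(oe_is_bait2, "bait-bait", "bait-other")
    return replace(call_set, df=df, bait_map=bait_map)


def apply_threshold(call_set: CallSet, spec: MetricSpec) -> CallSet:
    """Subset to calls passing the cutoff; stricter cutoffs give nested
    subsets."""
    if spec.kind != call_set.metric_kind:
        raise ValueError(
            f"metric kind mismatch: spec is {spec.kind!r}, "
            f"call set is {call_set.metric_kind!r}"
        )
    mask = spec.passes(call_set.df["metric_value"].to_numpy())
    return replace(call_set, df=call_set.df.loc[mask].reset_index(drop=True))


def fraction_baits_with_interaction(call_set: CallSet, bait_map: BaitMap) -> float:
    """Fraction of baited fragments appearing in at least one call.

    A bait counts if it appears as the bait of any call or as the partner
    of a bait-bait call.
    """
    if len(bait_map) == 0:
        raise ValueError("empty bait map")
    seen = set(call_set.df["bait_id"].tolist())
    seen |= {o for o in call_set.df["oe_id"].tolist() if o in bait_map}
    return len(seen & set(bait_map.frag_ids)) / len(bait_map)
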