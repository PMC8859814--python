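"""Restriction fragment maps, bait maps and in-silico digestion.

Capture Hi-C works at restriction-fragment resolution: every read pair is
assigned to the pair of fragments produced by digesting the genome with the
library's enzyme (a 6-cutter such as HindIII, or a 4-cutter such as MboI).
This module builds that coordinate system — the *rmap* listing all fragments
and the *baitmap* listing the captured subset — and implements the probe
eligibility rules used when designing 120-mer capture baits.

All internal coordinates are 1-based inclusive (the rmap convention);
0-based inputs are converted at the boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Enzyme",
    "HINDIII",
    "MBOI",
    "ENZYMES",
    "Fragment",
    "FragmentMap",
    "BaitMap",
    "BaitDesignRules",
    "ProbeCandidate",
    "digest_sequence",
    "digest_genome",
    "read_fasta",
    "read_rmap",
    "write_rmap",
    "read_baitmap",
    "write_baitmap",
    "bait_eligible",
]

_VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme defined by its recognition site and cut offset.

    ``cut_offset`` is the number of bases from the start of the recognition
    sequence to the cut position on the top strand: HindIII (A^AGCTT) has
    offset 1, MboI (^GATC) offset 0.
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        rec = self.recognition.upper()
        if len(rec) < 4:
            raise ValueError(f"recognition site too short: {rec!r}")
        if set(rec) - set("ACGT"):
            raise ValueError(f"recognition must be ACGT only, got {rec!r}")
        if not 0 <= self.cut_offset <= len(rec):
            raise ValueError(
                f"cut_offset {self.cut_offset} outside recognition of length {len(rec)}"
            )
        object.__setattr__(self, "recognition", rec)


HINDIII = Enzyme("HindIII", "AAGCTT", 1)
MBOI = Enzyme("MboI", "GATC", 0)
ENZYMES: Mapping[str, Enzyme] = {"HindIII": HINDIII, "MboI": MBOI}


@dataclass(frozen=True)
class Fragment:
    """One restriction fragment; coordinates 1-based inclusive."""

    chrom: str
    start: int
    end: int
    frag_id: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"invalid fragment interval [{self.start}, {self.end}] on {self.chrom}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class FragmentMap:
    """Ordered restriction fragments partitioning each chromosome.

    Fragments on one chromosome are contiguous (each start = previous
    end + 1), begin at 1 and end at the chromosome length; ``frag_id`` is
    assigned genome-wide in chromosome-then-coordinate order.
    """

    def __init__(self, fragments: Sequence[Fragment]):
        if not fragments:
            raise ValueError("FragmentMap requires at least one fragment")
        self._df = pd.DataFrame(
            {
                "chrom": [f.chrom for f in fragments],
                "start": np.array([f.start for f in fragments], dtype=np.int64),
                "end": np.array([f.end for f in fragments], dtype=np.int64),
                "frag_id": np.array([f.frag_id for f in fragments], dtype=np.int64),
            }
        )
        self._validate()
        self._by_id = {
            int(r.frag_id): (r.chrom, int(r.start), int(r.end))
            for r in self._df.itertuples(index=False)
        }
        # per-chromosome coordinate arrays for O(log n) positional lookup
        self._chrom_index: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {
            str(c): (
                g["start"].to_numpy(),
                g["end"].to_numpy(),
                g["frag_id"].to_numpy(),
            )
            for c, g in self._df.groupby("chrom", sort=False)
        }

    def _validate(self) -> None:
        ids = self._df["frag_id"].to_numpy()
        if np.any(np.diff(ids) <= 0):
            k = int(np.argmax(np.diff(ids) <= 0))
            raise ValueError(f"frag_ids not strictly increasing at row {k + 1}")
        for chrom, g in self._df.groupby("chrom", sort=False):
            starts = g["start"].to_numpy()
            ends = g["end"].to_numpy()
            if starts[0] != 1:
                raise ValueError(f"{chrom}: first fragment starts at {starts[0]}, expected 1")
            gaps = starts[1:] - ends[:-1]
            bad = np.nonzero(gaps != 1)[0]
            if bad.size:
                i = int(bad[0])
                kind = "gap" if gaps[i] > 1 else "overlap"
                raise ValueError(
                    f"{chrom}: {kind} between fragments ending {ends[i]} and starting {starts[i + 1]}"
                )

    @property
    def df(self) -> pd.DataFrame:
        """The map as a DataFrame (chrom, start, end, frag_id)."""
        return self._df

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: int(g["end"].iloc[-1]) for c, g in self._df.groupby("chrom", sort=False)}

    @property
    def frag_ids(self) -> np.ndarray:
        return self._df["frag_id"].to_numpy()

    def __len__(self) -> int:
        return len(self._df)

    def __iter__(self) -> Iterator[Fragment]:
        for row in self._df.itertuples(index=False):
            yield Fragment(row.chrom, int(row.start), int(row.end), int(row.frag_id))

    def __contains__(self, frag_id: int) -> bool:
        return int(frag_id) in self._by_id

    def fragment(self, frag_id: int) -> Fragment:
        try:
            chrom, start, end = self._by_id[int(frag_id)]
        except KeyError:
            raise KeyError(f"frag_id {frag_id} not in FragmentMap") from None
        return Fragment(str(chrom), start, end, int(frag_id))

    def locate(self, chrom: str, pos: int) -> Fragment:
        """Fragment containing a 1-based position."""
        g = self._chrom_index.get(chrom)
        if g is None:
            raise KeyError(f"chromosome {chrom!r} not in FragmentMap")
        starts, ends, ids = g
        if not 1 <= pos <= int(ends[-1]):
            raise ValueError(f"position {pos} outside {chrom} [1, {int(ends[-1])}]")
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        return Fragment(chrom, int(starts[i]), int(ends[i]), int(ids[i]))

    def resolve_exact(self, chrom: str, start: int, end: int) -> int:
        """frag_id of the fragment matching the interval exactly, else KeyError."""
        frag = self.locate(chrom, start)
        if frag.start != start or frag.end != end:
            raise KeyError(f"no fragment exactly matching {chrom}:{start}-{end}")
        return frag.frag_id

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FragmentMap):
            return NotImplemented
        return self._df.equals(other._df)


@dataclass
class BaitMap:
    """The baited (captured) subset of a FragmentMap, with annotations."""

    annotations: dict[int, str] = field(default_factory=dict)

    @property
    def frag_ids(self) -> frozenset[int]:
        return frozenset(self.annotations)

    def __contains__(self, frag_id: int) -> bool:
        return frag_id in self.annotations

    def __len__(self) -> int:
        return len(self.annotations)

    @classmethod
    def from_ids(cls, frag_ids, fragment_map: FragmentMap | None = None) -> "BaitMap":
        ann = {int(i): f"bait_{int(i)}" for i in frag_ids}
        bm = cls(ann)
        if fragment_map is not None:
            bm.validate(fragment_map)
        return bm

    def validate(self, fragment_map: FragmentMap) -> None:
        missing = [i for i in self.annotations if i not in fragment_map]
        if missing:
            raise ValueError(f"baited frag_ids absent from FragmentMap: {missing[:5]}")


@dataclass(frozen=True)
class BaitDesignRules:
    """Capture-probe design constraints for bait eligibility.

    Defaults follow the promoter-capture design: 120-mer probes anchored
    within 330 bp of a fragment terminus, 25–65% GC, and at most two
    consecutive N bases.
    """

    probe_length: int = 120
    gc_min: float = 0.25
    gc_max: float = 0.65
    max_terminus_distance: int = 330
    max_consecutive_n: int = 2

    def __post_init__(self) -> None:
        if not 0 <= self.gc_min < self.gc_max <= 1:
            raise ValueError("require 0 <= gc_min < gc_max <= 1")
        if self.probe_length <= 0:
            raise ValueError("probe_length must be positive")


@dataclass(frozen=True)
class ProbeCandidate:
    """A passing probe window, in fragment-local 1-based coordinates."""

    start: int
    end: int
    terminus: str  # "left" or "right"
    gc: float


def _check_sequence(seq: str) -> str:
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    bad = set(seq) - _VALID_BASES
    if bad:
        raise ValueError(f"non-ACGTN characters in sequence: {sorted(bad)}")
    return seq


def find_cut_sites(seq: str, enzyme: Enzyme) -> list[int]:
    """1-based cut positions: each is the start of the fragment created.

    The scan advances one base at a time so overlapping recognition matches
    are all found. N never matches. Cuts at position 1 or beyond the
    sequence end are dropped (they would create an empty fragment).
    """
    seq = _check_sequence(seq)
    rec = enzyme.recognition
    sites: list[int] = []
    i = seq.find(rec)
    while i != -1:
        cut = i + enzyme.cut_offset + 1  # 1-based start of the downstream fragment
        if 1 < cut <= len(seq):
            sites.append(cut)
        i = seq.find(rec, i + 1)
    return sites


def digest_sequence(
    seq: str, chrom: str, enzyme: Enzyme, first_id: int = 1
) -> list[Fragment]:
    """Digest one chromosome sequence into an ordered fragment list."""
    seq = _check_sequence(seq)
    cuts = find_cut_sites(seq, enzyme)
    bounds = [1, *cuts, len(seq) + 1]
    return [
        Fragment(chrom, bounds[k], bounds[k + 1] - 1, first_id + k)
        for k in range(len(bounds) - 1)
    ]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (wrapped or unwrapped) multi-record FASTA into an ordered dict."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: dict[str, list[str]] = {}
    name: str | None = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                if name in records:
                    raise ValueError(f"duplicate chromosome name {name!r} in {path}")
                records[name] = []
            else:
                if name is None:
                    raise ValueError(f"sequence before first header in {path}")
                records[name].append(line)
    if not records:
        raise ValueError(f"no records in {path}")
    return {n: "".join(parts) for n, parts in records.items()}


def write_fasta(path: str | Path, genome: Mapping[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def digest_genome(
    fasta: str | Path | Mapping[str, str], enzyme: Enzyme
) -> FragmentMap:
    """Digest every chromosome of a FASTA (path or name→sequence mapping).

    frag_ids are assigned genome-wide in input order, starting at 1.
    """
    genome = fasta if isinstance(fasta, Mapping) else read_fasta(fasta)
    fragments: list[Fragment] = []
    next_id = 1
    for chrom, seq in genome.items():
        frags = digest_sequence(seq, chrom, enzyme, first_id=next_id)
        fragments.extend(frags)
        next_id += len(frags)
    return FragmentMap(fragments)


def read_rmap(path: str | Path, zero_based: bool = False) -> FragmentMap:
    """Read a 4-column rmap TSV (chrom, start, end, frag_id), no header.

    ``zero_based=True`` imports 0-based half-open digest profiles (as
    supplied by some pipelines) by shifting starts by +1.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "frag_id"],
        dtype={"chrom": str},
    )
    for col in ("start", "end", "frag_id"):
        if not pd.api.types.is_integer_dtype(df[col]):
            raise ValueError(f"non-integer values in rmap column {col!r}")
    if zero_based:
        df["start"] = df["start"] + 1
    frags = [
        Fragment(r.chrom, int(r.start), int(r.end), int(r.frag_id))
        for r in df.itertuples(index=False)
    ]
    return FragmentMap(frags)


def write_rmap(path: str | Path, fragment_map: FragmentMap) -> None:
    fragment_map.df.sort_values("frag_id").to_csv(
        path, sep="\t", header=False, index=False
    )


def read_baitmap(path: str | Path, fragment_map: FragmentMap) -> BaitMap:
    """Read a 5-column baitmap TSV (chrom, start, end, frag_id, annotation).

    Coordinates must match the FragmentMap row with the same frag_id.
    """
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "frag_id", "annotation"],
        dtype={"chrom": str, "annotation": str},
    )
    ann: dict[int, str] = {}
    for r in df.itertuples(index=False):
        fid = int(r.frag_id)
        if fid not in fragment_map:
            raise ValueError(f"baitmap frag_id {fid} absent from FragmentMap")
        frag = fragment_map.fragment(fid)
        if (frag.chrom, frag.start, frag.end) != (r.chrom, int(r.start), int(r.end)):
            raise ValueError(
                f"baitmap coordinates {r.chrom}:{r.start}-{r.end} do not match "
                f"FragmentMap fragment {fid} ({frag.chrom}:{frag.start}-{frag.end})"
            )
        ann[fid] = str(r.annotation)
    return BaitMap(ann)


def write_baitmap(path: str | Path, bait_map: BaitMap, fragment_map: FragmentMap) -> None:
    rows = []
    for fid in sorted(bait_map.annotations):
        frag = fragment_map.fragment(fid)
        rows.append((frag.chrom, frag.start, frag.end, fid, bait_map.annotations[fid]))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def _max_run_of_n(window: str) -> int:
    best = run = 0
    for base in window:
        run = run + 1 if base == "N" else 0
        best = max(best, run)
    return best


def _window_ok(window: str, rules: BaitDesignRules) -> tuple[bool, float]:
    gc = (window.count("G") + window.count("C")) / len(window)
    ok = rules.gc_min <= gc <= rules.gc_max and _max_run_of_n(window) <= rules.max_consecutive_n
    return ok, gc


def bait_eligible(
    fragment: Fragment, seq: str, rules: BaitDesignRules = BaitDesignRules()
) -> tuple[bool, list[ProbeCandidate]]:
    """Decide whether a fragment admits a capture probe at either terminus.

    A candidate is a ``probe_length`` window whose start (left terminus) or
    end (right terminus) lies within ``max_terminus_distance`` of that
    terminus, with GC in [gc_min, gc_max] and at most ``max_consecutive_n``
    consecutive Ns. The window closest to its terminus wins; at most one
    candidate per end is returned. Fragments shorter than the probe are
    ineligible, not an error.
    """
    seq = _check_sequence(seq)
    if len(seq) != fragment.length:
        raise ValueError(
            f"sequence length {len(seq)} != fragment length {fragment.length}"
        )
    L, P = len(seq), rules.probe_length
    if L < P:
        return False, []
    candidates: list[ProbeCandidate] = []
    max_off = min(rules.max_terminus_distance, L - P)
    for off in range(0, max_off + 1):  # left terminus: window start at off
        ok, gc = _window_ok(seq[off : off + P], rules)
        if ok:
            candidates.append(ProbeCandidate(off + 1, off + P, "left", gc))
            break
    for off in range(0, max_off + 1):  # right terminus: window end at L - off
        ok, gc = _window_ok(seq[L - off - P : L - off], rules)
        if ok:
            candidates.append(ProbeCandidate(L - off - P + 1, L - off, "right", gc))
            break
    return bool(candidates), candidates
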