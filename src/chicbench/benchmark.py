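"""Benchmark orchestration: caller → LF → metrics across tools and replicates.

`run_benchmark` drives the whole comparison the toolkit exists for: for
each tool's per-replicate call tables it sweeps significance thresholds,
measures replicate reproducibility at several extension windows, overlaps
other ends with peak tracks, and applies joint-mean thresholding — then
writes the report tables and a machine-readable run manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .calls import (
    CallSet,
    MetricSpec,
    apply_threshold,
    fraction_baits_with_interaction,
    read_calls,
)
from .fragment_map import BaitMap, FragmentMap, read_baitmap, read_rmap
from .metrics import (
    DEFAULT_PADS,
    PeakSet,
    functional_overlap_fraction,
    joint_mean_pass,
    read_peaks,
    reproducibility_fraction,
    support_table,
)
from .significance import local_filter

__all__ = ["BenchmarkConfig", "ToolEntry", "run_benchmark", "load_config"]

DEFAULT_QVALUE_SWEEP = (0.05, 0.01, 0.001)
DEFAULT_SCORE_SWEEP = (5.0, 10.0, 15.0)


@dataclass
class ToolEntry:
    label: str
    call_paths: list[str]
    metric_kind: str = "qvalue"
    local_filter: bool = False


@dataclass
class BenchmarkConfig:
    rmap: str
    baitmap: str
    tools: list[ToolEntry]
    qvalue_sweep: tuple[float, ...] = DEFAULT_QVALUE_SWEEP
    score_sweep: tuple[float, ...] = DEFAULT_SCORE_SWEEP
    pads: tuple[int, ...] = DEFAULT_PADS
    peak_paths: Mapping[str, str] = field(default_factory=dict)
    min_support: int = 2
    outdir: str = "benchmark_out"

    def __post_init__(self) -> None:
        if not self.tools:
            raise ValueError("config needs at least one tool")
        for t in self.tools:
            if len(t.call_paths) < 2:
                raise ValueError(f"tool {t.label!r} needs >= 2 replicates")
            if t.local_filter and t.metric_kind != "qvalue":
                raise ValueError(
                    f"tool {t.label!r}: local filtering needs q-value calls"
                )


def load_config(path: str | Path) -> BenchmarkConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    tools = [ToolEntry(**t) for t in raw.pop("tools")]
    return BenchmarkConfig(tools=tools, **raw)


def _sweep_for(kind: str, config: BenchmarkConfig) -> list[MetricSpec]:
    cuts = config.qvalue_sweep if kind == "qvalue" else config.score_sweep
    return [MetricSpec(kind, c) for c in cuts]


def run_benchmark(config: BenchmarkConfig) -> dict[str, pd.DataFrame]:
    """Run the full comparison and write report TSVs to ``config.outdir``.

    Tables: ``counts`` (per tool × threshold: interaction count, bait-bait
    proportion, fraction of baits with >= 1 interaction, percent decrease
    vs the loosest cutoff), ``reproducibility`` (per tool × pad),
    ``functional`` (per tool × feature × pad, with other-end counts), and
    ``manifest.json``. Deterministic given identical inputs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    fragment_map = read_rmap(config.rmap)
    bait_map = read_baitmap(config.baitmap, fragment_map)
    peaks = [
        read_peaks(p, feature=name) for name, p in sorted(config.peak_paths.items())
    ]

    count_rows, repro_rows, func_rows, joint_rows = [], [], [], []
    for tool in config.tools:
        call_sets = [
            read_calls(p, fragment_map, bait_map, tool.label, f"rep{k + 1}")
            for k, p in enumerate(tool.call_paths)
        ]
        if tool.local_filter:
            call_sets = [local_filter(cs)[0] for cs in call_sets]

        sweep = _sweep_for(tool.metric_kind, config)
        base_counts: float | None = None
        for spec in sweep:
            thresholded = [apply_threshold(cs, spec) for cs in call_sets]
            n_total = sum(len(cs) for cs in thresholded)
            n_bb = sum(int((cs.df["call_class"] == "bait-bait").sum()) for cs in thresholded)
            fracs = [
                fraction_baits_with_interaction(cs, bait_map) for cs in thresholded
            ]
            if base_counts is None:
                base_counts = n_total
            pct_decrease = (
                100.0 * (base_counts - n_total) / base_counts if base_counts else 0.0
            )
            count_rows.append(
                (
                    tool.label, spec.kind, spec.cutoff, n_total,
                    n_bb / n_total if n_total else 0.0,
                    sum(fracs) / len(fracs), pct_decrease,
                )
            )

        loosest = _sweep_for(tool.metric_kind, config)[0]
        thresholded = [apply_threshold(cs, loosest) for cs in call_sets]
        for pad in config.pads:
            st = support_table(thresholded, pad, fragment_map)
            frac, _ = reproducibility_fraction(st, config.min_support)
            repro_rows.append((tool.label, pad, len(st), frac))
        # joint mean over the supplied tables (full tables when the caller
        # exports unthresholded results; a lower bound otherwise)
        try:
            _, stat = joint_mean_pass(
                [cs.df.rename(columns={}) for cs in call_sets], loosest,
                min_replicates=config.min_support,
            )
            joint_rows.append((tool.label, loosest.kind, loosest.cutoff, stat))
        except ValueError:
            pass
        for ps in peaks:
            for pad in config.pads:
                for cs in thresholded:
                    _, table = functional_overlap_fraction(cs, ps, pad, fragment_map)
                    func_rows.append(
                        (
                            tool.label, cs.replicate, ps.feature, pad,
                            int(table["n_other_ends"].iloc[0]),
                            int(table["n_overlapping"].iloc[0]),
                            float(table["fraction"].iloc[0]),
                        )
                    )

    tables = {
        "counts": pd.DataFrame(
            count_rows,
            columns=[
                "tool", "metric", "cutoff", "n_interactions",
                "bait_bait_fraction", "frac_baits_with_interaction",
                "pct_decrease_vs_loosest",
            ],
        ),
        "reproducibility": pd.DataFrame(
            repro_rows, columns=["tool", "pad", "n_union", "fraction_reproducible"]
        ),
        "functional": pd.DataFrame(
            func_rows,
            columns=[
                "tool", "replicate", "feature", "pad",
                "n_other_ends", "n_overlapping", "fraction",
            ],
        ),
        "joint_mean": pd.DataFrame(
            joint_rows, columns=["tool", "metric", "cutoff", "relative_increase"]
        ),
    }
    for name, df in tables.items():
        df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)

    manifest = {
        "version": __version__,
        "rmap": config.rmap,
        "baitmap": config.baitmap,
        "tools": [t.label for t in config.tools],
        "qvalue_sweep": list(config.qvalue_sweep),
        "score_sweep": list(config.score_sweep),
        "pads": list(config.pads),
        "peaks": dict(config.peak_paths),
        "config_hash": _config_hash(config),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return tables


def _config_hash(config: BenchmarkConfig) -> str:
    blob = json.dumps(
        {
            "rmap": config.rmap,
            "baitmap": config.baitmap,
            "tools": [
                (t.label, t.call_paths, t.metric_kind, t.local_filter)
                for t in config.tools
            ],
            "qvalue_sweep": list(config.qvalue_sweep),
            "score_sweep": list(config.score_sweep),
            "pads": list(config.pads),
            "peaks": dict(config.peak_paths),
            "min_support": config.min_support,
        },
        sort_keys=True,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
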