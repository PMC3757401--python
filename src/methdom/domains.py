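"""Fold-change probe classification, domain segmentation, and summaries.

Thresholds follow the strict reading of the calling rule: fold change > 2 is
hypomethylated, < 0.5 hypermethylated, everything else (including the exact
boundary values) neutral.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from methdom.genome import DomainInterval, HYPO as TRUTH_HYPO


class ProbeLabel(str, Enum):
    HYPO = "HYPO"
    HYPER = "HYPER"
    NEUTRAL = "NEUTRAL"


@dataclass(frozen=True)
class ProbeCall:
    probe_id: str
    label: ProbeLabel


@dataclass(frozen=True)
class DomainCall:
    chrom: str
    start: int
    end: int
    label: ProbeLabel
    n_probes: int
    mean_fold_change: float

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"domain end must exceed start: {self}")
        if self.label is ProbeLabel.NEUTRAL:
            raise ValueError("NEUTRAL never forms a domain")


@dataclass(frozen=True)
class ChromosomeSummary:
    chrom: str
    n_hypo_probes: int
    n_hyper_probes: int
    hypo_to_hyper_ratio: float  # inf when hyper == 0 < hypo; nan when both zero
    ratio_defined: bool


@dataclass(frozen=True)
class RecoveryMetrics:
    """Base-pair Jaccard against truth plus per-truth-domain boundary offsets."""

    jaccard: float
    boundary_offsets: Tuple[Tuple[float, float], ...]  # (|start delta|, |end delta|) per truth domain

    @property
    def max_boundary_offset(self) -> float:
        if not self.boundary_offsets:
            return 0.0
        return max(max(o) for o in self.boundary_offsets)


def classify_probes(
    grid: pd.DataFrame, hypo_cut: float = 2.0, hyper_cut: float = 0.5
) -> List[ProbeCall]:
    """One label per probe from its fold change; strict inequalities."""
    if not hyper_cut < hypo_cut:
        raise ValueError(f"require hyper_cut < hypo_cut, got {hyper_cut} >= {hypo_cut}")
    fold = grid["fold_change"].to_numpy(float)
    bad = ~np.isfinite(fold)
    if bad.any():
        probe = grid["id"].iloc[int(np.flatnonzero(bad)[0])]
        raise ValueError(f"non-finite fold change at probe {probe!r}")
    calls = []
    for pid, fc in zip(grid["id"], fold):
        if fc > hypo_cut:
            label = ProbeLabel.HYPO
        elif fc < hyper_cut:
            label = ProbeLabel.HYPER
        else:
            label = ProbeLabel.NEUTRAL
        calls.append(ProbeCall(pid, label))
    return calls


def calls_to_frame(calls: Sequence[ProbeCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {"id": [c.probe_id for c in calls], "label": [c.label.value for c in calls]}
    )


def segment(
    calls: Sequence[ProbeCall],
    grid: pd.DataFrame,
    max_gap: int = 2,
    min_probes: int = 5,
) -> List[DomainCall]:
    """Merge same-label probe runs into domains.

    Two probes of the same (non-neutral) label join one run when at most
    ``max_gap`` probes lie between them and all of those are NEUTRAL. Runs
    with fewer than ``min_probes`` supporting probes are dropped. Domains span
    the footprint of their first through last supporting probe.
    """
    if max_gap < 0:
        raise ValueError(f"max_gap must be >= 0, got {max_gap}")
    if min_probes < 1:
        raise ValueError(f"min_probes must be >= 1, got {min_probes}")
    if len(calls) != len(grid):
        raise ValueError("calls are not aligned with the probe grid")
    for call, pid in zip(calls, grid["id"]):
        if call.probe_id != pid:
            raise ValueError(
                f"calls are not aligned with the probe grid (call {call.probe_id!r} "
                f"vs probe {pid!r})"
            )

    labels = [c.label for c in calls]
    chroms = grid["chrom"].tolist()
    starts = grid["start"].to_numpy(np.int64)
    ends = grid["end"].to_numpy(np.int64)
    folds = grid["fold_change"].to_numpy(float)

    domains: List[DomainCall] = []
    for target in (ProbeLabel.HYPO, ProbeLabel.HYPER):
        run: List[int] = []
        run_chrom: Optional[str] = None

        def flush():
            if len(run) >= min_probes:
                domains.append(
                    DomainCall(
                        chrom=run_chrom,
                        start=int(starts[run[0]]),
                        end=int(ends[run[-1]]),
                        label=target,
                        n_probes=len(run),
                        mean_fold_change=float(np.mean(folds[run])),
                    )
                )
            run.clear()

        for i, label in enumerate(labels):
            if label is not target:
                continue
            if run and chroms[i] == run_chrom:
                between = labels[run[-1] + 1 : i]
                if len(between) <= max_gap and all(
                    b is ProbeLabel.NEUTRAL for b in between
                ):
                    run.append(i)
                    continue
            flush()
            run_chrom = chroms[i]
            run.append(i)
        flush()
    domains.sort(key=lambda d: (d.chrom, d.start))
    return domains


def summarize_chromosomes(
    calls: Sequence[ProbeCall], grid: pd.DataFrame
) -> List[ChromosomeSummary]:
    """Per-chromosome hypo/hyper probe counts and their ratio."""
    if len(calls) != len(grid):
        raise ValueError("calls are not aligned with the probe grid")
    df = pd.DataFrame({"chrom": grid["chrom"], "label": [c.label for c in calls]})
    out = []
    for chrom, sub in df.groupby("chrom", sort=True):
        n_hypo = int((sub["label"] == ProbeLabel.HYPO).sum())
        n_hyper = int((sub["label"] == ProbeLabel.HYPER).sum())
        if n_hyper > 0:
            ratio, defined = n_hypo / n_hyper, True
        elif n_hypo > 0:
            ratio, defined = math.inf, False
        else:
            ratio, defined = math.nan, False
        out.append(ChromosomeSummary(chrom, n_hypo, n_hyper, ratio, defined))
    return out


def summaries_to_frame(summaries: Sequence[ChromosomeSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [s.chrom for s in summaries],
            "n_hypo_probes": [s.n_hypo_probes for s in summaries],
            "n_hyper_probes": [s.n_hyper_probes for s in summaries],
            "hypo_to_hyper_ratio": [s.hypo_to_hyper_ratio for s in summaries],
            "ratio_defined": [s.ratio_defined for s in summaries],
        }
    )


def _merge_intervals(ivs: List[Tuple[str, int, int]]) -> List[Tuple[str, int, int]]:
    ivs = sorted(ivs)
    merged: List[Tuple[str, int, int]] = []
    for chrom, s, e in ivs:
        if merged and merged[-1][0] == chrom and s <= merged[-1][2]:
            merged[-1] = (chrom, merged[-1][1], max(merged[-1][2], e))
        else:
            merged.append((chrom, s, e))
    return merged


def _intersection_bp(a: List[Tuple[str, int, int]], b: List[Tuple[str, int, int]]) -> int:
    total = 0
    for chrom, s1, e1 in a:
        for c2, s2, e2 in b:
            if c2 == chrom:
                total += max(0, min(e1, e2) - max(s1, s2))
    return total


def compare_to_truth(
    domains: Sequence[DomainCall],
    truth: Sequence[DomainInterval],
    label: ProbeLabel = ProbeLabel.HYPO,
) -> RecoveryMetrics:
    """Jaccard between called and truth bases of one label, plus boundary offsets.

    For each truth domain the offset pair is the absolute distance between its
    boundaries and the span of overlapping calls; an unmatched truth domain
    reports infinite offsets.
    """
    called = _merge_intervals(
        [(d.chrom, d.start, d.end) for d in domains if d.label is label]
    )
    truth_ivs = _merge_intervals(
        [(d.chrom, d.start, d.end) for d in truth if d.label == label.value]
    )
    inter = _intersection_bp(called, truth_ivs)
    union = sum(e - s for _, s, e in called) + sum(e - s for _, s, e in truth_ivs) - inter
    jaccard = inter / union if union > 0 else (1.0 if not called and not truth_ivs else 0.0)

    offsets: List[Tuple[float, float]] = []
    for chrom, ts, te in truth_ivs:
        hits = [(s, e) for c, s, e in called if c == chrom and s < te and e > ts]
        if not hits:
            offsets.append((math.inf, math.inf))
        else:
            span_s = min(s for s, _ in hits)
            span_e = max(e for _, e in hits)
            offsets.append((abs(span_s - ts), abs(span_e - te)))
    return RecoveryMetrics(jaccard=jaccard, boundary_offsets=tuple(offsets))


def domains_to_frame(domains: Sequence[DomainCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [d.chrom for d in domains],
            "start": [d.start for d in domains],
            "end": [d.end for d in domains],
            "label": [d.label.value for d in domains],
            "n_probes": [d.n_probes for d in domains],
            "mean_fold_change": [d.mean_fold_change for d in domains],
        }
    )
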