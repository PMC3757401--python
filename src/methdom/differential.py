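"""Two-condition comparison: ratio-of-ratios, smoothing, en-bloc change
detection over domains, and discordantly labelled probe sites.

Sign convention: ratio = control fold change / treated fold change, so values
above one mean the DNA became more methylated (lost McrBC resistance) after
treatment, and below one the reverse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from methdom.domains import DomainCall, ProbeCall, ProbeLabel
from methdom.genome import GeneModel


class ChangeVerdict(str, Enum):
    GAINED_METH = "GAINED_METH"
    LOST_METH = "LOST_METH"
    UNCHANGED = "UNCHANGED"


class SiteDirection(str, Enum):
    HYPER_IN_A_HYPO_IN_B = "HYPER_IN_A_HYPO_IN_B"
    HYPO_IN_A_HYPER_IN_B = "HYPO_IN_A_HYPER_IN_B"


@dataclass(frozen=True)
class DifferentialSite:
    probe_id: str
    chrom: str
    start: int
    end: int
    label_a: ProbeLabel
    label_b: ProbeLabel
    direction: SiteDirection


@dataclass(frozen=True)
class DomainChange:
    chrom: str
    start: int
    end: int
    label: ProbeLabel
    verdict: ChangeVerdict
    mean_smoothed: float
    agreement: float  # fraction of the domain's probes on the verdict's side
    n_probes: int


def _check_grids_match(control: pd.DataFrame, treated: pd.DataFrame) -> None:
    if len(control) != len(treated):
        raise ValueError(
            f"probe grids differ in size ({len(control)} vs {len(treated)})"
        )
    for col in ("id", "chrom", "start"):
        a = control[col].to_numpy()
        b = treated[col].to_numpy()
        mismatch = a != b
        if mismatch.any():
            i = int(np.flatnonzero(mismatch)[0])
            raise ValueError(
                f"probe grids disagree at row {i}: {col} {a[i]!r} vs {b[i]!r}"
            )


def ratio_of_ratios(control: pd.DataFrame, treated: pd.DataFrame) -> pd.DataFrame:
    """Per-probe control/treated fold-change ratio on a shared grid."""
    _check_grids_match(control, treated)
    fc_c = control["fold_change"].to_numpy(float)
    fc_t = treated["fold_change"].to_numpy(float)
    if not np.isfinite(fc_c).all() or not np.isfinite(fc_t).all():
        raise ValueError("non-finite fold change in input")
    if (fc_t <= 0).any() or (fc_c <= 0).any():
        raise ValueError("fold changes must be positive")
    return pd.DataFrame(
        {
            "id": control["id"].to_numpy(),
            "chrom": control["chrom"].to_numpy(),
            "start": control["start"].to_numpy(np.int64),
            "end": control["end"].to_numpy(np.int64),
            "ratio_of_ratios": fc_c / fc_t,
        }
    )


def smooth(track: pd.DataFrame, window_probes: int = 25) -> pd.DataFrame:
    """Centered moving average per chromosome; edges use shrinking windows."""
    if window_probes < 1:
        raise ValueError(f"window_probes must be >= 1, got {window_probes}")
    out = track.copy()
    smoothed = np.empty(len(out))
    for _, sub in out.groupby("chrom", sort=False):
        vals = sub["ratio_of_ratios"]
        smoothed[sub.index.to_numpy()] = (
            vals.rolling(window_probes, center=True, min_periods=1).mean().to_numpy()
        )
    out["smoothed"] = smoothed
    return out


def detect_enbloc(
    track: pd.DataFrame,
    domains: Sequence[DomainCall],
    delta: float = 0.2,
) -> List[DomainChange]:
    """Per-domain verdict from the mean smoothed ratio.

    mean > 1 + delta -> GAINED_METH; mean < 1 - delta -> LOST_METH; otherwise
    UNCHANGED. Agreement is the fraction of the domain's raw per-probe ratios
    lying on the verdict's side of the same thresholds.
    """
    if delta <= 0:
        raise ValueError(f"delta must be > 0, got {delta}")
    if "smoothed" not in track.columns:
        track = smooth(track)
    changes: List[DomainChange] = []
    for d in domains:
        mask = (
            (track["chrom"] == d.chrom)
            & (track["start"] < d.end)
            & (track["end"] > d.start)
        )
        sub = track[mask]
        if sub.empty:
            continue
        mean_sm = float(sub["smoothed"].mean())
        raw = sub["ratio_of_ratios"].to_numpy(float)
        if mean_sm > 1 + delta:
            verdict = ChangeVerdict.GAINED_METH
            agreement = float((raw > 1 + delta).mean())
        elif mean_sm < 1 - delta:
            verdict = ChangeVerdict.LOST_METH
            agreement = float((raw < 1 - delta).mean())
        else:
            verdict = ChangeVerdict.UNCHANGED
            agreement = float(((raw >= 1 - delta) & (raw <= 1 + delta)).mean())
        changes.append(
            DomainChange(
                chrom=d.chrom,
                start=d.start,
                end=d.end,
                label=d.label,
                verdict=verdict,
                mean_smoothed=mean_sm,
                agreement=agreement,
                n_probes=len(sub),
            )
        )
    return changes


def differential_sites(
    calls_a: Sequence[ProbeCall],
    calls_b: Sequence[ProbeCall],
    grid: pd.DataFrame,
) -> List[DifferentialSite]:
    """Probes labelled HYPER in one condition and HYPO in the other."""
    if len(calls_a) != len(grid) or len(calls_b) != len(grid):
        raise ValueError("call lists are not aligned with the probe grid")
    sites: List[DifferentialSite] = []
    for ca, cb, row in zip(calls_a, calls_b, grid.itertuples()):
        if ca.probe_id != row.id or cb.probe_id != row.id:
            raise ValueError(f"call/grid probe id mismatch at {row.id!r}")
        if ca.label is ProbeLabel.HYPER and cb.label is ProbeLabel.HYPO:
            direction = SiteDirection.HYPER_IN_A_HYPO_IN_B
        elif ca.label is ProbeLabel.HYPO and cb.label is ProbeLabel.HYPER:
            direction = SiteDirection.HYPO_IN_A_HYPER_IN_B
        else:
            continue
        sites.append(
            DifferentialSite(
                probe_id=row.id,
                chrom=row.chrom,
                start=int(row.start),
                end=int(row.end),
                label_a=ca.label,
                label_b=cb.label,
                direction=direction,
            )
        )
    return sites


def annotate_sites(
    sites: Sequence[DifferentialSite],
    genes: Sequence[GeneModel],
    large_gene_bp: int = 100_000,
) -> pd.DataFrame:
    """Any-bp gene overlap per site; flags overlap with a large (>100 kb) gene."""
    rows = []
    for s in sites:
        hits = [
            g
            for g in genes
            if g.chrom == s.chrom and g.start < s.end and g.end > s.start
        ]
        rows.append(
            {
                "probe_id": s.probe_id,
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "direction": s.direction.value,
                "genes": ",".join(g.id for g in hits) if hits else "none",
                "gene_lengths": ",".join(str(g.end - g.start) for g in hits)
                if hits
                else ".",
                "in_large_gene": any(g.end - g.start > large_gene_bp for g in hits),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "probe_id",
            "chrom",
            "start",
            "end",
            "direction",
            "genes",
            "gene_lengths",
            "in_large_gene",
        ],
    )
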