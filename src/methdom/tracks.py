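"""Windowed genome tracks and gene-level epigenetic summaries.

Provides the 50 kb CpG-density track (log10 count + 2), gene-density counts,
Pearson correlation between aligned tracks, length-weighted histone-mark
scores per gene, mark-vs-expression correlation, and the promoter/gene-body
methylation pattern classifier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import TYPE_CHECKING, Dict, Iterable, List, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

if TYPE_CHECKING:  # pragma: no cover
    from methdom.genome import GeneModel, GenomeModel

DEFAULT_WINDOW = 50_000


class Region(str, Enum):
    PROMOTER = "PROMOTER"
    BODY = "BODY"
    WHOLE = "WHOLE"


class GenePattern(str, Enum):
    ACTIVE_PATTERN = "ACTIVE_PATTERN"
    SILENCED_PATTERN = "SILENCED_PATTERN"
    MIXED = "MIXED"


@dataclass
class WindowTrack:
    """Fixed-width non-overlapping windows tiling each chromosome.

    ``data`` holds columns (chrom, start, end, value); the final window of a
    chromosome may be truncated at the chromosome end.
    """

    width: int
    data: pd.DataFrame

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError(f"window width must be > 0, got {self.width}")
        required = {"chrom", "start", "end", "value"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"WindowTrack data missing column(s): {sorted(missing)}")

    def chrom_arrays(self, chrom: str):
        sub = self.data[self.data["chrom"] == chrom]
        return sub["start"].to_numpy(), sub["value"].to_numpy(float)

    @property
    def values(self) -> np.ndarray:
        return self.data["value"].to_numpy(float)

    def __len__(self) -> int:
        return len(self.data)


class CorrelationResult(NamedTuple):
    r: float
    p: float
    n: int
    defined: bool


def make_windows(chrom_lengths: Dict[str, int], width: int) -> pd.DataFrame:
    """Window skeleton (chrom, start, end) tiling every chromosome."""
    rows = []
    for chrom, length in chrom_lengths.items():
        starts = np.arange(0, length, width, dtype=np.int64)
        ends = np.minimum(starts + width, length)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    if not rows:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    return pd.concat(rows, ignore_index=True)


def _counts_per_window(positions: np.ndarray, length: int, width: int) -> np.ndarray:
    n_windows = max(1, -(-length // width))
    edges = np.arange(0, (n_windows + 1) * width, width, dtype=np.int64)
    counts, _ = np.histogram(positions, bins=edges)
    return counts


def cpg_density_track(model: "GenomeModel", window: int = DEFAULT_WINDOW) -> WindowTrack:
    """log10(CpG count per window) + 2; zero-count windows score 0.0.

    The 0.0 sentinel for empty windows (rather than -inf) keeps the track
    finite; such windows are flagged in the ``empty`` column.
    """
    if window <= 0:
        raise ValueError(f"window must be > 0, got {window}")
    frames = []
    for chrom, length in model.chrom_lengths.items():
        counts = _counts_per_window(model.cpg_positions[chrom], length, window)
        value = np.where(counts > 0, np.log10(np.maximum(counts, 1)) + 2.0, 0.0)
        starts = np.arange(len(counts), dtype=np.int64) * window
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": np.minimum(starts + window, length),
                    "value": value,
                    "empty": counts == 0,
                }
            )
        )
    return WindowTrack(width=window, data=pd.concat(frames, ignore_index=True))


def gene_density_track(
    genes: Sequence["GeneModel"],
    chrom_lengths: Dict[str, int],
    window: int = DEFAULT_WINDOW,
) -> WindowTrack:
    """Raw count of gene starts per window."""
    if window <= 0:
        raise ValueError(f"window must be > 0, got {window}")
    frames = []
    for chrom, length in chrom_lengths.items():
        starts = np.array([g.start for g in genes if g.chrom == chrom], dtype=np.int64)
        counts = _counts_per_window(starts, length, window)
        wstarts = np.arange(len(counts), dtype=np.int64) * window
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": wstarts,
                    "end": np.minimum(wstarts + window, length),
                    "value": counts.astype(float),
                }
            )
        )
    return WindowTrack(width=window, data=pd.concat(frames, ignore_index=True))


def track_correlation(a: WindowTrack, b: WindowTrack) -> CorrelationResult:
    """Pearson r and two-sided p between two tracks on the same window grid."""
    if a.width != b.width or len(a) != len(b):
        raise ValueError("tracks are not on the same window grid")
    if not (
        (a.data["chrom"].values == b.data["chrom"].values).all()
        and (a.data["start"].values == b.data["start"].values).all()
    ):
        raise ValueError("tracks are not on the same window grid")
    return _pearson(a.values, b.values)


def _pearson(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 paired observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(math.nan, math.nan, n, False)
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(float(r), float(p), n, True)


def _interval_window_mean(
    track: WindowTrack, chrom: str, start: int, end: int
) -> float:
    """Length-weighted mean of window values over [start, end)."""
    if end <= start:
        raise ValueError(f"empty interval [{start}, {end})")
    wstarts, values = track.chrom_arrays(chrom)
    if len(wstarts) == 0:
        raise ValueError(f"track has no windows on chromosome {chrom!r}")
    width = track.width
    first = max(0, int(start) // width)
    last = min(len(wstarts) - 1, (int(end) - 1) // width)
    total = 0.0
    weight = 0.0
    for i in range(first, last + 1):
        w0 = wstarts[i]
        ov = min(end, w0 + width) - max(start, w0)
        if ov > 0:
            total += values[i] * ov
            weight += ov
    return total / weight


def gene_mark_score(
    gene: "GeneModel", mark: WindowTrack, region: Region = Region.WHOLE
) -> float:
    """Length-weighted mean mark value over the chosen gene region."""
    region = Region(region)
    if region is Region.WHOLE:
        start, end = gene.start, gene.end
    elif region is Region.PROMOTER:
        start, end = gene.promoter
    else:
        start, end = gene.body
    return _interval_window_mean(mark, gene.chrom, start, end)


def mark_expression_correlation(
    genes: Sequence["GeneModel"],
    mark: WindowTrack,
    region: Region = Region.WHOLE,
) -> CorrelationResult:
    """Pearson correlation between per-gene mark score and expression."""
    genes = list(genes)
    if len(genes) < 3:
        raise ValueError(f"need at least 3 genes, got {len(genes)}")
    scores = np.array([gene_mark_score(g, mark, region) for g in genes])
    expr = np.array([g.expression for g in genes], float)
    return _pearson(scores, expr)


@dataclass
class GeneMethylationPattern:
    gene_id: str
    promoter_meth: float  # NaN when the promoter holds no CpG
    body_meth: float  # NaN when the body holds no CpG
    pattern: GenePattern
    missing: bool = False


def classify_gene_pattern(
    gene: "GeneModel",
    cpg_positions: np.ndarray,
    meth_state: np.ndarray,
    promoter_cut: float = 0.5,
) -> GeneMethylationPattern:
    """Label a gene by its promoter/body methylation configuration.

    promoter < cut and body >= cut -> ACTIVE_PATTERN (expressed-gene shape);
    promoter >= cut and body < cut -> SILENCED_PATTERN; anything else MIXED.
    A region without CpGs yields NaN and the missing flag (never an exception).
    """
    cpg_positions = np.asarray(cpg_positions)
    meth_state = np.asarray(meth_state, float)

    def region_mean(start: int, end: int) -> float:
        lo = np.searchsorted(cpg_positions, start, side="left")
        hi = np.searchsorted(cpg_positions, end, side="left")
        if hi <= lo:
            return math.nan
        return float(meth_state[lo:hi].mean())

    pstart, pend = gene.promoter
    bstart, bend = gene.body
    promoter_meth = region_mean(pstart, pend)
    body_meth = region_mean(bstart, bend) if bend > bstart else math.nan

    if math.isnan(promoter_meth) or math.isnan(body_meth):
        return GeneMethylationPattern(gene.id, promoter_meth, body_meth, GenePattern.MIXED, True)
    if promoter_meth < promoter_cut and body_meth >= promoter_cut:
        pattern = GenePattern.ACTIVE_PATTERN
    elif promoter_meth >= promoter_cut and body_meth < promoter_cut:
        pattern = GenePattern.SILENCED_PATTERN
    else:
        pattern = GenePattern.MIXED
    return GeneMethylationPattern(gene.id, promoter_meth, body_meth, pattern)


def gene_methylation_patterns(
    model: "GenomeModel", promoter_cut: float = 0.5
) -> List[GeneMethylationPattern]:
    """Pattern for every gene of a simulated genome."""
    out = []
    for g in model.genes:
        out.append(
            classify_gene_pattern(
                g, model.cpg_positions[g.chrom], model.meth_state[g.chrom], promoter_cut
            )
        )
    return out


def patterns_to_frame(patterns: Iterable[GeneMethylationPattern]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [p.gene_id for p in patterns],
            "promoter_meth": [p.promoter_meth for p in patterns],
            "body_meth": [p.body_meth for p in patterns],
            "pattern": [p.pattern.value for p in patterns],
            "missing": [p.missing for p in patterns],
        }
    )
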