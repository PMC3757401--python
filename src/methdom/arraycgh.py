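"""Two-channel probe signals and fold-change / log2 ratios.

The resistant (undigested, size-selected) channel is the fraction of each
probe footprint covered by resistant fragments, floored at a small epsilon
and jittered with multiplicative lognormal noise; the total-genomic channel
is uniform. Fold change = resistant / total; log2 ratio = log2(fold change).
Normalization rescales the resistant channel so the channel medians match.
"""

from __future__ import annotations

from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from methdom.genome import GenomeModel
from methdom.mcrbc import Fragment

SIGNAL_FLOOR = 1e-3

PROBE_COLUMNS = [
    "id",
    "chrom",
    "start",
    "end",
    "signal_resistant",
    "signal_total",
    "fold_change",
    "log2_ratio",
]


def validate_probe_table(grid: pd.DataFrame, signals: bool = False) -> None:
    required = ["id", "chrom", "start", "end"]
    if signals:
        required = PROBE_COLUMNS
    missing = [c for c in required if c not in grid.columns]
    if missing:
        raise ValueError(f"probe table missing column(s): {missing}")
    if grid["id"].duplicated().any():
        dup = grid.loc[grid["id"].duplicated(), "id"].iloc[0]
        raise ValueError(f"duplicate probe id: {dup!r}")
    by = grid.sort_values(["chrom", "start"], kind="stable")
    if not (by.index == grid.index).all():
        raise ValueError("probe table not sorted by (chrom, start)")


def make_probe_grid(model: GenomeModel, spacing: int, footprint: int = 60) -> pd.DataFrame:
    """Evenly spaced probe grid tiling each chromosome; signals unset."""
    if footprint < 1:
        raise ValueError(f"footprint must be >= 1, got {footprint}")
    if spacing < footprint:
        raise ValueError(f"spacing ({spacing}) must be >= footprint ({footprint})")
    frames = []
    for chrom in sorted(model.sequences):
        length = len(model.sequences[chrom])
        if spacing > length:
            raise ValueError(
                f"probe spacing {spacing} exceeds length of {chrom} ({length} bp)"
            )
        starts = np.arange(0, length - footprint + 1, spacing, dtype=np.int64)
        frames.append(
            pd.DataFrame(
                {
                    "id": [f"{chrom}_p{i:07d}" for i in range(len(starts))],
                    "chrom": chrom,
                    "start": starts,
                    "end": starts + footprint,
                }
            )
        )
    grid = pd.concat(frames, ignore_index=True)
    validate_probe_table(grid)
    return grid


def _coverage_fraction(
    starts: np.ndarray, ends: np.ndarray, fragments: Sequence[Fragment]
) -> np.ndarray:
    """Fraction of each [start, end) interval covered by the fragments.

    Fragments must be non-overlapping; computed via a prefix-sum of covered bp.
    """
    if len(starts) == 0:
        return np.empty(0)
    fs = np.array([f.start for f in fragments], dtype=np.int64)
    fe = np.array([f.end for f in fragments], dtype=np.int64)
    order = np.argsort(fs)
    fs, fe = fs[order], fe[order]
    if len(fs) == 0:
        return np.zeros(len(starts))
    if len(fs) > 1 and (fs[1:] < fe[:-1]).any():
        raise ValueError("fragments overlap; coverage is ill-defined")
    # cum[k] = total bp of the first k fragments
    cum = np.concatenate([[0], np.cumsum(fe - fs)])

    def covered_upto(x: np.ndarray) -> np.ndarray:
        """Total fragment bp in [0, x)."""
        i = np.searchsorted(fs, x, side="right")  # fragments starting before x
        j = np.maximum(i - 1, 0)
        partial = np.clip(np.minimum(x, fe[j]) - fs[j], 0, None)
        return np.where(i > 0, cum[j] + partial, 0)

    cov = covered_upto(ends) - covered_upto(starts)
    return cov / (ends - starts)


def simulate_signals(
    grid: pd.DataFrame,
    resistant: Sequence[Fragment],
    noise_sd: float,
    seed: int,
) -> pd.DataFrame:
    """Fill channel signals from resistant-fragment coverage plus lognormal noise."""
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    validate_probe_table(grid)
    rng = np.random.default_rng(seed)
    out = grid.copy()
    by_chrom: Dict[str, List[Fragment]] = {}
    for f in resistant:
        by_chrom.setdefault(f.chrom, []).append(f)
    coverage = np.zeros(len(out))
    for chrom, sub in out.groupby("chrom", sort=False):
        frac = _coverage_fraction(
            sub["start"].to_numpy(np.int64),
            sub["end"].to_numpy(np.int64),
            by_chrom.get(chrom, []),
        )
        coverage[sub.index.to_numpy()] = frac
    noise = np.exp(rng.normal(0.0, noise_sd, len(out))) if noise_sd > 0 else 1.0
    out["signal_resistant"] = np.maximum(coverage, SIGNAL_FLOOR) * noise
    out["signal_total"] = 1.0
    return _recompute_ratios(out)


def _recompute_ratios(grid: pd.DataFrame) -> pd.DataFrame:
    grid["fold_change"] = grid["signal_resistant"] / grid["signal_total"]
    with np.errstate(divide="ignore"):
        grid["log2_ratio"] = np.log2(grid["fold_change"])
    return grid


def normalize(grid: pd.DataFrame) -> pd.DataFrame:
    """Rescale the resistant channel so its median matches the total channel's."""
    validate_probe_table(grid, signals=True)
    med_res = float(np.median(grid["signal_resistant"]))
    med_tot = float(np.median(grid["signal_total"]))
    if med_res <= 0 or med_tot <= 0:
        raise ValueError("cannot normalize: non-positive channel median")
    out = grid.copy()
    out["signal_resistant"] = out["signal_resistant"] * (med_tot / med_res)
    return _recompute_ratios(out)
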