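"""In-silico McrBC digestion and gel-style size selection.

Recognition model: a half-site is a methylated C preceded by a purine, on
either strand (Pu-mC). A cut is placed at the integer midpoint of every pair
of *consecutive* half-sites whose spacing lies within the pairing window
(default 40-3000 bp). Digestion is deterministic and complete; fragments tile
each chromosome exactly. "High molecular weight" DNA is whatever survives a
length threshold, standing in for recovery near the gel top.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence

import numpy as np
import pandas as pd

from methdom.genome import GenomeModel

_PURINES = frozenset(b"AG")
_PYRIMIDINES = frozenset(b"CT")  # complement of a purine on the minus strand


@dataclass(frozen=True)
class HalfSite:
    """A methylated C in Pu-mC context; ``pos`` is the C's 0-based position."""

    chrom: str
    pos: int
    flank: str
    strand: str = "+"


@dataclass(frozen=True)
class Fragment:
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"fragment end must exceed start: {self}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class DigestParams:
    min_pair_spacing: int = 40
    max_pair_spacing: int = 3_000
    size_threshold: int = 20_000
    meth_call_threshold: float = 0.5
    cut_offset_rule: str = "MIDPOINT"

    def __post_init__(self):
        if not 0 <= self.min_pair_spacing < self.max_pair_spacing:
            raise ValueError(
                "require 0 <= min_pair_spacing < max_pair_spacing, got "
                f"{self.min_pair_spacing}, {self.max_pair_spacing}"
            )
        if self.size_threshold <= 0:
            raise ValueError(f"size_threshold must be > 0, got {self.size_threshold}")
        if not 0.0 <= self.meth_call_threshold <= 1.0:
            raise ValueError("meth_call_threshold must lie in [0, 1]")
        if self.cut_offset_rule != "MIDPOINT":
            raise ValueError(f"unsupported cut_offset_rule {self.cut_offset_rule!r}")


def _half_site_arrays(model: GenomeModel, params: DigestParams, chrom: str):
    """(positions, strands, flank bytes) of half-sites on one chromosome, sorted."""
    seq = np.frombuffer(model.sequences[chrom].encode("ascii"), dtype=np.uint8)
    pos = model.cpg_positions[chrom]
    meth = model.meth_state[chrom]
    hot = pos[meth >= params.meth_call_threshold]
    if len(hot) == 0:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty, empty
    plus = hot[hot > 0]
    plus = plus[np.isin(seq[plus - 1], list(_PURINES))]
    minus = hot[hot + 2 < len(seq)]
    minus = minus[np.isin(seq[minus + 2], list(_PYRIMIDINES))]
    positions = np.concatenate([plus, minus + 1])
    strands = np.concatenate([np.zeros(len(plus), dtype=np.int64), np.ones(len(minus), dtype=np.int64)])
    # flank base: plus-strand purine as-is; minus-strand purine = complement of seq[p+2]
    flank_plus = seq[plus - 1] if len(plus) else np.empty(0, dtype=np.uint8)
    flank_minus = np.where(seq[minus + 2] == ord("T"), ord("A"), ord("G")).astype(np.uint8)
    flanks = np.concatenate([flank_plus, flank_minus])
    order = np.argsort(positions, kind="stable")
    return positions[order], strands[order], flanks[order]


def find_half_sites(model: GenomeModel, params: DigestParams = DigestParams()) -> List[HalfSite]:
    """All Pu-mC half-sites, both strands, sorted by (chrom, pos).

    A CpG counts as methylated when its meth_state >= meth_call_threshold.
    Plus strand: the C of the CpG at position p, requiring a purine at p-1.
    Minus strand: the complementary C at p+1, requiring a plus-strand
    pyrimidine at p+2 (a purine on the minus strand).
    """
    sites: List[HalfSite] = []
    for chrom in sorted(model.sequences):
        positions, strands, flanks = _half_site_arrays(model, params, chrom)
        sites.extend(
            HalfSite(chrom, int(p), chr(f), "+" if s == 0 else "-")
            for p, s, f in zip(positions, strands, flanks)
        )
    return sites


def _cut_positions(site_pos: np.ndarray, params: DigestParams) -> np.ndarray:
    if len(site_pos) < 2:
        return np.empty(0, dtype=np.int64)
    gaps = np.diff(site_pos)
    eligible = (gaps >= params.min_pair_spacing) & (gaps <= params.max_pair_spacing)
    cuts = (site_pos[:-1][eligible] + site_pos[1:][eligible]) // 2
    return np.unique(cuts)


def digest(model: GenomeModel, params: DigestParams = DigestParams()) -> List[Fragment]:
    """Complete digestion: fragments between midpoint cuts, tiling each chromosome."""
    fragments: List[Fragment] = []
    for chrom in sorted(model.sequences):
        length = len(model.sequences[chrom])
        positions, _, _ = _half_site_arrays(model, params, chrom)
        cuts = _cut_positions(positions, params)
        cuts = cuts[(cuts > 0) & (cuts < length)]
        edges = np.concatenate([[0], cuts, [length]])
        for s, e in zip(edges[:-1], edges[1:]):
            fragments.append(Fragment(chrom, int(s), int(e)))
    return fragments


def size_select(fragments: Sequence[Fragment], size_threshold: int) -> List[Fragment]:
    """Keep fragments of length >= size_threshold, order preserved."""
    if size_threshold <= 0:
        raise ValueError(f"size_threshold must be > 0, got {size_threshold}")
    return [f for f in fragments if f.length >= size_threshold]


def fragment_length_histogram(
    fragments: Sequence[Fragment], bin_edges: Iterable[int] | None = None
) -> pd.DataFrame:
    """In-silico gel: fragment counts and total bp per length bin."""
    lengths = np.array([f.length for f in fragments], dtype=np.int64)
    if bin_edges is None:
        top = int(lengths.max()) if len(lengths) else 1
        bin_edges = np.unique(
            np.concatenate([[0], np.geomspace(100, max(top, 101), 30).astype(np.int64), [top + 1]])
        )
    edges = np.asarray(list(bin_edges), dtype=np.int64)
    counts, _ = np.histogram(lengths, bins=edges)
    bp = np.histogram(lengths, bins=edges, weights=lengths)[0].astype(np.int64)
    return pd.DataFrame(
        {"bin_start": edges[:-1], "bin_end": edges[1:], "n_fragments": counts, "total_bp": bp}
    )


def fragments_to_frame(fragments: Sequence[Fragment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [f.chrom for f in fragments],
            "start": [f.start for f in fragments],
            "end": [f.end for f in fragments],
        }
    )


def frame_to_fragments(df: pd.DataFrame) -> List[Fragment]:
    return [Fragment(r.chrom, int(r.start), int(r.end)) for r in df.itertuples()]
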