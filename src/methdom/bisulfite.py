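"""In-silico bisulfite conversion, read simulation, and methylation calling.

Each simulated molecule samples its CpG methylation independently from the
per-CpG probabilities, so read pileups recover those probabilities with
binomial error. Reads carry true coordinates (no alignment step); calling
works purely from the converted read sequences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from methdom.domains import DomainCall, ProbeLabel
from methdom.genome import GenomeModel

_COMPLEMENT = bytes.maketrans(b"ACGT", b"TGCA")


@dataclass(frozen=True)
class BisRead:
    """One converted single-end read; ``sequence`` is in read (5'->3') orientation."""

    chrom: str
    start: int
    length: int
    strand: str
    sequence: str

    def __post_init__(self):
        if self.length != len(self.sequence):
            raise ValueError("read length disagrees with sequence length")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass
class CpGCall:
    chrom: str
    pos: int
    n_C: int
    n_T: int
    low_coverage: bool = False

    @property
    def coverage(self) -> int:
        return self.n_C + self.n_T

    @property
    def meth_fraction(self) -> float:
        if self.coverage == 0:
            return math.nan
        return self.n_C / self.coverage


def _convert_plus(
    template: np.ndarray,
    offset: int,
    cpg_positions: np.ndarray,
    meth_sample: np.ndarray,
    rng: np.random.Generator,
    efficiency: float,
) -> np.ndarray:
    """Convert the plus-strand template of one molecule in place.

    ``meth_sample`` is the molecule's sampled 0/1 methylation per CpG (aligned
    with ``cpg_positions``); protected Cs are the methylated CpG Cs.
    """
    out = template.copy()
    c_mask = out == ord("C")
    idx = np.flatnonzero(c_mask) + offset
    lo = np.searchsorted(cpg_positions, offset)
    hi = np.searchsorted(cpg_positions, offset + len(template))
    protected = set(cpg_positions[lo:hi][meth_sample[lo:hi] == 1].tolist())
    convert = np.array([p not in protected for p in idx], dtype=bool)
    if efficiency < 1.0:
        convert &= rng.random(len(idx)) < efficiency
    out[np.flatnonzero(c_mask)[convert]] = ord("T")
    return out


def bisulfite_convert(
    sequence: str,
    cpg_positions: np.ndarray,
    meth_state: np.ndarray,
    seed: int,
    efficiency: float = 1.0,
) -> str:
    """Convert one plus-strand molecule of ``sequence``.

    Every C outside CpG context converts to T (with the given efficiency);
    the C of each CpG is retained iff the molecule, sampled per CpG from
    ``meth_state``, is methylated there.
    """
    if not 0.0 <= efficiency <= 1.0:
        raise ValueError(f"efficiency must lie in [0, 1], got {efficiency}")
    rng = np.random.default_rng(seed)
    template = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    cpg_positions = np.asarray(cpg_positions, dtype=np.int64)
    meth_sample = (rng.random(len(cpg_positions)) < np.asarray(meth_state, float)).astype(np.int8)
    return _convert_plus(template, 0, cpg_positions, meth_sample, rng, efficiency).tobytes().decode(
        "ascii"
    )


def simulate_reads(
    model: GenomeModel,
    region: Tuple[str, int, int],
    coverage: float,
    read_len: int = 100,
    seed: int = 0,
    efficiency: float = 1.0,
) -> List[BisRead]:
    """Uniform bisulfite reads over ``region`` at the requested fold coverage.

    Each read is an independent molecule: its CpG methylation is sampled from
    the model's per-CpG probabilities, both strands sequenced equally.
    """
    chrom, start, end = region
    if chrom not in model.sequences:
        raise ValueError(f"unknown chromosome {chrom!r}")
    length = len(model.sequences[chrom])
    if not 0 <= start < end <= length:
        raise ValueError(f"region [{start}, {end}) out of bounds for {chrom} ({length} bp)")
    if coverage < 0:
        raise ValueError(f"coverage must be >= 0, got {coverage}")
    if read_len < 1:
        raise ValueError(f"read_len must be >= 1, got {read_len}")
    if coverage > 0 and read_len > end - start:
        raise ValueError(f"read_len {read_len} exceeds region size {end - start}")
    n_reads = int(round(coverage * (end - start) / read_len))
    if n_reads == 0:
        return []
    rng = np.random.default_rng(seed)
    seq = np.frombuffer(model.sequences[chrom].encode("ascii"), dtype=np.uint8)
    cpg = model.cpg_positions[chrom]
    meth = model.meth_state[chrom]

    starts = rng.integers(start, end - read_len + 1, size=n_reads)
    strands = rng.random(n_reads) < 0.5
    reads: List[BisRead] = []
    for s, is_plus in zip(starts, strands):
        s = int(s)
        lo = np.searchsorted(cpg, s - 1)
        hi = np.searchsorted(cpg, s + read_len)
        local_cpg = cpg[lo:hi]
        sample = (rng.random(len(local_cpg)) < meth[lo:hi]).astype(np.int8)
        if is_plus:
            conv = _convert_plus(seq[s : s + read_len], s, local_cpg, sample, rng, efficiency)
            reads.append(
                BisRead(chrom, s, read_len, "+", conv.tobytes().decode("ascii"))
            )
        else:
            conv = _convert_minus(seq[s : s + read_len], s, local_cpg, sample, rng, efficiency)
            reads.append(
                BisRead(chrom, s, read_len, "-", conv.tobytes().decode("ascii"))
            )
    return reads


def _convert_minus(
    template: np.ndarray,
    offset: int,
    cpg_positions: np.ndarray,
    meth_sample: np.ndarray,
    rng: np.random.Generator,
    efficiency: float,
) -> np.ndarray:
    """Convert the minus-strand molecule of a genomic window.

    The molecule is the reverse complement of the window; its Cs sit opposite
    genomic Gs. The C opposite the G of a CpG (genomic position p+1 for a CpG
    at p) shares the CpG's sampled methylation state.
    """
    rc = np.frombuffer(
        template.tobytes().translate(_COMPLEMENT)[::-1], dtype=np.uint8
    ).copy()
    L = len(rc)
    c_mask = rc == ord("C")
    read_idx = np.flatnonzero(c_mask)
    # read index i corresponds to genomic position offset + L - 1 - i
    genomic = offset + L - 1 - read_idx
    protected_genomic = set((cpg_positions[meth_sample == 1] + 1).tolist())
    convert = np.array([g not in protected_genomic for g in genomic], dtype=bool)
    if efficiency < 1.0:
        convert &= rng.random(len(read_idx)) < efficiency
    rc[read_idx[convert]] = ord("T")
    return rc


def call_methylation(
    reads: Sequence[BisRead],
    cpg_positions: np.ndarray,
    min_coverage: int = 5,
    chrom: Optional[str] = None,
) -> List[CpGCall]:
    """Per-CpG C/T tallies from overlapping reads.

    Plus-strand reads report the CpG's C at position p; minus-strand reads
    report the complementary C at p+1. Sites below ``min_coverage`` are
    flagged, not dropped.
    """
    if min_coverage < 0:
        raise ValueError(f"min_coverage must be >= 0, got {min_coverage}")
    cpg_positions = np.asarray(cpg_positions, dtype=np.int64)
    if chrom is None:
        chroms = {r.chrom for r in reads}
        if len(chroms) > 1:
            raise ValueError("reads span several chromosomes; pass chrom explicitly")
        chrom = chroms.pop() if chroms else "chr1"
    n_C = np.zeros(len(cpg_positions), dtype=np.int64)
    n_T = np.zeros(len(cpg_positions), dtype=np.int64)
    for r in reads:
        if r.chrom != chrom:
            continue
        lo = np.searchsorted(cpg_positions, r.start if r.strand == "+" else r.start - 1)
        hi = np.searchsorted(cpg_positions, r.end if r.strand == "+" else r.end - 1)
        for k in range(lo, hi):
            p = cpg_positions[k]
            if r.strand == "+":
                if not (r.start <= p < r.end):
                    continue
                base = r.sequence[p - r.start]
            else:
                q = p + 1
                if not (r.start <= q < r.end):
                    continue
                base = r.sequence[r.start + r.length - 1 - q]
            if base == "C":
                n_C[k] += 1
            elif base == "T":
                n_T[k] += 1
    return [
        CpGCall(chrom, int(p), int(c), int(t), low_coverage=(c + t) < min_coverage)
        for p, c, t in zip(cpg_positions, n_C, n_T)
    ]


@dataclass(frozen=True)
class ConcordanceReport:
    """Bisulfite-vs-array agreement of binarized methylation with domain labels."""

    mean_meth_inside: float
    mean_meth_outside: float
    n_inside: int
    n_outside: int
    concordance: float  # fraction of sites whose binarized state matches the label


def validate_domains(
    calls: Sequence[CpGCall],
    domains: Sequence[DomainCall],
    binarize_cut: float = 0.5,
) -> ConcordanceReport:
    """Compare per-CpG calls with called domains.

    A site inside a HYPO domain is concordant when its binarized state is
    unmethylated (< cut); a site outside any HYPO domain is concordant when
    methylated (>= cut). Sites with zero coverage are ignored.
    """
    hypo = [(d.chrom, d.start, d.end) for d in domains if d.label is ProbeLabel.HYPO]
    inside_f: List[float] = []
    outside_f: List[float] = []
    for c in calls:
        if c.coverage == 0:
            continue
        if any(ch == c.chrom and s <= c.pos < e for ch, s, e in hypo):
            inside_f.append(c.meth_fraction)
        else:
            outside_f.append(c.meth_fraction)
    n_in, n_out = len(inside_f), len(outside_f)
    concordant = sum(f < binarize_cut for f in inside_f) + sum(
        f >= binarize_cut for f in outside_f
    )
    total = n_in + n_out
    return ConcordanceReport(
        mean_meth_inside=float(np.mean(inside_f)) if n_in else math.nan,
        mean_meth_outside=float(np.mean(outside_f)) if n_out else math.nan,
        n_inside=n_in,
        n_outside=n_out,
        concordance=concordant / total if total else math.nan,
    )


def sample_validation_sites(
    model: GenomeModel,
    interval: Tuple[str, int, int],
    n_sites: int = 39,
    site_width: int = 1_500,
    seed: int = 0,
    min_cpgs: int = 8,
) -> List[Tuple[str, int, int]]:
    """Randomly chosen non-overlapping loci inside an interval.

    Mirrors a validation design where each sampled "site" is a short locus
    (hundreds of bp to a few kb) rather than a single CpG; like real
    amplicon design, only loci carrying at least ``min_cpgs`` assayable CpGs
    qualify.
    """
    chrom, start, end = interval
    if end - start < site_width:
        raise ValueError("interval shorter than site_width")
    cpg = model.cpg_positions[chrom]
    rng = np.random.default_rng(seed)
    sites: List[Tuple[int, int]] = []
    for _ in range(n_sites * 500):
        s = int(rng.integers(start, end - site_width + 1))
        n_cpg = int(np.searchsorted(cpg, s + site_width) - np.searchsorted(cpg, s))
        if n_cpg < min_cpgs:
            continue
        if all(s + site_width <= a or s >= b for a, b in sites):
            sites.append((s, s + site_width))
        if len(sites) == n_sites:
            break
    if len(sites) < n_sites:
        raise ValueError(
            f"could not place {n_sites} non-overlapping {site_width} bp sites "
            f"with >= {min_cpgs} CpGs in interval"
        )
    return [(chrom, s, e) for s, e in sorted(sites)]


def site_methylation(
    model: GenomeModel,
    site: Tuple[str, int, int],
    coverage: float = 30.0,
    read_len: int = 100,
    seed: int = 0,
    efficiency: float = 1.0,
) -> float:
    """Pooled meth fraction of one locus from simulated reads (NaN if no CpG data)."""
    chrom, start, end = site
    reads = simulate_reads(model, site, coverage, read_len, seed, efficiency)
    cpg = model.cpg_positions[chrom]
    local = cpg[(cpg >= start) & (cpg < end)]
    calls = call_methylation(reads, local, min_coverage=0, chrom=chrom)
    total_c = sum(c.n_C for c in calls)
    total = sum(c.coverage for c in calls)
    return total_c / total if total else math.nan


def calls_to_frame(calls: Sequence[CpGCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [c.chrom for c in calls],
            "pos": [c.pos for c in calls],
            "n_C": [c.n_C for c in calls],
            "n_T": [c.n_T for c in calls],
            "coverage": [c.coverage for c in calls],
            "meth_fraction": [c.meth_fraction for c in calls],
            "low_coverage": [c.low_coverage for c in calls],
        }
    )
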