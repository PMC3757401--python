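"""Synthetic genome generator with ground-truth methylation domains.

Produces chromosomes whose CpG dinucleotides are injected at controlled
rates, megabase-scale hypomethylated domains placed in the CpG-poor (and
gene-poor) regions, per-CpG methylation probabilities, anti-correlated
H3K9Ac/H3K27Me3 window tracks, and genes whose expression is coupled
positively to H3K9Ac and negatively to H3K27Me3. Everything is driven by a
single seed; identical configs give identical models.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from methdom.config import SimConfig
from methdom.tracks import WindowTrack

HYPO = "HYPO"
BACKGROUND = "BACKGROUND"

_C = ord("C")
_G = ord("G")
_A = ord("A")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class DomainInterval:
    chrom: str
    start: int
    end: int
    label: str

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"domain end must exceed start: {self}")


@dataclass
class GeneModel:
    """A gene with strand-aware promoter and gene body intervals.

    Promoter = 1 kb upstream of the TSS through 500 bp downstream (clipped at
    chromosome bounds); body = the rest of the gene interval.
    """

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    expression: float
    promoter_upstream: int = 1_000
    promoter_downstream: int = 500
    chrom_length: Optional[int] = None

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"gene {self.id}: end must exceed start")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.id}: strand must be '+' or '-'")
        if self.expression < 0:
            raise ValueError(f"gene {self.id}: expression must be non-negative")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def promoter(self) -> Tuple[int, int]:
        if self.strand == "+":
            lo = self.start - self.promoter_upstream
            hi = self.start + self.promoter_downstream
        else:
            lo = self.end - self.promoter_downstream
            hi = self.end + self.promoter_upstream
        lo = max(0, lo)
        if self.chrom_length is not None:
            hi = min(hi, self.chrom_length)
        return lo, hi

    @property
    def body(self) -> Tuple[int, int]:
        """Gene interval with the promoter-overlapping part removed."""
        pstart, pend = self.promoter
        if self.strand == "+":
            return min(max(self.start, pend), self.end), self.end
        return self.start, max(min(self.end, pstart), self.start)


@dataclass
class GenomeModel:
    """Sequences plus every piece of ground truth the pipeline consumes.

    ``meth_state`` holds one methylation *probability* per CpG, aligned with
    ``cpg_positions`` (position of the plus-strand C of each CpG).
    """

    sequences: Dict[str, str]
    cpg_positions: Dict[str, np.ndarray]
    meth_state: Dict[str, np.ndarray]
    truth_domains: List[DomainInterval]
    genes: List[GeneModel]
    mark_tracks: Dict[str, WindowTrack]
    config: Optional[SimConfig] = None

    @property
    def chrom_lengths(self) -> Dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def validate(self) -> None:
        for chrom, seq in self.sequences.items():
            pos = self.cpg_positions[chrom]
            if len(pos) != len(self.meth_state[chrom]):
                raise ValueError(f"{chrom}: meth_state length != cpg_positions length")
            if len(pos) and (np.diff(pos) <= 0).any():
                raise ValueError(f"{chrom}: cpg_positions not strictly increasing")
            if len(pos) and (pos[-1] + 1 >= len(seq)):
                raise ValueError(f"{chrom}: CpG position out of bounds")
            m = self.meth_state[chrom]
            if len(m) and ((m < 0) | (m > 1)).any():
                raise ValueError(f"{chrom}: meth_state outside [0, 1]")
        spans: Dict[str, List[Tuple[int, int]]] = {}
        for d in self.truth_domains:
            L = self.chrom_lengths.get(d.chrom)
            if L is None or d.start < 0 or d.end > L:
                raise ValueError(f"truth domain out of chromosome bounds: {d}")
            spans.setdefault(d.chrom, []).append((d.start, d.end))
        for chrom, ivs in spans.items():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping truth domains on {chrom}")

    def copy(self) -> "GenomeModel":
        return GenomeModel(
            sequences=dict(self.sequences),
            cpg_positions={c: p.copy() for c, p in self.cpg_positions.items()},
            meth_state={c: m.copy() for c, m in self.meth_state.items()},
            truth_domains=list(self.truth_domains),
            genes=copy.deepcopy(self.genes),
            mark_tracks=self.mark_tracks,
            config=self.config,
        )

    def hypo_domains(self, chrom: Optional[str] = None) -> List[DomainInterval]:
        return [
            d
            for d in self.truth_domains
            if d.label == HYPO and (chrom is None or d.chrom == chrom)
        ]


# ---------------------------------------------------------------------------
# generator internals


def _place_domains(rng: np.random.Generator, length: int, n: int, size_range) -> List[Tuple[int, int]]:
    """Non-overlapping domain intervals with a small margin off chromosome ends."""
    lo, hi = size_range
    margin = min(length // 20, 100_000)
    placed: List[Tuple[int, int]] = []
    for _ in range(n):
        size = int(rng.integers(lo, hi + 1))
        for _attempt in range(1000):
            max_start = length - margin - size
            if max_start <= margin:
                raise ValueError(
                    f"cannot fit a {size} bp domain into a {length} bp chromosome"
                )
            start = int(rng.integers(margin, max_start + 1))
            end = start + size
            if all(end + 50_000 <= s or start >= e + 50_000 for s, e in placed):
                placed.append((start, end))
                break
        else:
            raise ValueError(
                f"could not place {n} non-overlapping domains of {lo}-{hi} bp "
                f"on a {length} bp chromosome"
            )
    return sorted(placed)


def _base_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    edges = np.cumsum([(1 - gc) / 2, gc / 2, gc / 2])
    r = rng.random(length)
    idx = (r > edges[0]).astype(np.uint8) + (r > edges[1]) + (r > edges[2])
    seq = _BASES[idx]
    # strip the CpGs the base model created, so density is set purely by injection
    cg = np.flatnonzero((seq[:-1] == _C) & (seq[1:] == _G))
    seq[cg + 1] = _A
    return seq


def _sample_cpg_sites(rng: np.random.Generator, start: int, end: int, rate: float) -> np.ndarray:
    """CpG start positions in [start, end-1) with ~``rate`` sites per bp.

    Consecutive sites are kept >= 2 bp apart so injected dinucleotides never
    overlap; gaps are geometric, i.e. an approximately Poisson site process.
    """
    span = end - start
    if rate <= 0 or span < 2:
        return np.empty(0, dtype=np.int64)
    out: List[np.ndarray] = []
    pos = start
    expected = int(span * rate) + 10
    while pos < end - 1:
        gaps = rng.geometric(min(rate, 0.5), size=expected) + 1
        pts = pos + np.cumsum(gaps) - 1
        out.append(pts)
        pos = int(pts[-1]) + 1
        expected = max(64, int((end - pos) * rate) + 10)
    sites = np.concatenate(out)
    return sites[sites < end - 1]


def _inject_cpgs(seq: np.ndarray, sites: np.ndarray) -> None:
    seq[sites] = _C
    seq[sites + 1] = _G


def _scan_cpgs(seq: np.ndarray) -> np.ndarray:
    return np.flatnonzero((seq[:-1] == _C) & (seq[1:] == _G)).astype(np.int64)


def _place_genes(
    rng: np.random.Generator,
    config: SimConfig,
    chrom: str,
    length: int,
    domains: List[Tuple[int, int]],
    n_genes: int,
) -> List[GeneModel]:
    """Non-overlapping genes; a small fraction placed wholly inside hypo domains."""
    glo, ghi = config.gene_length_range
    occupied: List[Tuple[int, int]] = []
    genes: List[GeneModel] = []
    dom_arr = domains or []
    for i in range(n_genes):
        in_domain = bool(dom_arr) and rng.random() < config.hypo_gene_fraction
        size = int(rng.integers(glo, ghi + 1))
        placed = False
        for _attempt in range(2000):
            if in_domain:
                ds, de = dom_arr[int(rng.integers(len(dom_arr)))]
                # keep domain genes interior: their methylated promoters would
                # otherwise shave resistant fragments off the domain edges
                margin = min(25_000, max(0, (de - ds - size) // 4))
                if de - ds <= size + 2 * margin + 2:
                    continue
                start = int(rng.integers(ds + margin + 1, de - size - margin))
            else:
                start = int(rng.integers(0, max(1, length - size)))
                if any(start < e and start + size > s for s, e in dom_arr):
                    continue
            end = start + size
            pad = config.promoter_upstream  # keep promoters from overlapping neighbours
            if any(start - pad < e and end + pad > s for s, e in occupied):
                continue
            occupied.append((start, end))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneModel(
                    id=f"{chrom}_g{i:05d}",
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    expression=0.0,
                    promoter_upstream=config.promoter_upstream,
                    promoter_downstream=config.promoter_downstream,
                    chrom_length=length,
                )
            )
            placed = True
            break
        if not placed:
            raise ValueError(
                f"could not place gene {i} on {chrom}: genome too crowded "
                f"(n_genes={n_genes}, gene_length_range={config.gene_length_range})"
            )
    genes.sort(key=lambda g: g.start)
    for j, g in enumerate(genes):
        g.id = f"{chrom}_g{j:05d}"
    return genes


def _mark_tracks(
    rng: np.random.Generator,
    chrom_lengths: Dict[str, int],
    domains: List[DomainInterval],
    config: SimConfig,
) -> Dict[str, WindowTrack]:
    """Complementary H3K9Ac (high outside hypo domains) and H3K27Me3 tracks."""
    width = config.mark_window
    rows_ac, rows_me = [], []
    for chrom, length in chrom_lengths.items():
        starts = np.arange(0, length, width, dtype=np.int64)
        ends = np.minimum(starts + width, length)
        mids = (starts + ends) // 2
        inside = np.zeros(len(starts), dtype=bool)
        for d in domains:
            if d.chrom == chrom and d.label == HYPO:
                inside |= (mids >= d.start) & (mids < d.end)
        ac = np.where(inside, 0.2, 1.0) + rng.normal(0, config.mark_noise_sd, len(starts))
        me = np.where(inside, 1.0, 0.2) + rng.normal(0, config.mark_noise_sd, len(starts))
        ac = np.clip(ac, 0.0, None)
        me = np.clip(me, 0.0, None)
        rows_ac.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends, "value": ac}))
        rows_me.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends, "value": me}))
    return {
        "H3K9Ac": WindowTrack(width=width, data=pd.concat(rows_ac, ignore_index=True)),
        "H3K27Me3": WindowTrack(width=width, data=pd.concat(rows_me, ignore_index=True)),
    }


def simulate_genome(config: SimConfig) -> GenomeModel:
    """Build a :class:`GenomeModel` realizing the configured domain structure.

    Hypomethylated domains are carved out as CpG-poor (rate ``cpg_rate_low``)
    and assigned per-CpG methylation probability ``domain_meth``; everything
    else is CpG-rich at ``cpg_rate_high`` with probability ``background_meth``.
    Active genes (outside domains) get hypomethylated promoters; genes inside
    domains get the inverse promoter-methylated / body-unmethylated shape.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    streams = {
        name: np.random.default_rng(seed)
        for name, seed in zip(
            ("placement", "sequence", "genes", "marks", "expression"), root.spawn(5)
        )
    }

    sequences: Dict[str, str] = {}
    cpg_positions: Dict[str, np.ndarray] = {}
    meth_state: Dict[str, np.ndarray] = {}
    truth_domains: List[DomainInterval] = []
    genes: List[GeneModel] = []

    # domains are spread round-robin over chromosomes
    per_chrom = [config.n_hypo_domains // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_hypo_domains % config.n_chromosomes):
        per_chrom[i] += 1
    gene_per_chrom = [config.n_genes // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_genes % config.n_chromosomes):
        gene_per_chrom[i] += 1

    for ci in range(config.n_chromosomes):
        chrom = f"chr{ci + 1}"
        L = config.genome_length
        domains = _place_domains(
            streams["placement"], L, per_chrom[ci], config.hypo_domain_length
        )
        seq = _base_sequence(streams["sequence"], L, config.gc_content)

        # inject CpGs region by region: low rate inside domains, high outside
        boundaries = [0]
        for s, e in domains:
            boundaries.extend([s, e])
        boundaries.append(L)
        for j, (rs, re) in enumerate(zip(boundaries[:-1], boundaries[1:])):
            rate = config.cpg_rate_low if j % 2 == 1 else config.cpg_rate_high
            sites = _sample_cpg_sites(streams["sequence"], rs, re, rate)
            _inject_cpgs(seq, sites)

        pos = _scan_cpgs(seq)
        meth = np.full(len(pos), config.background_meth, dtype=float)
        for s, e in domains:
            lo = np.searchsorted(pos, s)
            hi = np.searchsorted(pos, e)
            meth[lo:hi] = config.domain_meth

        chrom_genes = _place_genes(
            streams["genes"], config, chrom, L, domains, gene_per_chrom[ci]
        )
        # promoter overrides: active genes hypo-promoter, domain genes hyper-promoter
        for g in chrom_genes:
            inside = any(g.start >= s and g.end <= e for s, e in domains)
            ps, pe = g.promoter
            lo = np.searchsorted(pos, ps)
            hi = np.searchsorted(pos, pe)
            meth[lo:hi] = config.background_meth if inside else config.domain_meth

        sequences[chrom] = seq.tobytes().decode("ascii")
        cpg_positions[chrom] = pos
        meth_state[chrom] = meth
        truth_domains.extend(DomainInterval(chrom, s, e, HYPO) for s, e in domains)
        covered = sorted(domains)
        prev = 0
        for s, e in covered:
            if s > prev:
                truth_domains.append(DomainInterval(chrom, prev, s, BACKGROUND))
            prev = e
        if prev < L:
            truth_domains.append(DomainInterval(chrom, prev, L, BACKGROUND))
        genes.extend(chrom_genes)

    chrom_lengths = {c: len(s) for c, s in sequences.items()}
    marks = _mark_tracks(streams["marks"], chrom_lengths, truth_domains, config)

    # expression coupled to the mark landscape over each gene
    from methdom.tracks import Region, gene_mark_score  # local import avoids cycle at load

    c_ac, c_me = config.expression_coupling
    rng_e = streams["expression"]
    for g in genes:
        ac = gene_mark_score(g, marks["H3K9Ac"], Region.WHOLE)
        me = gene_mark_score(g, marks["H3K27Me3"], Region.WHOLE)
        g.expression = float(
            np.exp(c_ac * ac + c_me * me + rng_e.normal(0, config.expression_noise_sd))
        )

    model = GenomeModel(
        sequences=sequences,
        cpg_positions=cpg_positions,
        meth_state=meth_state,
        truth_domains=sorted(truth_domains, key=lambda d: (d.chrom, d.start)),
        genes=genes,
        mark_tracks=marks,
        config=config,
    )
    model.validate()
    return model


def apply_sssi(model: GenomeModel) -> GenomeModel:
    """Fully CpG-methylated copy: the SssI in-vitro methylation control."""
    out = model.copy()
    for chrom in out.meth_state:
        out.meth_state[chrom] = np.ones_like(out.meth_state[chrom])
    return out


def remethylate_domain(
    model: GenomeModel, domain_index: int, meth: Optional[float] = None
) -> GenomeModel:
    """Copy of the model with one truth HYPO domain re-methylated.

    Stand-in for a drug treatment that flips a whole domain en bloc; ``meth``
    defaults to the config's background methylation probability.
    """
    hypo = model.hypo_domains()
    if not 0 <= domain_index < len(hypo):
        raise IndexError(f"domain_index {domain_index} out of range (n={len(hypo)})")
    if meth is None:
        meth = model.config.background_meth if model.config else 0.85
    d = hypo[domain_index]
    out = model.copy()
    pos = out.cpg_positions[d.chrom]
    lo = np.searchsorted(pos, d.start)
    hi = np.searchsorted(pos, d.end)
    out.meth_state[d.chrom][lo:hi] = meth
    return out
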