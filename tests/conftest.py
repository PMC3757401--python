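import numpy as np
import pytest

from methdom.config import SimConfig
from methdom.genome import GenomeModel, simulate_genome


def model_from_sequence(seq: str, meth=1.0, chrom: str = "chr1") -> GenomeModel:
    """Minimal GenomeModel around a raw sequence; meth is scalar or per-CpG array."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    pos = np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G"))).astype(np.int64)
    if np.isscalar(meth):
        m = np.full(len(pos), float(meth))
    else:
        m = np.asarray(meth, dtype=float)
        assert len(m) == len(pos), "meth array must align with CpG count"
    return GenomeModel(
        sequences={chrom: seq},
        cpg_positions={chrom: pos},
        meth_state={chrom: m},
        truth_domains=[],
        genes=[],
        mark_tracks={},
    )


def random_sequence(rng: np.random.Generator, length: int, cpg_boost: float = 0.02) -> str:
    """Random sequence with CpGs sprinkled in at roughly cpg_boost per bp."""
    seq = rng.choice(list("ACGT"), size=length)
    n_cpg = rng.poisson(cpg_boost * length)
    if n_cpg and length > 2:
        starts = rng.choice(length - 1, size=min(n_cpg, length // 3), replace=False)
        for s in starts:
            seq[s] = "C"
            seq[s + 1] = "G"
    return "".join(seq)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(
        genome_length=400_000,
        n_hypo_domains=1,
        hypo_domain_length=(60_000, 80_000),
        n_genes=20,
        gene_length_range=(2_000, 6_000),
        mark_window=10_000,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_model(small_config) -> GenomeModel:
    return simulate_genome(small_config)
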