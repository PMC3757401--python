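import math

import numpy as np
import pytest

from methdom.bisulfite import (
    BisRead,
    bisulfite_convert,
    call_methylation,
    sample_validation_sites,
    simulate_reads,
    site_methylation,
    validate_domains,
)
from methdom.config import SimConfig
from methdom.domains import DomainCall, ProbeLabel
from methdom.genome import simulate_genome
from tests.conftest import model_from_sequence, random_sequence


class TestBisulfiteConvert:
    def test_fully_methylated_template(self):
        seq = "ACGTCCGA"  # CpGs at 1 and 5; non-CpG Cs at 4
        model = model_from_sequence(seq, 1.0)
        out = bisulfite_convert(seq, model.cpg_positions["chr1"], model.meth_state["chr1"], seed=0)
        assert out == "ACGTTCGA"  # CpG Cs kept, lone C converted

    def test_fully_unmethylated_template(self):
        seq = "ACGTCCGA"
        model = model_from_sequence(seq, 0.0)
        out = bisulfite_convert(seq, model.cpg_positions["chr1"], model.meth_state["chr1"], seed=0)
        assert "C" not in out

    def test_half_methylated_binomial(self):
        seq = ("AACGTT" * 200)  # 200 CpGs
        model = model_from_sequence(seq, 0.5)
        retained = []
        for seed in range(50):
            out = bisulfite_convert(
                seq, model.cpg_positions["chr1"], model.meth_state["chr1"], seed=seed
            )
            retained.append(out.count("C") / 200)
        mean = float(np.mean(retained))
        # 10000 draws of Bernoulli(0.5): tolerance of 5 binomial sigmas
        assert abs(mean - 0.5) < 5 * math.sqrt(0.25 / (200 * 50))

    def test_partial_efficiency_leaves_some_c(self):
        seq = "ACCCCCCCCA"
        out = bisulfite_convert(seq, np.array([], dtype=np.int64), np.array([]), seed=1,
                                efficiency=0.5)
        assert 0 < out.count("C") < 8


class TestSimulateReads:
    @pytest.fixture()
    def model(self):
        rng = np.random.default_rng(5)
        return model_from_sequence(random_sequence(rng, 10_000, cpg_boost=0.02), 1.0)

    def test_zero_coverage_empty(self, model):
        assert simulate_reads(model, ("chr1", 0, 10_000), 0.0) == []

    def test_read_count_expectation(self, model):
        reads = simulate_reads(model, ("chr1", 0, 10_000), 30.0, read_len=100, seed=1)
        assert len(reads) == 3_000

    def test_same_seed_identical(self, model):
        a = simulate_reads(model, ("chr1", 0, 5_000), 5.0, seed=9)
        b = simulate_reads(model, ("chr1", 0, 5_000), 5.0, seed=9)
        assert a == b

    def test_reads_within_region(self, model):
        reads = simulate_reads(model, ("chr1", 2_000, 4_000), 10.0, read_len=100, seed=2)
        assert all(2_000 <= r.start and r.end <= 4_000 for r in reads)

    def test_bad_region_rejected(self, model):
        with pytest.raises(ValueError, match="out of bounds"):
            simulate_reads(model, ("chr1", 0, 20_000), 1.0)
        with pytest.raises(ValueError, match="read_len"):
            simulate_reads(model, ("chr1", 0, 50), 1.0, read_len=100)


class TestCallMethylation:
    def test_all_c_reads(self):
        reads = [BisRead("chr1", 0, 4, "+", "ACGT") for _ in range(6)]
        (call,) = call_methylation(reads, np.array([1]), min_coverage=5)
        assert call.meth_fraction == 1.0
        assert call.coverage == 6
        assert not call.low_coverage

    def test_mixed_counts(self):
        reads = [BisRead("chr1", 0, 4, "+", "ACGT")] * 3 + [
            BisRead("chr1", 0, 4, "+", "ATGT")
        ] * 7
        (call,) = call_methylation(reads, np.array([1]), min_coverage=5)
        assert call.n_C == 3 and call.n_T == 7
        assert call.meth_fraction == pytest.approx(0.3)

    def test_minus_strand_reads_counted(self):
        # genome ...ACGT...; minus read over [0,4) is revcomp = ACGT; the
        # minus-strand C of the CpG at pos 1 sits at genomic 2, read index 1
        reads = [BisRead("chr1", 0, 4, "-", "ACGT") for _ in range(4)]
        (call,) = call_methylation(reads, np.array([1]), min_coverage=1)
        assert call.n_C == 4  # unconverted => methylated on the minus strand

    def test_coverage_bounded_by_reads(self):
        rng = np.random.default_rng(3)
        model = model_from_sequence(random_sequence(rng, 2_000, 0.02), 0.85)
        reads = simulate_reads(model, ("chr1", 0, 2_000), 8.0, seed=0)
        calls = call_methylation(reads, model.cpg_positions["chr1"], min_coverage=0)
        for c in calls:
            n_overlap = sum(1 for r in reads if r.start <= c.pos < r.end or r.start <= c.pos + 1 < r.end)
            assert c.coverage <= n_overlap

    def test_low_coverage_flagged(self):
        reads = [BisRead("chr1", 0, 4, "+", "ACGT")]
        (call,) = call_methylation(reads, np.array([1]), min_coverage=5)
        assert call.low_coverage


class TestStrandConsistency:
    def test_both_strands_agree_on_full_methylation(self):
        rng = np.random.default_rng(11)
        model = model_from_sequence(random_sequence(rng, 3_000, 0.03), 1.0)
        reads = simulate_reads(model, ("chr1", 0, 3_000), 20.0, seed=4)
        calls = call_methylation(reads, model.cpg_positions["chr1"], min_coverage=1)
        covered = [c for c in calls if c.coverage > 0]
        assert covered
        assert all(c.meth_fraction == 1.0 for c in covered)

    def test_both_strands_agree_on_no_methylation(self):
        rng = np.random.default_rng(12)
        model = model_from_sequence(random_sequence(rng, 3_000, 0.03), 0.0)
        reads = simulate_reads(model, ("chr1", 0, 3_000), 20.0, seed=4)
        calls = call_methylation(reads, model.cpg_positions["chr1"], min_coverage=1)
        covered = [c for c in calls if c.coverage > 0]
        assert covered
        assert all(c.meth_fraction == 0.0 for c in covered)


class TestRecovery:
    def test_binomial_error_bound(self):
        p = 0.85
        rng = np.random.default_rng(21)
        model = model_from_sequence(random_sequence(rng, 20_000, 0.02), p)
        reads = simulate_reads(model, ("chr1", 0, 20_000), 30.0, seed=5)
        calls = call_methylation(reads, model.cpg_positions["chr1"], min_coverage=5)
        fractions = [c.meth_fraction for c in calls if not c.low_coverage]
        assert len(fractions) > 100
        mae = float(np.mean(np.abs(np.array(fractions) - p)))
        assert mae < 2 * math.sqrt(p * (1 - p) / 30)


class TestValidateDomains:
    def test_perfect_concordance(self):
        domains = [DomainCall("chr1", 0, 1_000, ProbeLabel.HYPO, 10, 3.0)]
        calls = [_mk_call(100, 0.0), _mk_call(500, 0.0), _mk_call(5_000, 1.0)]
        report = validate_domains(calls, domains)
        assert report.concordance == 1.0
        assert report.mean_meth_inside == 0.0
        assert report.mean_meth_outside == 1.0

    def test_random_labels_near_half(self):
        rng = np.random.default_rng(8)
        domains = [DomainCall("chr1", 0, 5_000, ProbeLabel.HYPO, 10, 3.0)]
        calls = [
            _mk_call(int(rng.integers(0, 10_000)), float(rng.integers(0, 2)))
            for _ in range(2_000)
        ]
        report = validate_domains(calls, domains)
        assert abs(report.concordance - 0.5) < 0.05


def _mk_call(pos, fraction, coverage=10):
    from methdom.bisulfite import CpGCall

    n_c = int(round(fraction * coverage))
    return CpGCall("chr1", pos, n_c, coverage - n_c)


class TestValidationSites:
    def test_39_sites_in_hypo_domain_all_unmethylated(self):
        cfg = SimConfig(
            genome_length=1_500_000,
            n_hypo_domains=1,
            hypo_domain_length=(400_000, 500_000),
            domain_meth=0.05,
            n_genes=0,
            seed=23,
        )
        model = simulate_genome(cfg)
        (domain,) = model.hypo_domains()
        sites = sample_validation_sites(
            model, (domain.chrom, domain.start, domain.end), n_sites=39, seed=1
        )
        assert len(sites) == 39
        fractions = [
            site_methylation(model, s, coverage=30.0, seed=100 + i)
            for i, s in enumerate(sites)
        ]
        assert not any(math.isnan(f) for f in fractions)  # every site has CpGs
        assert all(f < 0.1 for f in fractions)

    def test_sites_do_not_overlap(self):
        model = model_from_sequence("A" * 100_000)
        sites = sample_validation_sites(
            model, ("chr1", 0, 100_000), n_sites=20, seed=0, min_cpgs=0
        )
        sites.sort(key=lambda s: s[1])
        for (_, _, e1), (_, s2, _) in zip(sites, sites[1:]):
            assert e1 <= s2
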