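import math

import numpy as np
import pandas as pd
import pytest

from methdom import tracks
from methdom.config import SimConfig
from methdom.genome import GeneModel, simulate_genome
from methdom.tracks import (
    GenePattern,
    Region,
    WindowTrack,
    classify_gene_pattern,
    cpg_density_track,
    gene_density_track,
    gene_mark_score,
    gene_methylation_patterns,
    mark_expression_correlation,
    track_correlation,
)
from tests.conftest import model_from_sequence, random_sequence
from tests.oracles import brute_interval_mean, brute_window_cpg_counts, textbook_pearson


def make_track(values, width=100, chrom="chr1"):
    starts = np.arange(len(values)) * width
    return WindowTrack(
        width=width,
        data=pd.DataFrame(
            {"chrom": chrom, "start": starts, "end": starts + width, "value": values}
        ),
    )


class TestCpgDensityTrack:
    def test_single_cpg_window_scores_two(self):
        seq = "A" * 30 + "CG" + "A" * 68  # one window, one CpG
        track = cpg_density_track(model_from_sequence(seq), window=100)
        assert track.values.tolist() == [2.0]

    def test_hundred_cpgs_score_four(self):
        seq = "CGAA" * 100  # 100 CpGs in a 400 bp window
        track = cpg_density_track(model_from_sequence(seq), window=400)
        assert track.values.tolist() == [4.0]

    def test_zero_cpg_sentinel(self):
        track = cpg_density_track(model_from_sequence("A" * 200), window=100)
        assert track.values.tolist() == [0.0, 0.0]
        assert track.data["empty"].all()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_substring_count_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_sequence(rng, 5_000, cpg_boost=0.03)
        window = 500
        track = cpg_density_track(model_from_sequence(seq), window=window)
        for value, count in zip(track.values, brute_window_cpg_counts(seq, window)):
            expected = math.log10(count) + 2 if count else 0.0
            assert value == pytest.approx(expected, abs=1e-12)

    def test_windows_tile_chromosome(self):
        track = cpg_density_track(model_from_sequence("ACGT" * 300), window=250)
        data = track.data
        assert data["start"].iloc[0] == 0
        assert (data["start"].iloc[1:].to_numpy() == data["end"].iloc[:-1].to_numpy()).all()
        assert data["end"].iloc[-1] == 1_200


class TestGeneDensityTrack:
    def test_empty(self):
        track = gene_density_track([], {"chr1": 1_000}, window=100)
        assert (track.values == 0).all()

    def test_counts_and_conservation(self):
        genes = [
            GeneModel(f"g{i}", "chr1", start, start + 50, "+", 1.0)
            for i, start in enumerate([10, 20, 30, 150, 990])
        ]
        track = gene_density_track(genes, {"chr1": 1_000}, window=100)
        assert track.values[0] == 3
        assert track.values[1] == 1
        assert track.values.sum() == len(genes)


class TestTrackCorrelation:
    def test_self_correlation(self):
        rng = np.random.default_rng(0)
        a = make_track(rng.random(50))
        res = track_correlation(a, a)
        assert res.r == pytest.approx(1.0)
        assert res.defined

    def test_negated(self):
        rng = np.random.default_rng(0)
        vals = rng.random(50)
        res = track_correlation(make_track(vals), make_track(-vals))
        assert res.r == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(3)
        x, y = rng.random(200), rng.random(200)
        res = track_correlation(make_track(x), make_track(y))
        assert res.r == pytest.approx(textbook_pearson(x, y), abs=1e-10)

    def test_zero_variance_flagged(self):
        res = track_correlation(make_track([1.0] * 10), make_track(np.arange(10.0)))
        assert not res.defined
        assert math.isnan(res.r)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            track_correlation(make_track([1, 2, 3]), make_track([1, 2, 3, 4]))


class TestGeneMarkScore:
    def test_gene_inside_one_window(self):
        track = make_track([5.0, 7.0], width=1_000)
        gene = GeneModel("g", "chr1", 100, 600, "+", 1.0)
        assert gene_mark_score(gene, track, Region.WHOLE) == 5.0

    def test_equal_split_two_windows(self):
        track = make_track([2.0, 6.0], width=1_000)
        gene = GeneModel("g", "chr1", 500, 1_500, "+", 1.0)
        assert gene_mark_score(gene, track, Region.WHOLE) == pytest.approx(4.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_bp_oracle(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.random(10)
        track = make_track(values, width=50)
        start = int(rng.integers(0, 400))
        end = start + int(rng.integers(10, 100))
        gene = GeneModel("g", "chr1", start, end, "+", 1.0)
        expected = brute_interval_mean(
            track.data["start"], 50, values, start, end
        )
        assert gene_mark_score(gene, track, Region.WHOLE) == pytest.approx(expected)

    def test_region_selection(self):
        track = make_track(np.arange(10.0), width=1_000)
        gene = GeneModel("g", "chr1", 2_000, 6_000, "+", 1.0)
        whole = gene_mark_score(gene, track, Region.WHOLE)
        promoter = gene_mark_score(gene, track, Region.PROMOTER)
        body = gene_mark_score(gene, track, Region.BODY)
        assert promoter < whole < body  # ramp track: promoter upstream of body


class TestMarkExpressionCorrelation:
    def _genes_with_scores(self, track, n=50, rng=None):
        rng = rng or np.random.default_rng(0)
        genes = []
        for i in range(n):
            start = int(rng.integers(0, 90)) * 100
            genes.append(GeneModel(f"g{i}", "chr1", start, start + 80, "+", 0.0))
        return genes

    def test_exact_linear_coupling(self):
        rng = np.random.default_rng(1)
        track = make_track(rng.random(100), width=100)
        genes = self._genes_with_scores(track, rng=rng)
        for g in genes:
            g.expression = 3.0 * gene_mark_score(g, track, Region.WHOLE) + 1.0
        res = mark_expression_correlation(genes, track)
        assert res.r == pytest.approx(1.0)
        assert res.p < 1e-10

    def test_permuted_expression_decorrelates(self):
        rng = np.random.default_rng(2)
        track = make_track(rng.random(100), width=100)
        genes = self._genes_with_scores(track, n=100, rng=rng)
        for g in genes:
            g.expression = 3.0 * gene_mark_score(g, track, Region.WHOLE)
        pvals = []
        for _ in range(50):
            expr = np.array([g.expression for g in genes])
            rng.shuffle(expr)
            for g, e in zip(genes, expr):
                g.expression = float(e)
            pvals.append(mark_expression_correlation(genes, track).p)
        # roughly uniform p-values: mean near 0.5, a fair share above 0.5
        assert 0.25 < float(np.mean(pvals)) < 0.75
        assert sum(p > 0.5 for p in pvals) >= 10

    def test_too_few_genes_rejected(self):
        track = make_track([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            mark_expression_correlation([], track)


class TestClassifyGenePattern:
    def _gene(self):
        return GeneModel("g", "chr1", 2_000, 10_000, "+", 1.0)

    def test_active_pattern(self):
        gene = self._gene()
        # promoter [1000, 2500), body [2500, 10000)
        cpg = np.array([1_500, 2_000, 3_000, 6_000])
        meth = np.array([0.05, 0.05, 0.9, 0.9])
        res = classify_gene_pattern(gene, cpg, meth)
        assert res.pattern is GenePattern.ACTIVE_PATTERN
        assert res.promoter_meth == pytest.approx(0.05)
        assert res.body_meth == pytest.approx(0.9)

    def test_silenced_pattern(self):
        res = classify_gene_pattern(
            self._gene(), np.array([1_500, 3_000]), np.array([0.9, 0.05])
        )
        assert res.pattern is GenePattern.SILENCED_PATTERN

    def test_mixed_pattern(self):
        res = classify_gene_pattern(
            self._gene(), np.array([1_500, 3_000]), np.array([0.9, 0.9])
        )
        assert res.pattern is GenePattern.MIXED

    def test_no_cpg_flagged_missing(self):
        res = classify_gene_pattern(self._gene(), np.array([]), np.array([]))
        assert res.missing
        assert res.pattern is GenePattern.MIXED
        assert math.isnan(res.promoter_meth)


def test_active_genes_express_more_than_silenced():
    cfg = SimConfig(
        genome_length=4_000_000,
        n_hypo_domains=2,
        hypo_domain_length=(400_000, 600_000),
        n_genes=200,
        gene_length_range=(3_000, 10_000),
        hypo_gene_fraction=0.25,
        seed=17,
    )
    model = simulate_genome(cfg)
    patterns = gene_methylation_patterns(model)
    by_id = {p.gene_id: p.pattern for p in patterns}
    active = [g.expression for g in model.genes if by_id[g.id] is GenePattern.ACTIVE_PATTERN]
    silenced = [g.expression for g in model.genes if by_id[g.id] is GenePattern.SILENCED_PATTERN]
    assert len(active) >= 100 and len(silenced) >= 20
    assert np.mean(active) > np.mean(silenced)


def test_fold_change_anticorrelates_with_cpg_density():
    """Windowed mean fold change vs CpG density is negative on simulations."""
    from methdom import arraycgh, mcrbc

    negatives = 0
    for seed in range(3):
        cfg = SimConfig(
            genome_length=3_000_000,
            n_hypo_domains=2,
            hypo_domain_length=(300_000, 500_000),
            n_genes=0,
            seed=100 + seed,
        )
        model = simulate_genome(cfg)
        frags = mcrbc.size_select(mcrbc.digest(model), 20_000)
        grid = arraycgh.normalize(
            arraycgh.simulate_signals(
                arraycgh.make_probe_grid(model, 5_000), frags, 0.2, seed
            )
        )
        density = cpg_density_track(model, window=50_000)
        win = (grid["start"] // 50_000).to_numpy()
        mean_fold = grid.groupby(win)["fold_change"].mean()
        aligned = density.values[mean_fold.index.to_numpy()]
        r = textbook_pearson(mean_fold.to_numpy(), aligned)
        negatives += r < 0
    assert negatives == 3
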