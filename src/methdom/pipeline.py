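"""End-to-end orchestration: simulate -> digest -> size-select -> array ->
normalize -> classify -> segment -> summarize -> tracks -> bisulfite
validation (-> optional two-condition comparison), with a run manifest.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import os
from dataclasses import asdict
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

import methdom
from methdom import arraycgh, bisulfite, differential, domains as dom, io, mcrbc, tracks
from methdom.config import SimConfig
from methdom.genome import GenomeModel, apply_sssi, remethylate_domain, simulate_genome


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    outdir: Path,
    config: SimConfig,
    params: Dict,
    files: List[Path],
) -> Dict:
    manifest = {
        "tool": "methdom",
        "version": methdom.__version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "seed": config.seed,
        "config": config.to_dict(),
        "params": params,
        "files": {str(p.relative_to(outdir)): _sha256(p) for p in sorted(files)},
    }
    target = outdir / "manifest.json"
    tmp = target.with_suffix(".json.tmp")
    tmp.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    os.replace(tmp, target)  # atomic publish
    return manifest


def run_pipeline(
    config: SimConfig,
    outdir,
    digest_params: Optional[mcrbc.DigestParams] = None,
    probe_spacing: int = 5_000,
    probe_footprint: int = 60,
    hypo_cut: float = 2.0,
    hyper_cut: float = 0.5,
    max_gap: int = 2,
    min_probes: int = 5,
    cpg_window: int = tracks.DEFAULT_WINDOW,
    bis_coverage: float = 30.0,
    bis_n_sites: int = 39,
    bis_site_width: int = 1_500,
    with_treatment: bool = False,
) -> Dict:
    """Run every stage on one simulated genome; returns the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = {
        "probe_spacing": probe_spacing,
        "probe_footprint": probe_footprint,
        "hypo_cut": hypo_cut,
        "hyper_cut": hyper_cut,
        "max_gap": max_gap,
        "min_probes": min_probes,
        "cpg_window": cpg_window,
        "bis_coverage": bis_coverage,
        "bis_n_sites": bis_n_sites,
        "bis_site_width": bis_site_width,
        "with_treatment": with_treatment,
    }
    dp = digest_params or mcrbc.DigestParams()
    params["digest"] = asdict(dp)
    files: List[Path] = []

    def emit(name: str):
        p = outdir / name
        files.append(p)
        return p

    # stage: simulate
    model = simulate_genome(config)
    io.write_fasta(model.sequences, emit("genome.fasta"))
    io.write_meth_bedgraph(model, emit("methylation.bedgraph"))
    truth_df = pd.DataFrame(
        {
            "chrom": [d.chrom for d in model.truth_domains],
            "start": [d.start for d in model.truth_domains],
            "end": [d.end for d in model.truth_domains],
            "name": [d.label for d in model.truth_domains],
        }
    )
    io.write_bed(truth_df, emit("truth_domains.bed"))
    io.write_genes_tsv(model.genes, emit("genes.tsv"))
    for mark, track in model.mark_tracks.items():
        io.write_bedgraph(track.data, emit(f"mark_{mark}.bedgraph"))

    # stage: SssI control digestion (full-methylation sanity track)
    sssi = apply_sssi(model)
    sssi_frags = mcrbc.size_select(mcrbc.digest(sssi, dp), dp.size_threshold)
    io.write_bed(mcrbc.fragments_to_frame(sssi_frags), emit("fragments_sssi_resistant.bed"))

    # stage: digest + size selection
    fragments = mcrbc.digest(model, dp)
    io.write_bed(mcrbc.fragments_to_frame(fragments), emit("fragments.bed"))
    mcrbc.fragment_length_histogram(fragments).to_csv(
        emit("fragment_gel.tsv"), sep="\t", index=False
    )
    resistant = mcrbc.size_select(fragments, dp.size_threshold)
    io.write_bed(mcrbc.fragments_to_frame(resistant), emit("fragments_resistant.bed"))

    # stage: array simulation + normalization
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xA88A]))
    grid = arraycgh.make_probe_grid(model, probe_spacing, probe_footprint)
    grid = arraycgh.simulate_signals(
        grid, resistant, config.noise_sd, int(rng.integers(0, 2**31))
    )
    grid = arraycgh.normalize(grid)
    io.write_probe_tsv(grid, emit("probes.tsv"))

    # stage: classify + segment + summarize
    calls = dom.classify_probes(grid, hypo_cut, hyper_cut)
    domain_calls = dom.segment(calls, grid, max_gap=max_gap, min_probes=min_probes)
    df = dom.domains_to_frame(domain_calls)
    bed = df.rename(columns={"label": "name"})
    bed["score"] = (100 * bed["mean_fold_change"]).round().astype(np.int64).clip(0, 1000)
    io.write_bed(bed, emit("domain_calls.bed"))
    dom.summaries_to_frame(dom.summarize_chromosomes(calls, grid)).to_csv(
        emit("chromosome_summary.tsv"), sep="\t", index=False
    )
    recovery = dom.compare_to_truth(domain_calls, model.truth_domains)

    # stage: tracks and correlations
    cpg_track = tracks.cpg_density_track(model, cpg_window)
    io.write_bedgraph(cpg_track.data, emit("cpg_density.bedgraph"))
    gene_track = tracks.gene_density_track(model.genes, model.chrom_lengths, cpg_window)
    io.write_bedgraph(gene_track.data, emit("gene_density.bedgraph"))
    corr_rows = []
    if len(model.genes) >= 3:
        for mark in ("H3K9Ac", "H3K27Me3"):
            r = tracks.mark_expression_correlation(model.genes, model.mark_tracks[mark])
            corr_rows.append(
                {"pair": f"{mark}_vs_expression", "r": r.r, "p": r.p, "n": r.n}
            )
    mark_corr = tracks.track_correlation(
        model.mark_tracks["H3K9Ac"], model.mark_tracks["H3K27Me3"]
    )
    corr_rows.append(
        {"pair": "H3K9Ac_vs_H3K27Me3", "r": mark_corr.r, "p": mark_corr.p, "n": mark_corr.n}
    )
    pd.DataFrame(corr_rows).to_csv(emit("correlations.tsv"), sep="\t", index=False)
    tracks.patterns_to_frame(tracks.gene_methylation_patterns(model)).to_csv(
        emit("gene_patterns.tsv"), sep="\t", index=False
    )

    # stage: bisulfite validation of the largest called HYPO domain
    hypo_calls = [d for d in domain_calls if d.label is dom.ProbeLabel.HYPO]
    if hypo_calls:
        biggest = max(hypo_calls, key=lambda d: d.end - d.start)
        site_seed = int(rng.integers(0, 2**31))
        # cap at what fits: sites are non-overlapping within the domain
        n_sites = min(bis_n_sites, (biggest.end - biggest.start) // (2 * bis_site_width))
        sites = bisulfite.sample_validation_sites(
            model,
            (biggest.chrom, biggest.start, biggest.end),
            n_sites=n_sites,
            site_width=bis_site_width,
            seed=site_seed,
        )
        fractions = [
            bisulfite.site_methylation(
                model, s, coverage=bis_coverage, seed=int(rng.integers(0, 2**31))
            )
            for s in sites
        ]
        pd.DataFrame(
            {
                "chrom": [s[0] for s in sites],
                "start": [s[1] for s in sites],
                "end": [s[2] for s in sites],
                "meth_fraction": fractions,
            }
        ).to_csv(emit("bisulfite_validation.tsv"), sep="\t", index=False)

    # stage: optional en-bloc comparison against a re-methylated condition
    if with_treatment and model.hypo_domains():
        treated_model = remethylate_domain(model, 0)
        t_frags = mcrbc.size_select(mcrbc.digest(treated_model, dp), dp.size_threshold)
        t_grid = arraycgh.make_probe_grid(model, probe_spacing, probe_footprint)
        t_grid = arraycgh.simulate_signals(
            t_grid, t_frags, config.noise_sd, int(rng.integers(0, 2**31))
        )
        t_grid = arraycgh.normalize(t_grid)
        track = differential.smooth(differential.ratio_of_ratios(grid, t_grid))
        io.write_bedgraph(
            track.rename(columns={"ratio_of_ratios": "value"})[
                ["chrom", "start", "end", "value"]
            ],
            emit("differential_raw.bedgraph"),
        )
        changes = differential.detect_enbloc(track, domain_calls)
        pd.DataFrame(
            {
                "chrom": [c.chrom for c in changes],
                "start": [c.start for c in changes],
                "end": [c.end for c in changes],
                "verdict": [c.verdict.value for c in changes],
                "mean_smoothed": [c.mean_smoothed for c in changes],
                "agreement": [c.agreement for c in changes],
            }
        ).to_csv(emit("domain_changes.tsv"), sep="\t", index=False)

    manifest = write_manifest(outdir, config, params, files)
    manifest["recovery"] = {
        "jaccard": recovery.jaccard,
        "max_boundary_offset": recovery.max_boundary_offset,
    }
    return manifest
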