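# methdom

Methylation-domain mapping by simulated McrBC digestion and array-CGH
readout.

Unmethylated DNA resists the methylation-dependent McrBC enzyme, so the
large fragments that survive digestion mark hypomethylated genomic domains.
`methdom` implements that assay end to end, in silico, with full ground
truth:

- **genome simulation** — chromosomes with CpG dinucleotides injected at
  controlled rates, megabase-scale hypomethylated domains placed in CpG-poor
  and gene-poor regions, per-CpG methylation probabilities, complementary
  H3K9Ac / H3K27Me3 window tracks, and gene expression coupled positively to
  H3K9Ac and negatively to H3K27Me3;
- **digestion** — purine-mC half-site model, midpoint cuts between eligible
  half-site pairs (40–3000 bp apart), gel-style size selection of
  high-molecular-weight resistant fragments, plus an SssI full-methylation
  control;
- **array readout** — two-channel probe signals (resistant vs total
  genomic), lognormal noise, median normalization, fold-change and log2
  ratios;
- **domain calling** — fold change > 2 ⇒ hypomethylated, < 0.5 ⇒
  hypermethylated (strict inequalities), run merging with gap tolerance,
  per-chromosome hypo/hyper summaries, recovery metrics against truth;
- **tracks** — the 50 kb CpG-density track (log10 of the window CpG count,
  plus 2), gene density, Pearson track/expression correlations, per-gene
  promoter/body methylation pattern classification;
- **bisulfite validation** — per-molecule conversion, read simulation at
  chosen loci, per-CpG C/T calling, and domain concordance reports;
- **differential analysis** — control/treated ratio-of-ratios with a
  smoothed average, en-bloc domain change verdicts, and discordantly
  labelled probe sites between two conditions.

Everything is deterministic given a seed. No external data is required;
real-data mode consumes a FASTA genome plus the documented TSV/bedGraph
formats.

## Command line

```sh
methdom simulate   --config config.yaml --seed 1 --outdir out/
methdom digest     --fasta out/genome.fasta --meth out/methylation.bedgraph \
                   --out-fragments frags.bed --out-resistant resistant.bed --out-hist gel.tsv
methdom array      --fasta out/genome.fasta --fragments resistant.bed --out probes.tsv
methdom call-domains --probes probes.tsv --out-domains domains.bed --out-summary chrom.tsv
methdom cpg-density --fasta out/genome.fasta --out density.bedgraph
methdom bisulfite  --fasta out/genome.fasta --meth out/methylation.bedgraph \
                   --region chr1:100000-150000 --out-calls calls.tsv
methdom compare    --control probes_a.tsv --treated probes_b.tsv --out-prefix diff
methdom correlate  --track-a density.bedgraph --track-b mark.bedgraph
methdom run-all    --config config.yaml --seed 1 --outdir run/
```

`run-all` executes simulate → SssI control → digest → size-select → array →
normalize → classify → segment → summarize → tracks → bisulfite validation
(→ optional treatment comparison with `--with-treatment`) and writes a
`manifest.json` recording the config, seed, parameters and SHA-256 digests
of every output.

The simulation config is a YAML file; every field of `SimConfig`
(`src/methdom/config.py`) is addressable. Defaults describe a 10 Mb
chromosome with three 0.5–1 Mb hypomethylated domains.

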