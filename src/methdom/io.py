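"""Readers and writers for the plain-text interchange formats.

BED and bedGraph intervals are 0-based half-open. Malformed lines are
reported with file name and 1-based line number. CRLF input is accepted and
normalized. Tables are tab-separated with a header row and '.' for missing
values.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from methdom.arraycgh import PROBE_COLUMNS, validate_probe_table
from methdom.genome import GeneModel

MISSING = "."


# -- FASTA ------------------------------------------------------------------


def write_fasta(sequences: Dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> Dict[str, str]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# -- BED / bedGraph ---------------------------------------------------------


def _parse_lines(path) -> Iterable[Tuple[int, List[str]]]:
    path = Path(path)
    with open(path, newline=None) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def _parse_interval(path, lineno: int, fields: List[str], min_fields: int) -> Tuple[str, int, int]:
    if len(fields) < min_fields:
        raise ValueError(
            f"{path}:{lineno}: expected at least {min_fields} tab-separated fields, "
            f"got {len(fields)}"
        )
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError:
        raise ValueError(f"{path}:{lineno}: non-integer coordinates {fields[1]!r}, {fields[2]!r}")
    if start < 0:
        raise ValueError(f"{path}:{lineno}: negative start {start}")
    if end <= start:
        raise ValueError(f"{path}:{lineno}: end ({end}) must exceed start ({start})")
    return chrom, start, end


def write_bed(df: pd.DataFrame, path) -> None:
    """Write (chrom, start, end[, name[, score]]) rows as BED."""
    cols = [c for c in ("chrom", "start", "end", "name", "score") if c in df.columns]
    with open(path, "w") as fh:
        for row in df[cols].itertuples(index=False):
            fh.write("\t".join(str(v) for v in row) + "\n")


def read_bed(path) -> pd.DataFrame:
    rows = []
    for lineno, fields in _parse_lines(path):
        chrom, start, end = _parse_interval(path, lineno, fields, 3)
        row = {"chrom": chrom, "start": start, "end": end}
        if len(fields) > 3:
            row["name"] = fields[3]
        if len(fields) > 4:
            row["score"] = fields[4]
        rows.append(row)
    if not rows:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    return pd.DataFrame(rows)


def write_bedgraph(df: pd.DataFrame, path) -> None:
    values = df["value"].to_numpy(float)
    if not np.isfinite(values).all():
        i = int(np.flatnonzero(~np.isfinite(values))[0])
        raise ValueError(f"non-finite bedGraph value at row {i}")
    with open(path, "w") as fh:
        for row in df[["chrom", "start", "end", "value"]].itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.value:.6g}\n")


def read_bedgraph(path) -> pd.DataFrame:
    rows = []
    for lineno, fields in _parse_lines(path):
        chrom, start, end = _parse_interval(path, lineno, fields, 4)
        try:
            value = float(fields[3])
        except ValueError:
            raise ValueError(f"{path}:{lineno}: non-numeric value {fields[3]!r}")
        if not math.isfinite(value):
            raise ValueError(f"{path}:{lineno}: non-finite value {fields[3]!r}")
        rows.append({"chrom": chrom, "start": start, "end": end, "value": value})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


# -- probe tables -----------------------------------------------------------


def write_probe_tsv(grid: pd.DataFrame, path) -> None:
    cols = [c for c in PROBE_COLUMNS if c in grid.columns]
    grid[cols].to_csv(path, sep="\t", index=False, na_rep=MISSING)


def read_probe_tsv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"probe table not found: {path}")
    df = pd.read_csv(path, sep="\t", na_values=[MISSING])
    required = ["id", "chrom", "start", "end"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: probe table missing column(s) {missing}")
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    has_signals = {"signal_resistant", "signal_total"} <= set(df.columns)
    if has_signals and not {"fold_change", "log2_ratio"} <= set(df.columns):
        df["fold_change"] = df["signal_resistant"] / df["signal_total"]
        df["log2_ratio"] = np.log2(df["fold_change"])
    validate_probe_table(df, signals=has_signals)
    return df


# -- gene tables ------------------------------------------------------------

GENE_COLUMNS = ["chrom", "start", "end", "id", "strand", "expression"]


def write_genes_tsv(genes: Sequence[GeneModel], path) -> None:
    pd.DataFrame(
        {
            "chrom": [g.chrom for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "id": [g.id for g in genes],
            "strand": [g.strand for g in genes],
            "expression": [g.expression for g in genes],
        }
    ).to_csv(path, sep="\t", index=False)


def read_genes_tsv(path) -> List[GeneModel]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in GENE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: gene table missing column(s) {missing}")
    return [
        GeneModel(
            id=str(r.id),
            chrom=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            strand=str(r.strand),
            expression=float(r.expression),
        )
        for r in df.itertuples()
    ]


# -- reads ------------------------------------------------------------------


def write_fastq(reads, path, quality_char: str = "I") -> None:
    """Reads as FASTQ with a fixed quality string; id encodes true coordinates."""
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            name = f"read{i:07d}/{r.chrom}:{r.start}-{r.end}({r.strand})"
            fh.write(f"@{name}\n{r.sequence}\n+\n{quality_char * r.length}\n")


# -- per-CpG methylation bedGraph ------------------------------------------


def write_meth_bedgraph(model, path) -> None:
    frames = []
    for chrom in sorted(model.sequences):
        pos = model.cpg_positions[chrom]
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": pos,
                    "end": pos + 2,
                    "value": model.meth_state[chrom],
                }
            )
        )
    write_bedgraph(pd.concat(frames, ignore_index=True), path)


def read_meth_bedgraph(path, sequences: Dict[str, str]):
    """Per-CpG methylation keyed to a genome; returns (positions, states) dicts."""
    df = read_bedgraph(path)
    positions: Dict[str, np.ndarray] = {}
    states: Dict[str, np.ndarray] = {}
    for chrom in sorted(sequences):
        sub = df[df["chrom"] == chrom].sort_values("start")
        positions[chrom] = sub["start"].to_numpy(np.int64)
        states[chrom] = sub["value"].to_numpy(float)
        if ((states[chrom] < 0) | (states[chrom] > 1)).any():
            raise ValueError(f"{path}: methylation values outside [0, 1] on {chrom}")
    return positions, states
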