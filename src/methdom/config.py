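"""Simulation configuration: validated parameter bundle for the generator."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Tuple

import yaml


def _as_pair(value, name: str) -> Tuple[int, int]:
    try:
        lo, hi = value
    except (TypeError, ValueError):
        raise ValueError(f"{name} must be a (min, max) pair, got {value!r}")
    return int(lo), int(hi)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a synthetic methylome genome.

    Probabilities are per-CpG methylation probabilities; rates are expected
    CpG dinucleotides per bp. ``seed`` drives every random draw downstream.
    """

    genome_length: int = 10_000_000
    n_chromosomes: int = 1
    gc_content: float = 0.42
    cpg_rate_high: float = 0.02
    cpg_rate_low: float = 0.005
    n_hypo_domains: int = 3
    hypo_domain_length: Tuple[int, int] = (500_000, 1_000_000)
    background_meth: float = 0.85
    domain_meth: float = 0.05
    n_genes: int = 200
    gene_length_range: Tuple[int, int] = (2_000, 20_000)
    hypo_gene_fraction: float = 0.1
    promoter_upstream: int = 1_000
    promoter_downstream: int = 500
    mark_window: int = 50_000
    mark_noise_sd: float = 0.05
    expression_coupling: Tuple[float, float] = (1.0, -1.0)
    expression_noise_sd: float = 0.5
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(
            self, "hypo_domain_length", _as_pair(self.hypo_domain_length, "hypo_domain_length")
        )
        object.__setattr__(
            self, "gene_length_range", _as_pair(self.gene_length_range, "gene_length_range")
        )
        object.__setattr__(
            self, "expression_coupling", tuple(float(x) for x in self.expression_coupling)
        )
        self.validate()

    def validate(self) -> None:
        """Raise ``ValueError`` naming the first offending field."""
        if self.genome_length < 2:
            raise ValueError(f"genome_length must be >= 2, got {self.genome_length}")
        if self.n_chromosomes < 1:
            raise ValueError(f"n_chromosomes must be >= 1, got {self.n_chromosomes}")
        for name in ("gc_content", "background_meth", "domain_meth", "hypo_gene_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("cpg_rate_high", "cpg_rate_low"):
            v = getattr(self, name)
            if not 0.0 <= v <= 0.5:
                raise ValueError(f"{name} must lie in [0, 0.5], got {v}")
        if self.n_hypo_domains < 0:
            raise ValueError(f"n_hypo_domains must be >= 0, got {self.n_hypo_domains}")
        lo, hi = self.hypo_domain_length
        if not 0 < lo <= hi:
            raise ValueError(f"hypo_domain_length must satisfy 0 < min <= max, got {lo, hi}")
        if hi > self.genome_length:
            raise ValueError(
                f"hypo_domain_length max ({hi}) exceeds genome_length ({self.genome_length})"
            )
        if self.n_genes < 0:
            raise ValueError(f"n_genes must be >= 0, got {self.n_genes}")
        glo, ghi = self.gene_length_range
        if not 0 < glo <= ghi:
            raise ValueError(f"gene_length_range must satisfy 0 < min <= max, got {glo, ghi}")
        if self.promoter_upstream < 0 or self.promoter_downstream < 0:
            raise ValueError("promoter_upstream/promoter_downstream must be >= 0")
        if self.mark_window < 1:
            raise ValueError(f"mark_window must be >= 1, got {self.mark_window}")
        for name in ("mark_noise_sd", "expression_noise_sd", "noise_sd"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        ac, me = self.expression_coupling
        if ac < 0 or me > 0:
            raise ValueError(
                "expression_coupling must be (non-negative activating, non-positive "
                f"repressive), got {self.expression_coupling}"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hypo_domain_length"] = list(self.hypo_domain_length)
        d["gene_length_range"] = list(self.gene_length_range)
        d["expression_coupling"] = list(self.expression_coupling)
        return d

    def replace(self, **kwargs) -> "SimConfig":
        d = asdict(self)
        d.update(kwargs)
        return SimConfig(**d)


def load_config(path) -> SimConfig:
    """Read a :class:`SimConfig` from a YAML mapping; unknown keys rejected."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    known = set(SimConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config field(s) in {path}: {sorted(unknown)}")
    return SimConfig(**raw)


def dump_config(config: SimConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
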