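"""Simulation configuration for synthetic pan-genome cohorts."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import yaml

logger = logging.getLogger(__name__)

SV_TYPES = ("DEL", "INV", "DUP", "TRA")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a synthetic cohort.

    Defaults describe a desk-scale rice-like cohort: 40 accessions in two
    population groups over a two-chromosome 1.2 Mb genome, 100 core and
    200 dispensable genes with strongly group-structured dispensable
    frequencies, a handful of 0.3-2 kb structural variants per accession,
    20-fold 100 bp paired-end sequencing with a 460 bp mean insert, and a
    heritable trait driven by one causal presence/absence marker.
    """

    seed: int = 0
    n_accessions: int = 40
    n_groups: int = 2
    chrom_lengths: tuple[int, ...] = (600_000, 600_000)
    n_core_genes: int = 100
    n_dispensable_genes: int = 200
    #: per-group (low, high) range the per-gene presence frequency is drawn from
    dispensable_freq_ranges: tuple[tuple[float, float], ...] = (
        (0.75, 0.95),
        (0.15, 0.35),
    )
    #: structural variants injected per accession, by type
    sv_counts: dict[str, int] = field(
        default_factory=lambda: {"DEL": 8, "INV": 4, "DUP": 4, "TRA": 1}
    )
    sv_size_range: tuple[int, int] = (300, 2000)
    read_length: int = 100
    depth: float = 20.0
    insert_mean: int = 460
    insert_sd: int = 50
    error_rate: float = 0.0
    gc: float = 0.5
    heritability: float = 0.6
    #: fraction of genetic variance carried by the causal marker
    causal_share: float = 0.5
    #: gene id, "auto" (pick a mid-frequency dispensable gene), or None
    causal_gene: str | None = "auto"

    def __post_init__(self) -> None:
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")
        for name in ("n_accessions", "n_core_genes", "n_dispensable_genes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if len(self.dispensable_freq_ranges) != self.n_groups:
            raise ValueError("need one dispensable frequency range per group")
        for lo, hi in self.dispensable_freq_ranges:
            if not (0 <= lo <= hi <= 1):
                raise ValueError("dispensable frequencies must satisfy 0 <= lo <= hi <= 1")
        for t, c in self.sv_counts.items():
            if t not in SV_TYPES:
                raise ValueError(f"unknown SV type {t!r}")
            if c < 0:
                raise ValueError("sv counts must be >= 0")
        lo, hi = self.sv_size_range
        if not (100 <= lo <= hi <= 1_000_000):
            raise ValueError("sv_size_range must lie within [100, 1000000]")
        if not 0 <= self.error_rate <= 1:
            raise ValueError("error_rate must lie in [0, 1]")
        if not 0 <= self.heritability <= 1:
            raise ValueError("heritability must lie in [0, 1]")
        if not 0 <= self.causal_share <= 1:
            raise ValueError("causal_share must lie in [0, 1]")
        if not 0 < self.gc < 1:
            raise ValueError("gc must lie in (0, 1)")
        if any(length <= 0 for length in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        if self.read_length <= 0 or self.depth < 0:
            raise ValueError("read_length must be positive and depth non-negative")
        if self.insert_mean <= 2 * self.read_length:
            logger.warning(
                "insert_mean %d <= 2*read_length %d; clamping to %d",
                self.insert_mean,
                self.read_length,
                2 * self.read_length,
            )
            object.__setattr__(self, "insert_mean", 2 * self.read_length)

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("chrom_lengths", "sv_size_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "dispensable_freq_ranges" in raw:
            raw["dispensable_freq_ranges"] = tuple(
                tuple(r) for r in raw["dispensable_freq_ranges"]
            )
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = {
            "seed": self.seed,
            "n_accessions": self.n_accessions,
            "n_groups": self.n_groups,
            "chrom_lengths": list(self.chrom_lengths),
            "n_core_genes": self.n_core_genes,
            "n_dispensable_genes": self.n_dispensable_genes,
            "dispensable_freq_ranges": [list(r) for r in self.dispensable_freq_ranges],
            "sv_counts": dict(self.sv_counts),
            "sv_size_range": list(self.sv_size_range),
            "read_length": self.read_length,
            "depth": self.depth,
            "insert_mean": self.insert_mean,
            "insert_sd": self.insert_sd,
            "error_rate": self.error_rate,
            "gc": self.gc,
            "heritability": self.heritability,
            "causal_share": self.causal_share,
            "causal_gene": self.causal_gene,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
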