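"""Map-to-pan gene presence/absence calling from alignment coverage.

A gene is scored per accession by coverage *breadth* — the fraction of its
bases under at least one aligned read — computed separately for the gene
body and for the coding region (union of CDS intervals of the
representative transcript).  A gene is called present when the coding
breadth exceeds 0.95 and the gene-body breadth exceeds 0.85 (both strict).
Accession-level QC mirrors the cohort filters: sequencing depth >= 20 fold
and mapping depth >= 15 fold.

All coordinates are 0-based half-open; conversion to/from 1-based GFF3
happens only in :mod:`panpav.io`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: strict presence thresholds: coding breadth > 0.95 AND body breadth > 0.85
DEFAULT_CDS_THRESHOLD = 0.95
DEFAULT_BODY_THRESHOLD = 0.85

#: accession QC: sequencing depth >= 20x and mapping depth >= 15x (inclusive)
DEFAULT_MIN_SEQ_DEPTH = 20.0
DEFAULT_MIN_MAP_DEPTH = 15.0


@dataclass(frozen=True)
class GeneModel:
    """A gene body plus the CDS intervals of its representative transcript.

    ``cds`` intervals must be non-overlapping and contained in
    ``[start, end)``; ``origin`` distinguishes reference genes from genes
    predicted on novel (non-reference) sequence.
    """

    gene_id: str
    seq_name: str
    start: int
    end: int
    strand: str = "+"
    cds: tuple[tuple[int, int], ...] = ()
    origin: str = "reference"

    def __post_init__(self) -> None:
        if self.end - self.start < 1:
            raise ValueError(f"gene {self.gene_id}: body length must be >= 1")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.origin not in ("reference", "novel"):
            raise ValueError(f"gene {self.gene_id}: origin must be reference|novel")
        srt = sorted(self.cds)
        for (s0, e0), (s1, e1) in zip(srt, srt[1:]):
            if s1 < e0:
                raise ValueError(f"gene {self.gene_id}: overlapping CDS intervals")
        for s, e in srt:
            if s < self.start or e > self.end:
                raise ValueError(f"gene {self.gene_id}: CDS outside gene body")
        object.__setattr__(self, "cds", tuple(srt))

    @property
    def body(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)


@dataclass(frozen=True)
class BreadthResult:
    """Per (gene, accession) coverage breadth over body and coding region."""

    gene_id: str
    accession: str
    body_fraction: float
    cds_fraction: float

    def __post_init__(self) -> None:
        for f in (self.body_fraction, self.cds_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("breadth fractions must lie in [0, 1]")


@dataclass(frozen=True)
class AccessionQc:
    accession: str
    sequencing_depth: float
    mapping_depth: float

    @property
    def passed(self) -> bool:
        return accession_qc(self.sequencing_depth, self.mapping_depth)


class PavMatrix:
    """A 0/1 presence matrix: rows are genes/SVs/families, columns accessions.

    Thin wrapper over a ``pandas.DataFrame`` that enforces binary entries
    and unique row/column ids.
    """

    def __init__(self, df: pd.DataFrame):
        if df.index.has_duplicates or df.columns.has_duplicates:
            raise ValueError("row and column ids must be unique")
        values = df.to_numpy()
        if values.size and not np.isin(values, (0, 1)).all():
            raise ValueError("matrix entries must be 0 or 1")
        self.df = df.astype(np.int8)

    @property
    def row_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def accessions(self) -> list[str]:
        return list(self.df.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.df.shape

    def subset_accessions(self, accessions: Sequence[str]) -> "PavMatrix":
        missing = [a for a in accessions if a not in self.df.columns]
        if missing:
            raise KeyError(f"unknown accessions: {missing}")
        return PavMatrix(self.df[list(accessions)])

    def values(self) -> np.ndarray:
        return self.df.to_numpy()

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index_label="id")

    @classmethod
    def from_tsv(cls, path) -> "PavMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        return isinstance(other, PavMatrix) and self.df.equals(other.df)


def interval_union(
    intervals: Iterable[tuple[int, int]],
) -> list[tuple[int, int]]:
    """Merge half-open intervals into a minimal sorted disjoint cover.

    Touching intervals (``[0,5)`` and ``[5,10)``) merge, because half-open
    adjacency leaves no gap.
    """
    ivs = sorted(intervals)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if e < s:
            raise ValueError(f"negative-length interval ({s}, {e})")
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def total_length(intervals: Iterable[tuple[int, int]]) -> int:
    return sum(e - s for s, e in interval_union(intervals))


def covered_fraction(
    aligned_spans: Iterable[tuple[int, int]],
    target: Sequence[tuple[int, int]],
) -> float:
    """Breadth of coverage of ``target`` by aligned reference spans.

    ``aligned_spans`` are the reference intervals under aligned read bases
    (CIGAR M/=/X blocks; deletions and introns within an alignment do not
    count as covered).  Depth beyond 1 is ignored: this is breadth, not
    depth.
    """
    target_u = interval_union(target)
    tlen = sum(e - s for s, e in target_u)
    if tlen == 0:
        raise ValueError("empty target interval set")
    cover = interval_union(aligned_spans)
    covered = 0
    ti = 0
    for cs, ce in cover:
        while ti < len(target_u) and target_u[ti][1] <= cs:
            ti += 1
        j = ti
        while j < len(target_u) and target_u[j][0] < ce:
            ts, te = target_u[j]
            covered += max(0, min(ce, te) - max(cs, ts))
            j += 1
    return covered / tlen


def call_presence(
    cds_fraction: float,
    body_fraction: float,
    cds_threshold: float = DEFAULT_CDS_THRESHOLD,
    body_threshold: float = DEFAULT_BODY_THRESHOLD,
) -> int:
    """1 iff coding breadth > cds_threshold AND body breadth > body_threshold.

    Both inequalities are strict: a gene at exactly 0.95 coding coverage is
    absent.
    """
    for f in (cds_fraction, body_fraction):
        if not 0.0 <= f <= 1.0:
            raise ValueError("fractions must lie in [0, 1]")
    return int(cds_fraction > cds_threshold and body_fraction > body_threshold)


def mapping_depth(total_mapped_bases: float, genome_size: int) -> float:
    """Fold mapping depth: total mapped bases divided by the genome size."""
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    return total_mapped_bases / genome_size


def accession_qc(
    sequencing_depth: float,
    mapping_depth: float,
    min_seq_depth: float = DEFAULT_MIN_SEQ_DEPTH,
    min_map_depth: float = DEFAULT_MIN_MAP_DEPTH,
) -> bool:
    """Accession passes iff sequencing depth >= 20 and mapping depth >= 15.

    Both bounds inclusive.
    """
    if sequencing_depth < 0 or mapping_depth < 0:
        raise ValueError("depths must be non-negative")
    return sequencing_depth >= min_seq_depth and mapping_depth >= min_map_depth


def breadth_for_gene(
    gene: GeneModel, aligned_spans: Sequence[tuple[int, int]], accession: str
) -> BreadthResult:
    """Compute body and CDS breadth of one gene from aligned spans on its sequence."""
    body_f = covered_fraction(aligned_spans, [gene.body])
    cds_f = covered_fraction(aligned_spans, list(gene.cds)) if gene.cds else body_f
    return BreadthResult(gene.gene_id, accession, body_f, cds_f)


def build_pav_matrix(
    calls: Iterable[BreadthResult],
    gene_order: Sequence[str] | None = None,
    accession_order: Sequence[str] | None = None,
    cds_threshold: float = DEFAULT_CDS_THRESHOLD,
    body_threshold: float = DEFAULT_BODY_THRESHOLD,
) -> PavMatrix:
    """Threshold breadth results into a 0/1 gene x accession matrix.

    Each (gene, accession) pair may appear at most once; pairs never
    observed are filled with 0 (absence) and logged.  Row order follows
    ``gene_order`` when given (the annotation order), else first-seen order.
    """
    seen: dict[tuple[str, str], int] = {}
    genes_seen: list[str] = []
    accs_seen: list[str] = []
    for r in calls:
        key = (r.gene_id, r.accession)
        if key in seen:
            raise ValueError(f"duplicate call for gene {r.gene_id}, accession {r.accession}")
        seen[key] = call_presence(r.cds_fraction, r.body_fraction, cds_threshold, body_threshold)
        if r.gene_id not in genes_seen:
            genes_seen.append(r.gene_id)
        if r.accession not in accs_seen:
            accs_seen.append(r.accession)
    genes = list(gene_order) if gene_order is not None else genes_seen
    accs = list(accession_order) if accession_order is not None else accs_seen
    data = np.zeros((len(genes), len(accs)), dtype=np.int8)
    n_missing = 0
    for i, g in enumerate(genes):
        for j, a in enumerate(accs):
            v = seen.get((g, a))
            if v is None:
                n_missing += 1
            else:
                data[i, j] = v
    if n_missing:
        logger.warning("%d (gene, accession) pairs had no call; filled as absent", n_missing)
    return PavMatrix(pd.DataFrame(data, index=genes, columns=accs))


@dataclass
class FamilyMap:
    """Mapping from gene-family id to its member gene ids.

    Each gene belongs to at most one family; empty families are invalid.
    """

    families: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for fam, members in self.families.items():
            if not members:
                raise ValueError(f"family {fam} is empty")
            for g in members:
                if g in seen:
                    raise ValueError(f"gene {g} assigned to more than one family")
                seen.add(g)

    def __iter__(self):
        return iter(self.families.items())


def family_rollup(pav: PavMatrix, families: FamilyMap) -> PavMatrix:
    """Roll a gene PAV matrix up to gene families.

    A family is present in an accession iff at least one of its member
    genes is present (cell-wise OR over member rows).
    """
    rows = []
    fam_ids = []
    idx = pav.df.index
    for fam, members in families:
        unknown = [g for g in members if g not in idx]
        if unknown:
            raise KeyError(f"family {fam} references genes absent from the matrix: {unknown}")
        rows.append(pav.df.loc[list(members)].to_numpy().max(axis=0))
        fam_ids.append(fam)
    data = np.array(rows, dtype=np.int8).reshape(len(fam_ids), len(pav.accessions))
    return PavMatrix(pd.DataFrame(data, index=fam_ids, columns=pav.accessions))


def coverage_mask(
    aligned_spans: Iterable[tuple[int, int]], seq_length: int
) -> np.ndarray:
    """Boolean per-base covered mask for one sequence (vectorized breadth).

    Used by the cohort pipeline where per-gene interval arithmetic over
    millions of spans would be slow.
    """
    delta = np.zeros(seq_length + 1, dtype=np.int32)
    for s, e in aligned_spans:
        s = max(0, min(s, seq_length))
        e = max(0, min(e, seq_length))
        if e > s:
            delta[s] += 1
            delta[e] -= 1
    return np.cumsum(delta[:-1]) > 0


def coverage_mask_from_arrays(
    starts: np.ndarray, ends: np.ndarray, seq_length: int
) -> np.ndarray:
    """Vectorized variant of :func:`coverage_mask` for span arrays."""
    delta = np.zeros(seq_length + 1, dtype=np.int64)
    s = np.clip(starts, 0, seq_length)
    e = np.clip(ends, 0, seq_length)
    keep = e > s
    np.add.at(delta, s[keep], 1)
    np.add.at(delta, e[keep], -1)
    return np.cumsum(delta[:-1]) > 0


def breadth_from_masks(
    genes: Sequence[GeneModel],
    masks: Mapping[str, np.ndarray],
    accession: str,
) -> list[BreadthResult]:
    """Per-gene breadth from per-sequence covered masks."""
    out = []
    for g in genes:
        mask = masks.get(g.seq_name)
        if mask is None:
            out.append(BreadthResult(g.gene_id, accession, 0.0, 0.0))
            continue
        body = float(mask[g.start : g.end].mean())
        if g.cds:
            cov = sum(int(mask[s:e].sum()) for s, e in g.cds)
            cdsf = cov / g.cds_length
        else:
            cdsf = body
        out.append(BreadthResult(g.gene_id, accession, body, cdsf))
    return out
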