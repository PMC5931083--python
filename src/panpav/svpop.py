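"""Cohort structural-variant consolidation.

Per-sample SV calls (deletions, inversions, duplications and
interchromosomal translocation breakpoints, novoBreak-style) pass a
support filter and a size filter, are pooled across samples, merged into
cohort variants when their breakpoints lie within 1 kb and their overlap
exceeds half of the combined extent, filtered on cohort frequency, and
finally laid out as a presence/absence matrix.

Coordinates are 0-based half-open internally; the VCF reader converts
from 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .covpav import PavMatrix

SV_TYPES = ("DEL", "INV", "DUP", "TRA")

# support filter constants: >=3 kmer-supporting reads AND
# (>4 split reads OR >=3 discordant pairs at both breakpoints)
MIN_KMER_READS = 3
MIN_SPLIT_READS_EXCLUSIVE = 4
MIN_DISCORDANT_PAIRS = 3

# interval-SV size bounds, inclusive
MIN_SV_SIZE = 100
MAX_SV_SIZE = 1_000_000

# merge rule: endpoints within 1 kb and overlap > half the union extent
MAX_ENDPOINT_DIST = 1000
MIN_RECIPROCAL_OVERLAP = 0.5


@dataclass(frozen=True)
class SvRecord:
    """One per-sample SV call with its support evidence.

    DEL/INV/DUP are intervals on one chromosome; TRA is a pair of
    breakpoints on two different chromosomes (``end`` is unused, ``chrom2``
    and ``pos2`` give the second breakpoint).  ``disc_pairs`` holds the
    discordant read-pair count at each of the two breakpoints.
    """

    sample: str
    svtype: str
    chrom: str
    start: int
    end: int = 0
    chrom2: str | None = None
    pos2: int | None = None
    kmer_reads: int = 0
    split_reads: int = 0
    disc_pairs: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if self.svtype not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.svtype!r}")
        if self.svtype == "TRA":
            if self.chrom2 is None or self.pos2 is None:
                raise ValueError("TRA requires chrom2 and pos2")
            if self.chrom2 == self.chrom:
                raise ValueError("TRA breakpoints must be interchromosomal")
        else:
            if self.start >= self.end:
                raise ValueError(f"{self.svtype} requires start < end")
        if self.kmer_reads < 0 or self.split_reads < 0 or min(self.disc_pairs) < 0:
            raise ValueError("support counts must be non-negative")

    @property
    def size(self) -> int | None:
        if self.svtype == "TRA":
            return None
        return self.end - self.start

    def breakpoints(self) -> tuple[tuple[str, int], tuple[str, int]]:
        """Orientation-normalized breakpoint pair (TRA only meaningful)."""
        if self.svtype == "TRA":
            a = (self.chrom, self.start)
            b = (self.chrom2, self.pos2)
            return (a, b) if a <= b else (b, a)
        return ((self.chrom, self.start), (self.chrom, self.end))

    @property
    def support(self) -> int:
        """Evidence score used to pick a merged-cluster representative."""
        return self.split_reads + self.kmer_reads


@dataclass
class MergedSv:
    """A cohort variant: merged per-sample records plus their accessions."""

    merged_id: str
    svtype: str
    representative: SvRecord
    members: list[SvRecord] = field(default_factory=list)

    @property
    def accessions(self) -> set[str]:
        return {m.sample for m in self.members}

    @property
    def chrom(self) -> str:
        return self.representative.chrom

    @property
    def start(self) -> int:
        return self.representative.start

    @property
    def end(self) -> int:
        return self.representative.end


def support_filter(r: SvRecord) -> bool:
    """Keep calls inferred by >=3 kmer reads with either >4 split reads or
    >=3 discordant pairs at both breakpoints."""
    if r.kmer_reads < MIN_KMER_READS:
        return False
    return r.split_reads > MIN_SPLIT_READS_EXCLUSIVE or min(r.disc_pairs) >= MIN_DISCORDANT_PAIRS


def size_filter(
    r: SvRecord, min_size: int = MIN_SV_SIZE, max_size: int = MAX_SV_SIZE
) -> bool:
    """Keep interval SVs sized 100 bp to 1 Mb inclusive; TRA has no size."""
    if r.svtype == "TRA":
        return True
    return min_size <= r.size <= max_size


def mergeable(
    a: SvRecord,
    b: SvRecord,
    max_endpoint_dist: int = MAX_ENDPOINT_DIST,
    min_overlap: float = MIN_RECIPROCAL_OVERLAP,
) -> bool:
    """Do two calls describe the same variant?

    Interval SVs: same type and chromosome, both endpoints within
    ``max_endpoint_dist`` and overlap > ``min_overlap`` of the union
    extent.  Translocations: same (normalized) chromosome pair with both
    breakpoints within ``max_endpoint_dist``.
    """
    if a.svtype != b.svtype:
        return False
    if a.svtype == "TRA":
        (ca1, pa1), (ca2, pa2) = a.breakpoints()
        (cb1, pb1), (cb2, pb2) = b.breakpoints()
        return (
            ca1 == cb1
            and ca2 == cb2
            and abs(pa1 - pb1) <= max_endpoint_dist
            and abs(pa2 - pb2) <= max_endpoint_dist
        )
    if a.chrom != b.chrom:
        return False
    if abs(a.start - b.start) > max_endpoint_dist or abs(a.end - b.end) > max_endpoint_dist:
        return False
    overlap = min(a.end, b.end) - max(a.start, b.start)
    union = max(a.end, b.end) - min(a.start, b.start)
    return overlap > min_overlap * union


def _sort_key(r: SvRecord):
    return (r.svtype, r.chrom, r.start, r.end, r.chrom2 or "", r.pos2 or 0, r.sample)


def _rep_key(r: SvRecord):
    # maximal support wins; ties by smallest start then sample id
    return (-r.support, r.start, r.sample)


def merge_cohort(
    records: Iterable[SvRecord],
    max_endpoint_dist: int = MAX_ENDPOINT_DIST,
    min_overlap: float = MIN_RECIPROCAL_OVERLAP,
) -> list[MergedSv]:
    """Greedy first-fit clustering of filtered SV calls into cohort variants.

    Records are canonically sorted by (type, chrom, start) so the result is
    independent of input order.  Each record joins the first existing
    cluster whose *representative* it can merge with, else founds a new
    cluster; the representative is the member with maximal evidence
    (split + kmer reads), ties by smallest start then sample id.  Matching
    against representatives rather than any member prevents unbounded
    chaining drift.
    """
    clusters: list[MergedSv] = []
    for rec in sorted(records, key=_sort_key):
        placed = False
        for cl in clusters:
            if cl.svtype == rec.svtype and mergeable(
                rec, cl.representative, max_endpoint_dist, min_overlap
            ):
                cl.members.append(rec)
                if _rep_key(rec) < _rep_key(cl.representative):
                    cl.representative = rec
                placed = True
                break
        if not placed:
            clusters.append(
                MergedSv(
                    merged_id="",
                    svtype=rec.svtype,
                    representative=rec,
                    members=[rec],
                )
            )
    for i, cl in enumerate(clusters):
        cl.merged_id = f"sv{i:05d}_{cl.svtype}"
    return clusters


def frequency_filter(
    merged: Sequence[MergedSv],
    cohort_size: int,
    min_accessions: int = 6,
    max_fraction: float = 0.8,
) -> list[MergedSv]:
    """Drop cohort variants seen in <6 accessions or >80% of the cohort.

    ``cohort_size`` is the full cohort the frequency is judged against
    (which may be larger than the accession subset later extracted).
    """
    if cohort_size <= 0:
        raise ValueError("cohort_size must be positive")
    for m in merged:
        if len(m.accessions) > cohort_size:
            raise ValueError(f"{m.merged_id}: accession set exceeds cohort_size")
    return [
        m
        for m in merged
        if min_accessions <= len(m.accessions) <= max_fraction * cohort_size
    ]


def sv_matrix(
    merged: Sequence[MergedSv], accessions: Sequence[str]
) -> tuple[PavMatrix, pd.DataFrame]:
    """Presence/absence matrix of merged SVs over ``accessions``.

    Returns the 0/1 matrix plus an annotation table (type, representative
    coordinates) indexed by merged id.  Pass a subset of accessions (e.g.
    the high-depth ones) to extract their columns.
    """
    accs = list(accessions)
    if len(set(accs)) != len(accs):
        raise ValueError("duplicate accession ids")
    data = np.zeros((len(merged), len(accs)), dtype=np.int8)
    ann_rows = []
    ids = []
    col = {a: j for j, a in enumerate(accs)}
    for i, m in enumerate(merged):
        ids.append(m.merged_id)
        for a in m.accessions:
            j = col.get(a)
            if j is not None:
                data[i, j] = 1
        rep = m.representative
        ann_rows.append(
            {
                "svtype": m.svtype,
                "chrom": rep.chrom,
                "start": rep.start,
                "end": rep.end if m.svtype != "TRA" else -1,
                "chrom2": rep.chrom2 or ".",
                "pos2": rep.pos2 if rep.pos2 is not None else -1,
                "n_accessions": len(m.accessions),
            }
        )
    matrix = PavMatrix(pd.DataFrame(data, index=ids, columns=accs))
    annotations = pd.DataFrame(ann_rows, index=ids)
    return matrix, annotations


TSV_COLUMNS = [
    "sample",
    "svtype",
    "chrom",
    "start",
    "end",
    "chrom2",
    "pos2",
    "kmer_reads",
    "split_reads",
    "disc_bp1",
    "disc_bp2",
]


def read_sv_tsv(path) -> list[SvRecord]:
    """Read per-sample SV calls from the documented TSV dialect."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "chrom2": str})
    missing = set(TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"SV TSV missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        is_tra = row.svtype == "TRA"
        out.append(
            SvRecord(
                sample=str(row.sample),
                svtype=row.svtype,
                chrom=str(row.chrom),
                start=int(row.start),
                end=int(row.end) if not is_tra else 0,
                chrom2=str(row.chrom2) if is_tra else None,
                pos2=int(row.pos2) if is_tra else None,
                kmer_reads=int(row.kmer_reads),
                split_reads=int(row.split_reads),
                disc_pairs=(int(row.disc_bp1), int(row.disc_bp2)),
            )
        )
    return out


def write_sv_tsv(records: Iterable[SvRecord], path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "sample": r.sample,
                "svtype": r.svtype,
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end if r.svtype != "TRA" else -1,
                "chrom2": r.chrom2 or ".",
                "pos2": r.pos2 if r.pos2 is not None else -1,
                "kmer_reads": r.kmer_reads,
                "split_reads": r.split_reads,
                "disc_bp1": r.disc_pairs[0],
                "disc_bp2": r.disc_pairs[1],
            }
        )
    pd.DataFrame(rows, columns=TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_sv_vcf(
    path,
    sample: str | None = None,
    kmer_key: str = "KMERS",
    split_key: str = "SPLIT",
    disc_keys: tuple[str, str] = ("DISC1", "DISC2"),
) -> list[SvRecord]:
    """Read novoBreak-style SV calls from an (uncompressed) VCF.

    SVTYPE/END/CHR2/POS2 follow the usual symbolic-allele conventions
    (1-based, converted to 0-based half-open here); the INFO keys carrying
    the support counts are configurable because they vary across caller
    versions.
    """
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vf:
        vcf_sample = sample
        if vcf_sample is None:
            vcf_sample = list(vf.header.samples)[0] if list(vf.header.samples) else "sample"
        for rec in vf:
            info = rec.info
            svtype = info.get("SVTYPE")
            if svtype not in SV_TYPES:
                continue
            kmer = int(_scalar(info.get(kmer_key, 0)))
            split = int(_scalar(info.get(split_key, 0)))
            d1 = int(_scalar(info.get(disc_keys[0], 0)))
            d2 = int(_scalar(info.get(disc_keys[1], 0)))
            if svtype == "TRA":
                out.append(
                    SvRecord(
                        sample=vcf_sample,
                        svtype="TRA",
                        chrom=rec.chrom,
                        start=rec.pos - 1,
                        chrom2=str(info.get("CHR2")),
                        pos2=int(_scalar(info.get("POS2", info.get("END", rec.pos)))) - 1,
                        kmer_reads=kmer,
                        split_reads=split,
                        disc_pairs=(d1, d2),
                    )
                )
            else:
                end = int(_scalar(info.get("END", rec.stop)))
                out.append(
                    SvRecord(
                        sample=vcf_sample,
                        svtype=svtype,
                        chrom=rec.chrom,
                        start=rec.pos - 1,
                        end=end,
                        kmer_reads=kmer,
                        split_reads=split,
                        disc_pairs=(d1, d2),
                    )
                )
    return out


def _scalar(v):
    if isinstance(v, (tuple, list)):
        return v[0]
    return v
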