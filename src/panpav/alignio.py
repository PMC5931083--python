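"""Alignment records and SAM/PAF readers and writers.

The in-memory unit is :class:`Alignment`: a read (or contig) aligned to a
target sequence as a set of aligned reference blocks.  Coverage-breadth
code consumes only the blocks; SAM round-trips go through pysam, PAF is
plain tab-separated text.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import pysam


@dataclass(frozen=True)
class Alignment:
    """One read aligned to a target, as reference-space aligned blocks.

    ``blocks`` are the target intervals under aligned read bases (CIGAR
    M/=/X); deletions/introns inside the alignment are the gaps between
    blocks and do not count as covered.  Unmapped records keep
    ``mapped=False`` and empty blocks.
    """

    qname: str
    target: str | None
    strand: str = "+"
    blocks: tuple[tuple[int, int], ...] = ()
    mapped: bool = True
    query_length: int = 0
    is_secondary: bool = False
    is_supplementary: bool = False
    is_duplicate: bool = False
    seq: str | None = None

    @property
    def target_start(self) -> int:
        return self.blocks[0][0]

    @property
    def target_end(self) -> int:
        return self.blocks[-1][1]

    @property
    def aligned_bases(self) -> int:
        return sum(e - s for s, e in self.blocks)


def spans_by_target(
    alignments: Iterable[Alignment],
    count_secondary: bool = True,
    count_duplicates: bool = False,
) -> dict[str, list[tuple[int, int]]]:
    """Collect aligned blocks per target sequence for breadth computation.

    Secondary and supplementary alignments count toward breadth by
    default; unmapped and duplicate-flagged records never do.
    """
    spans: dict[str, list[tuple[int, int]]] = {}
    for a in alignments:
        if not a.mapped:
            continue
        if a.is_duplicate and not count_duplicates:
            continue
        if (a.is_secondary or a.is_supplementary) and not count_secondary:
            continue
        spans.setdefault(a.target, []).extend(a.blocks)
    return spans


def _cigar(a: Alignment) -> str:
    if not a.blocks:
        return "*"
    parts = []
    qpos_used = a.aligned_bases
    clip = max(0, a.query_length - qpos_used)
    lead, trail = (clip, 0) if a.strand == "-" else (0, clip)
    if lead:
        parts.append(f"{lead}S")
    prev_end = None
    for s, e in a.blocks:
        if prev_end is not None and s > prev_end:
            parts.append(f"{s - prev_end}D")
        parts.append(f"{e - s}M")
        prev_end = e
    if trail:
        parts.append(f"{trail}S")
    return "".join(parts)


def write_sam(
    alignments: Iterable[Alignment],
    target_lengths: Mapping[str, int],
    path,
) -> None:
    """Write alignments as plain-text SAM via pysam."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": length} for name, length in target_lengths.items()],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        tid = {name: i for i, name in enumerate(target_lengths)}
        for a in alignments:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = a.qname
            if a.seq is not None:
                rec.query_sequence = a.seq
                rec.query_qualities = pysam.qualitystring_to_array("I" * len(a.seq))
            if not a.mapped:
                rec.is_unmapped = True
                out.write(rec)
                continue
            rec.reference_id = tid[a.target]
            rec.reference_start = a.target_start
            rec.mapping_quality = 60
            rec.is_reverse = a.strand == "-"
            rec.is_secondary = a.is_secondary
            rec.is_supplementary = a.is_supplementary
            rec.is_duplicate = a.is_duplicate
            rec.cigarstring = _cigar(a)
            out.write(rec)


def read_sam(path) -> Iterator[Alignment]:
    """Read alignments (SAM/BAM) into block form via pysam."""
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                yield Alignment(
                    qname=rec.query_name, target=None, mapped=False,
                    query_length=rec.query_length or 0,
                )
                continue
            yield Alignment(
                qname=rec.query_name,
                target=rec.reference_name,
                strand="-" if rec.is_reverse else "+",
                blocks=tuple(rec.get_blocks()),
                mapped=True,
                query_length=rec.query_length or rec.infer_read_length() or 0,
                is_secondary=rec.is_secondary,
                is_supplementary=rec.is_supplementary,
                is_duplicate=rec.is_duplicate,
            )


def write_paf(
    alignments: Iterable[Alignment],
    query_lengths: Mapping[str, int],
    target_lengths: Mapping[str, int],
    path,
) -> None:
    """Write mapped alignments as PAF (one line per alignment)."""
    with open(path, "w") as fh:
        for a in alignments:
            if not a.mapped:
                continue
            qlen = query_lengths.get(a.qname, a.query_length)
            nmatch = a.aligned_bases
            blen = a.target_end - a.target_start
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        a.qname, qlen, 0, nmatch, a.strand,
                        a.target, target_lengths[a.target],
                        a.target_start, a.target_end, nmatch, blen, 60,
                    )
                )
                + "\n"
            )


def read_paf(path) -> Iterator[Alignment]:
    """Read PAF lines as single-block alignments (cg tags are not required;
    without one, the whole target span counts as aligned)."""
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            qname, qlen = f[0], int(f[1])
            strand, target = f[4], f[5]
            tstart, tend = int(f[7]), int(f[8])
            yield Alignment(
                qname=qname,
                target=target,
                strand=strand,
                blocks=((tstart, tend),),
                query_length=qlen,
            )


@dataclass
class PafRow:
    """Typed view of a PAF line for contig-vs-reference screening."""

    qname: str
    qlen: int
    qstart: int
    qend: int
    strand: str
    target: str
    tlen: int
    tstart: int
    tend: int
    matches: int
    block_length: int


def read_paf_rows(path) -> Iterator[PafRow]:
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            yield PafRow(
                qname=f[0], qlen=int(f[1]), qstart=int(f[2]), qend=int(f[3]),
                strand=f[4], target=f[5], tlen=int(f[6]),
                tstart=int(f[7]), tend=int(f[8]),
                matches=int(f[9]), block_length=int(f[10]),
            )
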