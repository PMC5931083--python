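"""Paired-end read simulation and by-construction ("oracle") alignment.

Fragments are drawn around a configurable insert mean (default 460 bp);
the two mates are the fragment's first and last ``read_length`` bases,
the second reverse-complemented.  Because every read records its true
origin, alignment against a target that shares coordinates with the
source genome (directly, or through an accession-to-reference
:class:`~panpav.simdata.pangenome.Liftover`) needs no aligner: origins
are projected exactly, reads from sequence absent in the target come out
unmapped, and sequencing errors appear as mismatches, never as clips.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from ..alignio import Alignment
from .config import SimConfig
from .pangenome import BASES, Liftover, reverse_complement


@dataclass(frozen=True)
class ReadPair:
    """A simulated read pair with the true origin of each mate.

    Origins are (sequence name, 0-based start, strand) in the coordinates
    of the genome the pair was simulated from.
    """

    name: str
    accession: str
    mate1: str
    mate2: str
    origin1: tuple[str, int, str]
    origin2: tuple[str, int, str]


def pair_count(depth: float, total_length: int, read_length: int) -> int:
    """Number of read pairs for a target fold-coverage."""
    return int(round(depth * total_length / (2 * read_length)))


def simulate_fragments(
    seq_lengths: Mapping[str, int],
    config: SimConfig,
    rng: np.random.Generator,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Draw fragment intervals per sequence.

    Pairs are apportioned to sequences proportionally to length (largest
    remainder, so the total is exact); fragment sizes are normal around
    ``insert_mean`` (sd ``insert_sd``), clamped to [2*read_length,
    sequence length].
    """
    if config.depth <= 0:
        raise ValueError("depth must be positive to simulate reads")
    rl = config.read_length
    shortest = min(seq_lengths.values())
    if rl > shortest:
        raise ValueError(f"read_length {rl} exceeds shortest sequence ({shortest} bp)")
    total = sum(seq_lengths.values())
    n_pairs = pair_count(config.depth, total, rl)
    names = list(seq_lengths)
    exact = np.array([seq_lengths[c] / total * n_pairs for c in names])
    counts = np.floor(exact).astype(int)
    rem = np.argsort(-(exact - counts))
    for i in range(n_pairs - counts.sum()):
        counts[rem[i % len(names)]] += 1
    out = {}
    for name, count in zip(names, counts):
        L = seq_lengths[name]
        frag = np.clip(
            np.rint(rng.normal(config.insert_mean, config.insert_sd, size=count)),
            2 * rl,
            L,
        ).astype(np.int64)
        start = rng.integers(0, L - frag + 1)
        out[name] = (start, start + frag)
    return out


_BASE_INDEX = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _BASE_INDEX[_b] = _i


def _apply_errors(read: np.ndarray, rng: np.random.Generator, rate: float) -> np.ndarray:
    if rate <= 0:
        return read
    hit = np.nonzero(rng.random(read.size) < rate)[0]
    if hit.size:
        read = read.copy()
        # substitute with a uniformly random *different* base
        shift = rng.integers(1, 4, size=hit.size).astype(np.uint8)
        read[hit] = BASES[(_BASE_INDEX[read[hit]] + shift) % 4]
    return read


def simulate_reads(
    genome: Mapping[str, str],
    config: SimConfig,
    rng: np.random.Generator | int | None = None,
    accession: str = "sample",
) -> Iterator[ReadPair]:
    """Yield error-injected paired-end reads covering ``genome`` at
    ``config.depth`` fold."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng([config.seed if rng is None else rng, 7])
    rl = config.read_length
    frags = simulate_fragments({c: len(s) for c, s in genome.items()}, config, rng)
    i = 0
    for chrom, (starts, ends) in frags.items():
        arr = np.frombuffer(genome[chrom].encode(), dtype=np.uint8)
        for fs, fe in zip(starts, ends):
            m1 = _apply_errors(arr[fs : fs + rl], rng, config.error_rate)
            m2 = _apply_errors(arr[fe - rl : fe], rng, config.error_rate)
            yield ReadPair(
                name=f"{accession}_read{i:07d}",
                accession=accession,
                mate1=m1.tobytes().decode(),
                mate2=reverse_complement(m2.tobytes().decode()),
                origin1=(chrom, int(fs), "+"),
                origin2=(chrom, int(fe - rl), "-"),
            )
            i += 1


def oracle_align(
    reads: Iterable[ReadPair],
    target_names: Sequence[str],
    liftover: Liftover | None = None,
) -> Iterator[Alignment]:
    """Emit the true alignment of each mate onto the target.

    With ``liftover=None`` origins are used verbatim (reads simulated from
    the target itself); otherwise origins are projected through the
    accession's segment map, clipping mates that cross a breakpoint to
    their first aligned block.  Mates whose origin has no image in the
    target are emitted as unmapped records.
    """
    targets = set(target_names)
    for pair in reads:
        for mate_i, (seq, origin) in enumerate(
            ((pair.mate1, pair.origin1), (pair.mate2, pair.origin2)), start=1
        ):
            qname = f"{pair.name}/{mate_i}"
            chrom, start, strand = origin
            rl = len(seq)
            if liftover is None:
                if chrom in targets:
                    yield Alignment(
                        qname=qname, target=chrom, strand=strand,
                        blocks=((start, start + rl),), query_length=rl, seq=seq,
                    )
                else:
                    yield Alignment(qname=qname, target=None, mapped=False,
                                    query_length=rl, seq=seq)
                continue
            names, rs, re_, seg_strand, ok = liftover.project_intervals(
                chrom, np.array([start]), np.array([start + rl])
            )
            if ok[0] and names[0] in targets:
                # projected strand = origin strand composed with segment strand
                flip = seg_strand[0] == -1
                out_strand = strand if not flip else ("-" if strand == "+" else "+")
                yield Alignment(
                    qname=qname, target=str(names[0]), strand=out_strand,
                    blocks=((int(rs[0]), int(re_[0])),), query_length=rl, seq=seq,
                )
            else:
                yield Alignment(qname=qname, target=None, mapped=False,
                                query_length=rl, seq=seq)


def mate_spans(
    frags: Mapping[str, tuple[np.ndarray, np.ndarray]], read_length: int
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-sequence (starts, ends) arrays of both mates' aligned intervals."""
    out = {}
    for chrom, (fs, fe) in frags.items():
        starts = np.concatenate([fs, fe - read_length])
        ends = starts + read_length
        out[chrom] = (starts, ends)
    return out
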