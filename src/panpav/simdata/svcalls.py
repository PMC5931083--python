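"""Per-sample SV call tables derived from simulation truth.

Emulates the output of a breakpoint caller run independently per
accession: every injected truth SV yields a call with small coordinate
jitter and support counts that pass the cohort support filter, optionally
mixed with under-supported noise calls and rare (below the cohort
frequency floor) variants, so the downstream filter/merge machinery has
something real to reject.
"""

from __future__ import annotations

import numpy as np

from ..svpop import SvRecord
from .pangenome import PanTruth

JITTER = 25  # bp; small against the 1 kb merge radius and min 300 bp SV size


def sv_call_records(
    truth: PanTruth,
    jitter: int = JITTER,
    include_noise: bool = True,
    n_rare_sites: int = 2,
    rng: np.random.Generator | None = None,
) -> list[SvRecord]:
    """Turn the truth SV table into per-sample caller-style records."""
    if rng is None:
        rng = np.random.default_rng([truth.config.seed, 6])
    records: list[SvRecord] = []
    for row in truth.sv_truth.itertuples(index=False):
        records.append(_one_call(row, rng, jitter))
    if include_noise:
        records.extend(_noise_calls(truth, rng))
        records.extend(_rare_calls(truth, rng, n_rare_sites))
    return records


def _support(rng: np.random.Generator) -> dict:
    # passing evidence: always >=3 kmer reads, then either the split-read
    # route (>4) or the discordant-pair route (>=3 at both breakpoints)
    if rng.random() < 0.5:
        return {
            "kmer_reads": int(rng.integers(3, 21)),
            "split_reads": int(rng.integers(5, 31)),
            "disc_pairs": (int(rng.integers(0, 3)), int(rng.integers(0, 3))),
        }
    return {
        "kmer_reads": int(rng.integers(3, 21)),
        "split_reads": int(rng.integers(0, 5)),
        "disc_pairs": (int(rng.integers(3, 11)), int(rng.integers(3, 11))),
    }


def _one_call(row, rng: np.random.Generator, jitter: int) -> SvRecord:
    j = lambda: int(rng.integers(-jitter, jitter + 1))  # noqa: E731
    if row.svtype == "TRA":
        return SvRecord(
            sample=row.accession, svtype="TRA", chrom=row.chrom,
            start=int(row.start) + j(), chrom2=row.chrom2, pos2=int(row.pos2) + j(),
            **_support(rng),
        )
    return SvRecord(
        sample=row.accession, svtype=row.svtype, chrom=row.chrom,
        start=int(row.start) + j(), end=int(row.end) + j(),
        **_support(rng),
    )


def _noise_calls(truth: PanTruth, rng: np.random.Generator) -> list[SvRecord]:
    """Under-supported calls at random positions: must fail support_filter."""
    out = []
    chroms = list(truth.reference)
    for acc in truth.accessions:
        for _ in range(2):
            chrom = chroms[int(rng.integers(len(chroms)))]
            start = int(rng.integers(0, len(truth.reference[chrom]) - 3000))
            size = int(rng.integers(300, 2000))
            bad = {
                "kmer_reads": int(rng.integers(0, 3)),  # fails the kmer floor
                "split_reads": int(rng.integers(0, 5)),
                "disc_pairs": (int(rng.integers(0, 3)), int(rng.integers(0, 3))),
            }
            out.append(SvRecord(sample=acc, svtype="DEL", chrom=chrom,
                                start=start, end=start + size, **bad))
    return out


def _rare_calls(
    truth: PanTruth, rng: np.random.Generator, n_sites: int
) -> list[SvRecord]:
    """Well-supported variants in fewer than 6 accessions: the cohort
    frequency filter must remove them."""
    out = []
    accs = truth.accessions
    if len(accs) < 3:
        return out
    chroms = list(truth.reference)
    for s in range(n_sites):
        chrom = chroms[s % len(chroms)]
        # park rare sites in the buffer between gene and SV-pool regions
        start = int(len(truth.reference[chrom]) * 0.66) + (s // len(chroms)) * 4000
        size = 500
        carriers = rng.choice(len(accs), size=min(3, len(accs)), replace=False)
        for ci in carriers:
            out.append(
                SvRecord(sample=accs[int(ci)], svtype="DEL", chrom=chrom,
                         start=start, end=start + size, **_support(rng))
            )
    return out
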