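"""Synthetic pan-genome construction and accession-genome realization.

``build_pangenome`` lays out a random reference carrying core and
dispensable genes, draws a group-structured presence/absence truth matrix
(per-gene presence frequencies differ between population groups), and
places a cohort-shared pool of structural-variant sites each accession
samples from.  ``realize_accession`` turns truth into an actual accession
genome: absent dispensable genes are excised and the accession's
deletions, inversions, duplications and translocations are applied, while
a piecewise segment map (``Liftover``) records how every accession base
projects back onto the reference — the basis of by-construction "oracle"
alignments.

Genes live in the first ~65% of each chromosome and SV sites in the
remainder, mutually separated; this keeps gene presence governed solely by
the truth matrix and keeps distinct SV sites unambiguous under the 1 kb
merge rule.

All coordinates are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ..covpav import GeneModel, PavMatrix
from .config import SimConfig

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = np.zeros(256, dtype=np.uint8)
for a, b in zip(b"ACGTN", b"TGCAN"):
    _COMPLEMENT[a] = b

GENE_REGION_FRACTION = 0.65  # genes in the head of each chromosome ...
SV_REGION_START = 0.70  # ... SV sites in the tail, with a buffer between
SV_SITE_SEPARATION = 2500  # > 2x the 1 kb merge radius
CHROM_MARGIN = 300
MIN_INTERGENIC_GAP = 200
MAX_INTERGENIC_GAP = 600


def random_sequence(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(BASES, size=length, p=p).tobytes().decode()


def reverse_complement(seq: str) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    return _COMPLEMENT[arr][::-1].tobytes().decode()


@dataclass
class PanTruth:
    """Ground truth of a simulated cohort."""

    config: SimConfig
    reference: dict[str, str]
    genes: list[GeneModel]
    presence: PavMatrix  # genes x accessions, 0/1
    groups: dict[str, str]  # accession -> group label
    sv_pool: pd.DataFrame  # cohort SV sites (sv_id, svtype, chrom, start, end, chrom2, pos2)
    sv_truth: pd.DataFrame  # per-accession injected SVs (accession, sv_id, ...)
    phenotype: pd.DataFrame | None = None  # accession, value
    causal_gene: str | None = None
    causal_effect: float = 0.0

    @property
    def accessions(self) -> list[str]:
        return self.presence.accessions

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


@dataclass
class Segment:
    """One piece of an accession chromosome, mapped to reference space.

    The accession interval [acc_start, acc_end) carries the reference
    bases ref_name[ref_start:ref_end], reverse-complemented when strand is
    ``-``.
    """

    acc_start: int
    acc_end: int
    ref_name: str
    ref_start: int
    ref_end: int
    strand: str = "+"


class Liftover:
    """Piecewise-linear projection from accession to reference coordinates."""

    def __init__(self, segments: Mapping[str, Sequence[Segment]]):
        self._by_chrom: dict[str, dict[str, np.ndarray]] = {}
        self.segments = {c: list(s) for c, s in segments.items()}
        for chrom, segs in self.segments.items():
            segs = sorted(segs, key=lambda s: s.acc_start)
            self._by_chrom[chrom] = {
                "acc_start": np.array([s.acc_start for s in segs], dtype=np.int64),
                "acc_end": np.array([s.acc_end for s in segs], dtype=np.int64),
                "ref_start": np.array([s.ref_start for s in segs], dtype=np.int64),
                "ref_end": np.array([s.ref_end for s in segs], dtype=np.int64),
                "strand": np.array([1 if s.strand == "+" else -1 for s in segs]),
                "ref_name": np.array([s.ref_name for s in segs]),
            }

    def project_intervals(
        self, chrom: str, starts: np.ndarray, ends: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Project accession intervals onto the reference.

        Each interval is clipped to the segment containing its start (an
        interval crossing a breakpoint contributes only its first aligned
        block, as a clipped read alignment would).  Returns
        ``(ref_names, ref_starts, ref_ends, strands, valid)`` arrays, with
        strands +1/-1 for segments carried forward/reverse-complemented.
        """
        t = self._by_chrom[chrom]
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        i = np.searchsorted(t["acc_start"], starts, side="right") - 1
        i = np.clip(i, 0, len(t["acc_start"]) - 1)
        valid = (starts >= t["acc_start"][i]) & (starts < t["acc_end"][i])
        ce = np.minimum(ends, t["acc_end"][i])
        offset = starts - t["acc_start"][i]
        bl = np.maximum(ce - starts, 0)
        plus = t["strand"][i] == 1
        rs = np.where(
            plus,
            t["ref_start"][i] + offset,
            t["ref_end"][i] - offset - bl,
        )
        re_ = rs + bl
        return t["ref_name"][i], rs, re_, t["strand"][i], valid & (bl > 0)


@dataclass
class RealizedGenome:
    """An accession genome with its applied SVs and liftover to reference."""

    accession: str
    sequences: dict[str, str]
    liftover: Liftover
    applied_svs: pd.DataFrame  # sv_id, svtype, ref/acc-frame coordinates

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())


def _place_genes(
    rng: np.random.Generator, config: SimConfig, chrom_names: Sequence[str]
) -> list[GeneModel]:
    n_total = config.n_core_genes + config.n_dispensable_genes
    if n_total == 0:
        return []
    labels = np.array(
        ["core"] * config.n_core_genes + ["disp"] * config.n_dispensable_genes
    )
    rng.shuffle(labels)
    # round-robin genes over chromosomes proportionally to length
    lengths = np.array(config.chrom_lengths, dtype=float)
    per_chrom = np.floor(n_total * lengths / lengths.sum()).astype(int)
    while per_chrom.sum() < n_total:
        per_chrom[int(np.argmax(lengths / (per_chrom + 1)))] += 1
    genes: list[GeneModel] = []
    gi = 0
    counters = {"core": 0, "disp": 0}
    for ci, chrom in enumerate(chrom_names):
        limit = int(config.chrom_lengths[ci] * GENE_REGION_FRACTION)
        cursor = CHROM_MARGIN
        for _ in range(per_chrom[ci]):
            body_len = int(rng.integers(600, 1201))
            gap = int(rng.integers(MIN_INTERGENIC_GAP, MAX_INTERGENIC_GAP + 1))
            if cursor + body_len > limit:
                raise ValueError(
                    f"cannot place {n_total} non-overlapping genes: chromosome "
                    f"{chrom} gene region ({limit} bp) exhausted at gene {gi}; "
                    "reduce gene counts or enlarge chrom_lengths"
                )
            start = cursor
            end = start + body_len
            cds = _random_cds(rng, start, end)
            label = labels[gi]
            counters[label] += 1
            genes.append(
                GeneModel(
                    gene_id=f"{label}_{counters[label]:04d}",
                    seq_name=chrom,
                    start=start,
                    end=end,
                    strand="+" if rng.random() < 0.5 else "-",
                    cds=cds,
                    origin="reference",
                )
            )
            cursor = end + gap
            gi += 1
    return genes


def _random_cds(
    rng: np.random.Generator, start: int, end: int
) -> tuple[tuple[int, int], ...]:
    length = end - start
    n_exons = int(rng.integers(1, 4))
    exon_lens = rng.integers(60, 151, size=n_exons)
    intron_lens = rng.integers(40, 121, size=max(0, n_exons - 1))
    needed = int(exon_lens.sum() + intron_lens.sum()) + 40
    if needed > length:
        return ((start + 20, end - 20),)
    cds = []
    pos = start + 20
    for i in range(n_exons):
        cds.append((pos, pos + int(exon_lens[i])))
        pos += int(exon_lens[i])
        if i < n_exons - 1:
            pos += int(intron_lens[i])
    return tuple(cds)


def _place_sv_pool(
    rng: np.random.Generator, config: SimConfig, chrom_names: Sequence[str]
) -> pd.DataFrame:
    """Lay out cohort-shared SV sites in the gene-free tails, separated by
    > 2x the merge radius so distinct sites can never merge."""
    interval_types = [t for t in ("DEL", "INV", "DUP") if config.sv_counts.get(t, 0)]
    rows = []
    # candidate anchor positions per chromosome
    anchors: dict[str, list[int]] = {}
    for ci, chrom in enumerate(chrom_names):
        lo = int(config.chrom_lengths[ci] * SV_REGION_START)
        hi = config.chrom_lengths[ci] - CHROM_MARGIN - config.sv_size_range[1]
        anchors[chrom] = list(range(lo, hi, SV_SITE_SEPARATION + config.sv_size_range[1]))
    flat = [(c, a) for c in chrom_names for a in anchors[c]]
    rng.shuffle(flat)
    cursor = 0
    sv_i = 0
    for svtype in interval_types:
        pool_size = 2 * config.sv_counts[svtype]
        for _ in range(pool_size):
            if cursor >= len(flat):
                raise ValueError(
                    "cannot place the requested SV pool without collisions: "
                    "enlarge chrom_lengths or reduce sv_counts/sv_size_range"
                )
            chrom, anchor = flat[cursor]
            cursor += 1
            size = int(rng.integers(config.sv_size_range[0], config.sv_size_range[1] + 1))
            rows.append(
                {
                    "sv_id": f"truth_{svtype}_{sv_i:03d}",
                    "svtype": svtype,
                    "chrom": chrom,
                    "start": anchor,
                    "end": anchor + size,
                    "chrom2": ".",
                    "pos2": -1,
                }
            )
            sv_i += 1
    n_tra = config.sv_counts.get("TRA", 0)
    if n_tra:
        if len(chrom_names) < 2:
            raise ValueError("TRA simulation needs at least two chromosomes")
        for _ in range(2 * n_tra):
            if cursor + 2 > len(flat):
                raise ValueError(
                    "cannot place the requested SV pool without collisions: "
                    "enlarge chrom_lengths or reduce sv_counts"
                )
            (c1, a1), (c2, a2) = flat[cursor], flat[cursor + 1]
            cursor += 2
            if c1 == c2:
                continue
            rows.append(
                {
                    "sv_id": f"truth_TRA_{sv_i:03d}",
                    "svtype": "TRA",
                    "chrom": c1,
                    "start": a1,
                    "end": -1,
                    "chrom2": c2,
                    "pos2": a2,
                }
            )
            sv_i += 1
    return pd.DataFrame(
        rows, columns=["sv_id", "svtype", "chrom", "start", "end", "chrom2", "pos2"]
    )


def build_pangenome(config: SimConfig) -> PanTruth:
    """Generate the cohort ground truth: reference, genes, presence matrix,
    SV assignments, phenotypes.  Deterministic given ``config.seed``."""
    chrom_names = [f"chr{i + 1}" for i in range(len(config.chrom_lengths))]
    rng_seq = np.random.default_rng([config.seed, 0])
    reference = {
        name: random_sequence(rng_seq, length, config.gc)
        for name, length in zip(chrom_names, config.chrom_lengths)
    }
    rng_genes = np.random.default_rng([config.seed, 1])
    genes = _place_genes(rng_genes, config, chrom_names)

    accessions = [f"acc{i:03d}" for i in range(config.n_accessions)]
    group_of = {
        a: f"G{i * config.n_groups // max(1, config.n_accessions)}"
        for i, a in enumerate(accessions)
    }
    rng_pav = np.random.default_rng([config.seed, 2])
    gene_ids = [g.gene_id for g in genes]
    presence = np.ones((len(genes), len(accessions)), dtype=np.int8)
    disp_idx = [i for i, g in enumerate(genes) if g.gene_id.startswith("disp_")]
    group_labels = sorted({group_of[a] for a in accessions})
    freq_of = {
        g: config.dispensable_freq_ranges[gi] for gi, g in enumerate(group_labels)
    }
    for i in disp_idx:
        for gi, glabel in enumerate(group_labels):
            lo, hi = freq_of[glabel]
            f = rng_pav.uniform(lo, hi)
            members = [j for j, a in enumerate(accessions) if group_of[a] == glabel]
            presence[i, members] = (rng_pav.random(len(members)) < f).astype(np.int8)
    pav = PavMatrix(pd.DataFrame(presence, index=gene_ids, columns=accessions))

    rng_sv = np.random.default_rng([config.seed, 3])
    sv_pool = _place_sv_pool(rng_sv, config, chrom_names)
    # SV carriers are group-structured like dispensable genes: each pool site
    # is common in one group (~0.9) and rare in the others (~0.1), so the
    # per-group mean frequency stays ~0.5 and the expected per-accession SV
    # count per type equals sv_counts (pool size is 2x the count)
    truth_rows = []
    site_freqs: list[dict[str, float]] = []
    for si in range(len(sv_pool)):
        hi_group = group_labels[si % len(group_labels)]
        site_freqs.append(
            {
                g: (rng_sv.uniform(0.85, 0.95) if g == hi_group
                    else rng_sv.uniform(0.05, 0.15))
                for g in group_labels
            }
        )
    for acc in accessions:
        seen_tra_pairs: set[tuple[str, str]] = set()
        for si, row in enumerate(sv_pool.itertuples(index=False)):
            if rng_sv.random() >= site_freqs[si][group_of[acc]]:
                continue
            if row.svtype == "TRA":
                # at most one translocation per chromosome pair per accession
                pair = tuple(sorted((row.chrom, row.chrom2)))
                if pair in seen_tra_pairs:
                    continue
                seen_tra_pairs.add(pair)
            truth_rows.append({"accession": acc, **row._asdict()})
    sv_truth = pd.DataFrame(
        truth_rows,
        columns=["accession", "sv_id", "svtype", "chrom", "start", "end", "chrom2", "pos2"],
    )

    truth = PanTruth(
        config=config,
        reference=reference,
        genes=genes,
        presence=pav,
        groups=group_of,
        sv_pool=sv_pool,
        sv_truth=sv_truth,
    )
    from .phenotype import simulate_phenotype  # local import to avoid a cycle

    if config.causal_gene is not None and disp_idx:
        truth.phenotype = simulate_phenotype(truth, config)
    return truth


def realize_accession(truth: PanTruth, accession: str) -> RealizedGenome:
    """Construct one accession's genome from truth.

    Absent dispensable genes are excised; the accession's deletions,
    inversions and duplications are applied in reference order, then
    translocations exchange chromosome tails at their breakpoints.  The
    segment map built along the way gives exact accession-to-reference
    liftover and the applied-SV table in both coordinate frames.
    """
    if accession not in truth.accessions:
        raise KeyError(f"unknown accession {accession!r}")
    col = truth.presence.df[accession]
    ops_by_chrom: dict[str, list[dict]] = {c: [] for c in truth.reference}
    for g in truth.genes:
        if col[g.gene_id] == 0:
            ops_by_chrom[g.seq_name].append(
                {"sv_id": f"absent:{g.gene_id}", "svtype": "EXCISION",
                 "start": g.start, "end": g.end}
            )
    mine = truth.sv_truth[truth.sv_truth.accession == accession]
    tras = []
    for row in mine.itertuples(index=False):
        if row.svtype == "TRA":
            tras.append(row)
        else:
            ops_by_chrom[row.chrom].append(
                {"sv_id": row.sv_id, "svtype": row.svtype,
                 "start": int(row.start), "end": int(row.end)}
            )

    applied_rows = []
    segments: dict[str, list[Segment]] = {}
    for chrom, ref_seq in truth.reference.items():
        ops = sorted(ops_by_chrom[chrom], key=lambda o: o["start"])
        for a, b in zip(ops, ops[1:]):
            if b["start"] < a["end"]:
                raise ValueError(
                    f"SV/excision placement collision on {chrom}: "
                    f"{a['sv_id']} overlaps {b['sv_id']}"
                )
        segs: list[Segment] = []
        cursor_ref = 0
        cursor_acc = 0

        def emit(rs: int, re_: int, strand: str = "+") -> None:
            nonlocal cursor_acc
            if re_ > rs:
                segs.append(Segment(cursor_acc, cursor_acc + (re_ - rs), chrom, rs, re_, strand))
                cursor_acc += re_ - rs

        for op in ops:
            emit(cursor_ref, op["start"])
            if op["svtype"] in ("DEL", "EXCISION"):
                pass  # interval skipped
            elif op["svtype"] == "INV":
                emit(op["start"], op["end"], "-")
            elif op["svtype"] == "DUP":
                emit(op["start"], op["end"])
                emit(op["start"], op["end"])
            cursor_ref = op["end"]
            if op["svtype"] != "EXCISION":
                applied_rows.append(
                    {"sv_id": op["sv_id"], "svtype": op["svtype"], "chrom": chrom,
                     "ref_start": op["start"], "ref_end": op["end"]}
                )
        emit(cursor_ref, len(ref_seq))
        segments[chrom] = segs

    for row in tras:
        _apply_tra(segments, row, applied_rows)

    # accession-frame coordinates from the final segment map (a translocation
    # tail swap renumbers downstream segments, so they cannot be recorded
    # during interval-op processing)
    for rec in applied_rows:
        if rec["svtype"] == "TRA":
            continue
        rec.update(_locate_in_segments(segments, rec["chrom"],
                                       rec["ref_start"], rec["ref_end"],
                                       rec["svtype"]))

    sequences = {}
    for chrom, segs in segments.items():
        parts = []
        for s in segs:
            piece = truth.reference[s.ref_name][s.ref_start : s.ref_end]
            parts.append(reverse_complement(piece) if s.strand == "-" else piece)
        sequences[chrom] = "".join(parts)

    applied = pd.DataFrame(
        applied_rows,
        columns=["sv_id", "svtype", "chrom", "ref_start", "ref_end",
                 "acc_chrom", "acc_start", "acc_end"],
    )
    return RealizedGenome(
        accession=accession,
        sequences=sequences,
        liftover=Liftover(segments),
        applied_svs=applied,
    )


def _locate_in_segments(
    segments: dict[str, list[Segment]], chrom: str, rs: int, re_: int, svtype: str
) -> dict:
    """Accession-frame coordinates of an applied interval op, found by
    matching its reference interval against the final segment map."""
    if svtype in ("DEL", "EXCISION"):
        # junction point: end of the segment that abuts the removed interval
        for acc_chrom, segs in segments.items():
            for s in segs:
                if s.ref_name == chrom and s.strand == "+" and s.ref_end == rs:
                    return {"acc_chrom": acc_chrom, "acc_start": s.acc_end,
                            "acc_end": s.acc_end}
                if s.ref_name == chrom and s.strand == "+" and s.ref_start == re_:
                    return {"acc_chrom": acc_chrom, "acc_start": s.acc_start,
                            "acc_end": s.acc_start}
        return {"acc_chrom": chrom, "acc_start": 0, "acc_end": 0}
    matches = [
        (acc_chrom, s)
        for acc_chrom, segs in segments.items()
        for s in segs
        if s.ref_name == chrom and s.ref_start == rs and s.ref_end == re_
        and (s.strand == "-") == (svtype == "INV")
    ]
    if not matches:
        raise AssertionError(f"applied {svtype} {chrom}:{rs}-{re_} lost from segment map")
    acc_chrom = matches[0][0]
    return {
        "acc_chrom": acc_chrom,
        "acc_start": min(s.acc_start for _c, s in matches),
        "acc_end": max(s.acc_end for _c, s in matches),
    }


def _apply_tra(segments: dict[str, list[Segment]], row, applied_rows: list) -> None:
    """Reciprocal exchange of chromosome tails at the two breakpoints."""

    def split_at(chrom: str, ref_pos: int) -> int:
        segs = segments[chrom]
        for i, s in enumerate(segs):
            if s.strand == "+" and s.ref_name == chrom and s.ref_start <= ref_pos < s.ref_end:
                if ref_pos > s.ref_start:
                    left_len = ref_pos - s.ref_start
                    left = Segment(s.acc_start, s.acc_start + left_len, chrom, s.ref_start, ref_pos)
                    right = Segment(s.acc_start + left_len, s.acc_end, chrom, ref_pos, s.ref_end)
                    segs[i : i + 1] = [left, right]
                    return i + 1
                return i
        raise ValueError(
            f"translocation breakpoint {chrom}:{ref_pos} falls in rearranged "
            "sequence; placement collision"
        )

    c1, p1 = row.chrom, int(row.start)
    c2, p2 = row.chrom2, int(row.pos2)
    i1 = split_at(c1, p1)
    i2 = split_at(c2, p2)
    head1, tail1 = segments[c1][:i1], segments[c1][i1:]
    head2, tail2 = segments[c2][:i2], segments[c2][i2:]
    segments[c1] = _renumber(head1 + tail2)
    segments[c2] = _renumber(head2 + tail1)
    acc1 = segments[c1][i1 - 1].acc_end if i1 > 0 else 0
    acc2 = segments[c2][i2 - 1].acc_end if i2 > 0 else 0
    applied_rows.append(
        {"sv_id": row.sv_id, "svtype": "TRA", "chrom": c1,
         "ref_start": p1, "ref_end": -1,
         "acc_chrom": c1, "acc_start": acc1, "acc_end": acc2}
    )


def _renumber(segs: list[Segment]) -> list[Segment]:
    out = []
    cursor = 0
    for s in segs:
        length = s.acc_end - s.acc_start
        out.append(Segment(cursor, cursor + length, s.ref_name, s.ref_start, s.ref_end, s.strand))
        cursor += length
    return out
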