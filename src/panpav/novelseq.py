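"""Novel-sequence pipeline logic.

The novel (non-reference) portion of a pan-genome is built from per-sample
de novo assemblies: an assembler k-mer is planned from sequencing depth by
a local hill-climb on contig N50, gap-closed scaffolds are split back into
contigs at long N runs, contigs absent from the reference are selected,
redundancy is removed by greedy identity clustering (cd-hit-est
semantics), contaminant contigs are dropped by a best-hit taxonomy rule,
and the survivors are concatenated — 100 Ns between contigs — into a
single browsable scaffold with an invertible offset map back to the source
contigs.  Predicted genes on the novel sequence are deduplicated against
reference genes at 95% global protein identity.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import edlib

# k-mer planner: initial K from sequencing depth, K = 2*int(0.38*depth + 10) + 1
KMER_SLOPE = 0.38
KMER_INTERCEPT = 10.0
DEFAULT_K_MIN = 15
DEFAULT_K_MAX = 127

DEFAULT_SPACER = 100  # Ns between concatenated novel contigs
DEFAULT_MAX_N_RUN = 10  # split scaffolds at runs of more than this many Ns
DEFAULT_MIN_NOVEL_LEN = 500  # candidate novel contigs must exceed this
DEFAULT_MIN_ALN_BLOCK = 65  # "aligned" means a block at least this long ...
DEFAULT_MIN_ALN_IDENTITY = 0.90  # ... at at least this identity
DEFAULT_CLUSTER_IDENTITY = 0.90  # nucleotide redundancy threshold
DEFAULT_PROTEIN_IDENTITY = 0.95  # gene-level deduplication threshold
REQUIRED_CLADE = "Viridiplantae"


def initial_kmer(
    depth: float, k_min: int = DEFAULT_K_MIN, k_max: int = DEFAULT_K_MAX
) -> int:
    """Initial assembler k-mer from sequencing depth.

    ``K = 2 * int(0.38 * depth + 10) + 1`` — a linear depth model wrapped
    to the next odd integer — clamped into ``[k_min, k_max]``.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    k = 2 * int(KMER_SLOPE * depth + KMER_INTERCEPT) + 1
    k = max(k_min, min(k_max, k))
    if k % 2 == 0:
        k -= 1
    return k


def n50(lengths: Sequence[int]) -> int:
    """N50: largest length L with at least half the total bases in
    sequences of length >= L."""
    if len(lengths) == 0:
        raise ValueError("n50 of an empty length set is undefined")
    if min(lengths) <= 0:
        raise ValueError("lengths must be positive")
    srt = sorted(lengths, reverse=True)
    half = sum(srt) / 2
    acc = 0
    for length in srt:
        acc += length
        if acc >= half:
            return length
    raise AssertionError("unreachable")


@dataclass
class KmerPlan:
    """Trace of the N50 hill-climb over odd k-mer sizes."""

    depth: float
    evaluations: dict[int, float]
    chosen_k: int
    trace: list[tuple[int, int, int]] = field(default_factory=list)

    @property
    def n_evaluations(self) -> int:
        return len(self.evaluations)


def plan_kmer(
    depth: float,
    evaluator: Callable[[int], float],
    k_min: int = DEFAULT_K_MIN,
    k_max: int = DEFAULT_K_MAX,
) -> KmerPlan:
    """Choose an assembler k-mer by hill-climbing contig N50.

    Starting from the depth-derived initial K, the triple
    ``{K-2, K, K+2}`` is scored by ``evaluator`` (each K at most once,
    results cached); while the middle K's N50 is not the maximum of the
    current triple the window slides by 2 toward the argmax.  Ties favour
    stopping (the middle wins ties), so constant profiles terminate after
    three evaluations; hitting a bound stops the climb and the best
    evaluated K is chosen.
    """
    k_init = initial_kmer(depth, k_min, k_max)
    cache: dict[int, float] = {}

    def ev(k: int) -> float:
        if k not in cache:
            try:
                cache[k] = float(evaluator(k))
            except Exception as exc:  # noqa: BLE001 - re-raise with trace
                raise RuntimeError(
                    f"k-mer evaluator failed at K={k}; evaluated so far: {sorted(cache)}"
                ) from exc
        return cache[k]

    mid = k_init
    trace: list[tuple[int, int, int]] = []
    chosen: int | None = None
    while True:
        lo, hi = mid - 2, mid + 2
        if lo < k_min or hi > k_max:
            # window fell off a bound: score what fits and take the best
            for k in (lo, mid, hi):
                if k_min <= k <= k_max:
                    ev(k)
            break
        triple = (lo, mid, hi)
        vals = [ev(k) for k in triple]
        trace.append(triple)
        if vals[1] >= max(vals):  # middle wins ties
            chosen = mid
            break
        mid = triple[int(max(range(3), key=lambda i: vals[i]))]
    if chosen is None:
        # bound hit: best evaluated K, ties toward the current window middle
        chosen = max(cache, key=lambda k: (cache[k], -abs(k - mid), -k))
    return KmerPlan(depth=depth, evaluations=dict(cache), chosen_k=chosen, trace=trace)


_N_RUN = re.compile("N+")


def split_scaffold(seq: str, max_n_run: int = DEFAULT_MAX_N_RUN) -> list[str]:
    """Break a scaffold into contigs at runs of more than ``max_n_run`` Ns.

    Runs of ``max_n_run`` or fewer Ns stay inside their contig; empty
    fragments (e.g. from a scaffold that is all Ns) are dropped.
    """
    pieces: list[str] = []
    last = 0
    for m in _N_RUN.finditer(seq):
        if m.end() - m.start() > max_n_run:
            if m.start() > last:
                pieces.append(seq[last : m.start()])
            last = m.end()
    if last < len(seq):
        pieces.append(seq[last:])
    return pieces


@dataclass(frozen=True)
class ContigAlignment:
    """One alignment block of an assembled contig against a reference."""

    contig_id: str
    contig_length: int
    target: str
    contig_start: int
    contig_end: int
    target_start: int
    target_end: int
    matches: int
    block_length: int

    @property
    def identity(self) -> float:
        if self.block_length == 0:
            return 0.0
        return self.matches / self.block_length


def select_novel_candidates(
    contigs: Mapping[str, str],
    alignments: Iterable[ContigAlignment],
    min_len: int = DEFAULT_MIN_NOVEL_LEN,
    min_block: int = DEFAULT_MIN_ALN_BLOCK,
    min_identity: float = DEFAULT_MIN_ALN_IDENTITY,
) -> dict[str, str]:
    """Select contigs absent from the reference.

    A contig is a novel candidate iff it is strictly longer than
    ``min_len`` and has *no* reference alignment block of at least
    ``min_block`` bases at identity >= ``min_identity`` (the operational
    meaning of "unaligned").
    """
    aligned: set[str] = set()
    for a in alignments:
        if a.contig_id not in contigs:
            raise KeyError(f"alignment references unknown contig {a.contig_id!r}")
        if a.block_length >= min_block and a.identity >= min_identity:
            aligned.add(a.contig_id)
    return {
        cid: seq
        for cid, seq in contigs.items()
        if len(seq) > min_len and cid not in aligned
    }


def pair_identity(a: str, b: str) -> float:
    """Global-alignment identity with the shorter-sequence denominator.

    Matching bases from a Needleman-Wunsch alignment divided by the length
    of the shorter sequence (cd-hit-est semantics), so a perfect prefix of
    a longer sequence scores 1.0.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    res = edlib.align(a, b, mode="NW", task="path")
    matches = 0
    for n, op in re.findall(r"(\d+)([=XIDM])", res["cigar"]):
        if op == "=":
            matches += int(n)
    return min(1.0, matches / min(len(a), len(b)))


@dataclass
class ClusterResult:
    """Greedy clustering output: representative ids and the membership map."""

    representatives: list[str]
    membership: dict[str, str]  # sequence id -> representative id
    rounds: int = 1


def _greedy_pass(
    seqs: Mapping[str, str], threshold: float
) -> tuple[list[str], dict[str, str]]:
    order = sorted(seqs, key=lambda i: (-len(seqs[i]), i))
    reps: list[str] = []
    member: dict[str, str] = {}
    for sid in order:
        best_rep = None
        best_key = None
        for rid in reps:
            ident = pair_identity(seqs[sid], seqs[rid])
            if ident >= threshold:
                # highest identity; ties to the longest representative, then id
                key = (-ident, -len(seqs[rid]), rid)
                if best_key is None or key < best_key:
                    best_rep, best_key = rid, key
        if best_rep is None:
            reps.append(sid)
            member[sid] = sid
        else:
            member[sid] = best_rep
    return reps, member


def greedy_cluster(
    seqs: Mapping[str, str],
    threshold: float = DEFAULT_CLUSTER_IDENTITY,
    max_rounds: int = 3,
) -> ClusterResult:
    """Greedy length-sorted identity clustering, repeated to a fixed point.

    Sequences are visited longest-first; each joins the best-matching
    existing representative at identity >= ``threshold`` or founds a new
    cluster.  Because greedy order can leave residual redundancy among
    representatives, the representative set is re-clustered until stable,
    capped at ``max_rounds`` rounds.
    """
    ids = list(seqs)
    if len(set(ids)) != len(ids):  # Mapping guarantees this; guard for pair lists
        raise ValueError("duplicate sequence ids")
    for sid in ids:
        if not seqs[sid]:
            raise ValueError(f"sequence {sid!r} is empty")
    reps, member = _greedy_pass(seqs, threshold)
    rounds = 1
    while rounds < max_rounds:
        sub = {r: seqs[r] for r in reps}
        new_reps, rep_member = _greedy_pass(sub, threshold)
        rounds += 1
        if set(new_reps) == set(reps):
            break
        member = {sid: rep_member[r] for sid, r in member.items()}
        reps = new_reps
    return ClusterResult(representatives=reps, membership=member, rounds=rounds)


@dataclass(frozen=True)
class TaxHit:
    """A database hit for a contig, with the subject's taxonomic lineage."""

    query: str
    subject: str
    evalue: float
    pident: float
    lineage: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("e-value must be non-negative")
        if not 0 <= self.pident <= 100:
            raise ValueError("percent identity must lie in [0, 100]")
        if not self.lineage:
            raise ValueError("empty lineage")


def contamination_filter(
    contigs: Mapping[str, str],
    hits: Iterable[TaxHit],
    required_clade: str = REQUIRED_CLADE,
) -> dict[str, str]:
    """Drop contigs whose best database hit is outside ``required_clade``.

    The best hit is chosen by minimal e-value, ties broken by maximal
    percent identity (then subject id for determinism).  Contigs with no
    hits at all are kept: absence of evidence is not contamination.
    """
    best: dict[str, TaxHit] = {}
    for h in hits:
        if h.query not in contigs:
            raise KeyError(f"hit references unknown contig {h.query!r}")
        cur = best.get(h.query)
        if cur is None or (h.evalue, -h.pident, h.subject) < (
            cur.evalue,
            -cur.pident,
            cur.subject,
        ):
            best[h.query] = h
    kept = {}
    for cid, seq in contigs.items():
        h = best.get(cid)
        if h is None or required_clade in h.lineage:
            kept[cid] = seq
    return kept


@dataclass
class PanBuild:
    """The pan-genome layout: reference sequences plus one novel scaffold.

    ``offsets`` maps each novel contig id to its 0-based start on the
    scaffold; contigs are separated by exactly ``spacer`` N bases, with no
    leading or trailing spacer.
    """

    reference_names: tuple[str, ...]
    novel_name: str
    novel_sequence: str
    offsets: list[tuple[str, int, int]]  # (contig id, start offset, length)
    spacer: int = DEFAULT_SPACER


def build_pan(
    reference: Mapping[str, str],
    novel_contigs: Mapping[str, str],
    spacer: int = DEFAULT_SPACER,
    novel_name: str = "novel_scaffold",
) -> PanBuild:
    """Concatenate novel contigs with N spacers behind the reference.

    Reference sequences pass through untouched; contig ids must not
    collide with reference names.
    """
    collisions = set(novel_contigs) & set(reference)
    if collisions:
        raise ValueError(f"novel contig ids collide with reference names: {sorted(collisions)}")
    parts: list[str] = []
    offsets: list[tuple[str, int, int]] = []
    pos = 0
    for i, (cid, seq) in enumerate(novel_contigs.items()):
        if i > 0:
            parts.append("N" * spacer)
            pos += spacer
        parts.append(seq)
        offsets.append((cid, pos, len(seq)))
        pos += len(seq)
    return PanBuild(
        reference_names=tuple(reference),
        novel_name=novel_name,
        novel_sequence="".join(parts),
        offsets=offsets,
        spacer=spacer,
    )


SPACER = "spacer"


def pan_to_contig(build: PanBuild, pan_pos: int) -> tuple[str, int] | str:
    """Map a position on the novel scaffold back to (contig id, position).

    Positions inside an N spacer return the marker string ``"spacer"``.
    """
    if pan_pos < 0 or pan_pos >= len(build.novel_sequence):
        raise IndexError(f"position {pan_pos} outside novel scaffold")
    for cid, off, length in build.offsets:
        if off <= pan_pos < off + length:
            return (cid, pan_pos - off)
        if pan_pos < off:
            break
    return SPACER


def pan_gene_counts(origins: Mapping[str, str]) -> dict[str, int]:
    """Bookkeeping for a pan gene set: reference + novel = total.

    ``origins`` maps gene id to ``reference``/``novel`` (e.g. for the
    genes kept by :func:`dedup_genes`).
    """
    n_ref = sum(1 for o in origins.values() if o == "reference")
    n_novel = sum(1 for o in origins.values() if o == "novel")
    if n_ref + n_novel != len(origins):
        raise ValueError("origins must be 'reference' or 'novel'")
    return {"reference": n_ref, "novel": n_novel, "total": n_ref + n_novel}


def dedup_genes(
    proteins: Mapping[str, str],
    origins: Mapping[str, str],
    threshold: float = DEFAULT_PROTEIN_IDENTITY,
) -> list[str]:
    """Deduplicate pan-genome genes at global protein identity.

    Genes are clustered greedily on protein identity; reference genes are
    always kept, while a novel gene survives only when it is the
    representative of a cluster containing no reference gene.
    """
    for gid in proteins:
        if origins.get(gid) not in ("reference", "novel"):
            raise ValueError(f"gene {gid!r}: origin must be reference|novel")
    clusters = greedy_cluster(proteins, threshold=threshold)
    by_rep: dict[str, list[str]] = {}
    for gid, rep in clusters.membership.items():
        by_rep.setdefault(rep, []).append(gid)
    kept: list[str] = []
    for rep, members in by_rep.items():
        has_ref = any(origins[g] == "reference" for g in members)
        for g in members:
            if origins[g] == "reference":
                kept.append(g)
            elif g == rep and not has_ref:
                kept.append(g)
    return sorted(kept)
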