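"""K-mer planning, scaffold splitting, clustering, pan-genome assembly."""

import re

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from panpav.novelseq import (
    ContigAlignment,
    TaxHit,
    build_pan,
    contamination_filter,
    dedup_genes,
    greedy_cluster,
    initial_kmer,
    n50,
    pair_identity,
    pan_to_contig,
    plan_kmer,
    select_novel_candidates,
    split_scaffold,
)
from panpav.simdata import random_sequence


class TestInitialKmer:
    @pytest.mark.parametrize("depth, k", [(20, 35), (4.2, 23), (63.8, 69)])
    def test_formula(self, depth, k):
        assert initial_kmer(depth) == k

    def test_clamped_and_odd(self):
        assert initial_kmer(1000) == 127
        assert initial_kmer(0.001, k_min=15) == 21  # 2*int(10.0004)+1
        assert initial_kmer(500) % 2 == 1

    def test_bad_depth(self):
        with pytest.raises(ValueError):
            initial_kmer(0)


class TestN50:
    @pytest.mark.parametrize(
        "lengths, expected",
        [([100], 100), ([5, 4, 3, 2, 1], 4), ([8, 4, 3, 1], 8)],
    )
    def test_examples(self, lengths, expected):
        assert n50(lengths) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            n50([])

    @given(st.lists(st.integers(1, 500), min_size=1, max_size=30))
    def test_matches_definition_scan(self, lengths):
        """Brute force: largest L whose >=L sequences hold half the bases."""
        total = sum(lengths)
        candidates = [
            L for L in set(lengths)
            if sum(x for x in lengths if x >= L) >= total / 2
        ]
        assert n50(lengths) == max(candidates)


class TestPlanKmer:
    def test_hill_climb_trace_to_peak(self):
        profile = {k: 100 - (k - 41) ** 2 for k in range(15, 128, 2)}
        plan = plan_kmer(20, lambda k: profile[k])
        assert plan.chosen_k == 41
        assert sorted(plan.evaluations) == [33, 35, 37, 39, 41, 43]

    def test_constant_profile_stops_at_init(self):
        plan = plan_kmer(20, lambda k: 1.0)
        assert plan.chosen_k == 35
        assert plan.n_evaluations == 3

    def test_peak_at_init(self):
        profile = {k: 100 - (k - 35) ** 2 for k in range(15, 128, 2)}
        plan = plan_kmer(20, lambda k: profile[k])
        assert plan.chosen_k == 35
        assert plan.n_evaluations == 3

    def test_monotone_profiles_terminate_at_bounds(self):
        up = plan_kmer(20, lambda k: float(k))
        assert up.chosen_k == 127
        down = plan_kmer(20, lambda k: float(-k))
        assert down.chosen_k in (15, 17)  # best within the final window
        assert down.evaluations  # terminated with a trace

    def test_evaluation_budget(self):
        calls = []

        def ev(k):
            calls.append(k)
            return float(k % 7)

        plan_kmer(20, ev)
        assert len(calls) == len(set(calls))  # memoized, each K at most once
        assert len(calls) <= (127 - 15) // 2 + 1

    def test_evaluator_failure_carries_trace(self):
        def ev(k):
            if k == 37:
                raise RuntimeError("assembler crashed")
            return 1.0

        with pytest.raises(RuntimeError, match="K=37"):
            plan_kmer(20, ev)


class TestSplitScaffold:
    @pytest.mark.parametrize(
        "seq, expected",
        [
            ("AAA" + "N" * 11 + "CCC", ["AAA", "CCC"]),
            ("AAA" + "N" * 10 + "CCC", ["AAA" + "N" * 10 + "CCC"]),
            ("N" * 12, []),
            ("ACGT", ["ACGT"]),
            ("N" * 20 + "ACGT" + "N" * 20, ["ACGT"]),
        ],
    )
    def test_examples(self, seq, expected):
        assert split_scaffold(seq) == expected

    @given(st.text(alphabet="ACGTN", max_size=200))
    def test_conservation(self, seq):
        """Contigs plus the removed long N runs reconstruct the input."""
        contigs = split_scaffold(seq)
        assert "".join(contigs) == re.sub("N{11,}", "", seq)
        for c in contigs:
            assert not re.search("N{11,}", c)
            assert c != ""


class TestSelectNovelCandidates:
    def _aln(self, cid, length, block, matches):
        return ContigAlignment(contig_id=cid, contig_length=length, target="ref",
                               contig_start=0, contig_end=block,
                               target_start=0, target_end=block,
                               matches=matches, block_length=block)

    def test_length_strictly_over_500(self):
        contigs = {"a": "A" * 501, "b": "C" * 500}
        assert set(select_novel_candidates(contigs, [])) == {"a"}

    def test_good_alignment_drops_contig(self):
        contigs = {"a": "A" * 1000}
        alns = [self._aln("a", 1000, 900, 891)]  # identity 0.99
        assert select_novel_candidates(contigs, alns) == {}

    def test_short_block_kept(self):
        contigs = {"a": "A" * 1000}
        alns = [self._aln("a", 1000, 60, 57)]  # 60 bp block below min_block
        assert set(select_novel_candidates(contigs, alns)) == {"a"}

    def test_low_identity_block_kept(self):
        contigs = {"a": "A" * 1000}
        alns = [self._aln("a", 1000, 200, 100)]  # identity 0.5
        assert set(select_novel_candidates(contigs, alns)) == {"a"}

    def test_unknown_contig_rejected(self):
        with pytest.raises(KeyError):
            select_novel_candidates({}, [self._aln("ghost", 10, 10, 10)])


class TestPairIdentity:
    def test_identical(self):
        assert pair_identity("ACGTACGT", "ACGTACGT") == 1.0

    def test_prefix_uses_shorter_denominator(self):
        b = "ACGTTGCAACGTTGCA"
        assert pair_identity(b[:8], b) == 1.0

    def test_disjoint(self):
        assert pair_identity("AAAA", "TTTT") == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pair_identity("", "ACGT")

    def test_known_mismatch_count(self):
        a = "ACGTACGTAC"
        b = "ACGTTCGTAC"  # one substitution
        assert pair_identity(a, b) == pytest.approx(0.9)


class TestGreedyCluster:
    def test_identical_pair_one_representative(self):
        res = greedy_cluster({"a": "ACGTACGTAC", "b": "ACGTACGTAC"})
        assert len(res.representatives) == 1
        assert set(res.membership.values()) == set(res.representatives)

    def test_dissimilar_singletons(self):
        rng = np.random.default_rng(4)
        seqs = {f"s{i}": random_sequence(rng, 200) for i in range(3)}
        res = greedy_cluster(seqs)
        assert sorted(res.representatives) == sorted(seqs)

    def test_planted_clusters_recovered(self):
        """Five 2%-mutated copies of three distinct 1 kb sequences."""
        rng = np.random.default_rng(11)
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        seqs = {}
        for fam in range(3):
            ref = np.frombuffer(random_sequence(rng, 1000).encode(), np.uint8)
            for copy in range(5):
                mutated = ref.copy()
                hit = rng.random(1000) < 0.02
                mutated[hit] = bases[rng.integers(0, 4, hit.sum())]
                seqs[f"f{fam}c{copy}"] = mutated.tobytes().decode()
        res = greedy_cluster(seqs, threshold=0.90)
        assert len(res.representatives) == 3
        for sid, rep in res.membership.items():
            assert sid[:2] == rep[:2]  # assigned within its own family
            assert pair_identity(seqs[sid], seqs[rep]) >= 0.90


class TestContaminationFilter:
    def _hit(self, q, evalue, pident, lineage):
        return TaxHit(query=q, subject=f"sub_{evalue}", evalue=evalue,
                      pident=pident, lineage=lineage)

    def test_plant_best_hit_kept(self):
        contigs = {"c": "ACGT"}
        hits = [self._hit("c", 1e-30, 95.0,
                          ("Eukaryota", "Viridiplantae", "Oryza"))]
        assert set(contamination_filter(contigs, hits)) == {"c"}

    def test_bacterial_best_hit_dropped_despite_plant_second(self):
        contigs = {"c": "ACGT"}
        hits = [
            self._hit("c", 1e-50, 90.0, ("Bacteria", "Proteobacteria")),
            self._hit("c", 1e-10, 99.0, ("Eukaryota", "Viridiplantae")),
        ]
        assert contamination_filter(contigs, hits) == {}

    def test_evalue_tie_broken_by_identity(self):
        contigs = {"c": "ACGT"}
        hits = [
            self._hit("c", 1e-20, 80.0, ("Bacteria",)),
            self._hit("c", 1e-20, 95.0, ("Eukaryota", "Viridiplantae")),
        ]
        assert set(contamination_filter(contigs, hits)) == {"c"}

    def test_no_hits_kept(self):
        assert set(contamination_filter({"c": "ACGT"}, [])) == {"c"}


class TestPanBuild:
    def test_two_contigs_layout(self):
        build = build_pan({"chr1": "ACGT"}, {"c1": "A" * 300, "c2": "C" * 400})
        assert len(build.novel_sequence) == 800
        assert build.offsets == [("c1", 0, 300), ("c2", 400, 400)]
        assert build.novel_sequence[300:400] == "N" * 100

    def test_single_contig_no_spacer(self):
        build = build_pan({}, {"c1": "ACGTACGT"})
        assert build.novel_sequence == "ACGTACGT"

    def test_zero_contigs(self):
        build = build_pan({"chr1": "ACGT"}, {})
        assert build.novel_sequence == ""
        assert build.offsets == []

    def test_id_collision_rejected(self):
        with pytest.raises(ValueError, match="collide"):
            build_pan({"c1": "ACGT"}, {"c1": "ACGT"})

    @pytest.mark.parametrize(
        "pos, expected", [(0, ("c1", 0)), (350, "spacer"), (400, ("c2", 0))]
    )
    def test_pan_to_contig_examples(self, pos, expected):
        build = build_pan({}, {"c1": "A" * 300, "c2": "C" * 400})
        assert pan_to_contig(build, pos) == expected

    def test_out_of_range(self):
        build = build_pan({}, {"c1": "ACGT"})
        with pytest.raises(IndexError):
            pan_to_contig(build, 4)

    @given(st.integers(0, 2**32 - 1))
    def test_round_trip_on_non_spacer_positions(self, seed):
        rng = np.random.default_rng(seed)
        contigs = {
            f"c{i}": random_sequence(rng, int(rng.integers(50, 300)))
            for i in range(int(rng.integers(1, 6)))
        }
        build = build_pan({}, contigs)
        for cid, off, length in build.offsets:
            for pos in (0, length // 2, length - 1):
                assert pan_to_contig(build, off + pos) == (cid, pos)
                assert build.novel_sequence[off + pos] == contigs[cid][pos]


class TestDedupGenes:
    def test_novel_similar_to_reference_dropped(self):
        prot = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ" * 3
        mutated = prot[:50] + "A" + prot[51:]
        kept = dedup_genes({"refA": prot, "novB": mutated},
                           {"refA": "reference", "novB": "novel"})
        assert kept == ["refA"]

    def test_novel_cluster_keeps_representative_only(self):
        prot = "MSTNPKPQRKTKRNTNRRPQDVKFPGG" * 4
        longer = prot + "EXTRA"
        kept = dedup_genes({"novC": longer, "novD": prot},
                           {"novC": "novel", "novD": "novel"})
        assert kept == ["novC"]  # longest is the representative

    def test_reference_pair_both_kept(self):
        prot = "MLKFVQQQRSA" * 5
        kept = dedup_genes({"refA": prot, "refB": prot},
                           {"refA": "reference", "refB": "reference"})
        assert kept == ["refA", "refB"]

    def test_distinct_novel_genes_all_kept(self):
        rng = np.random.default_rng(8)
        alphabet = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype=np.uint8)
        prots = {
            f"nov{i}": rng.choice(alphabet, 120).tobytes().decode()
            for i in range(3)
        }
        kept = dedup_genes(prots, {g: "novel" for g in prots})
        assert kept == sorted(prots)
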