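"""Distances, trees, parsimony, kinship and mixed-model association."""

import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest

from panpav import popgen
from panpav.covpav import PavMatrix
from panpav.popgen import (
    DistanceMatrix,
    bn_kinship,
    bonferroni_threshold,
    emma_reml,
    emmax_scan,
    fitch_length,
    group_monophyly,
    nj_tree,
    pav_distance,
)
from panpav.popgen.kinship import KinshipMatrix
from panpav.popgen.mixedmodel import VarianceComponents


def matrix(data, rows, cols):
    return PavMatrix(pd.DataFrame(data, index=rows, columns=cols))


class TestPavDistance:
    def test_three_of_ten_markers_differ(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 2, size=10)
        b = a.copy()
        b[[2, 5, 7]] = 1 - b[[2, 5, 7]]  # differ at exactly 3 of 10 markers
        m = matrix(np.column_stack([a, b]), [f"m{i}" for i in range(10)], ["A", "B"])
        d = pav_distance(m)
        assert d.values[0, 1] == pytest.approx(0.3)
        np.testing.assert_allclose(np.diag(d.values), 0)

    def test_identical_and_complementary(self):
        m = matrix([[0, 0, 1], [1, 1, 0]], ["m1", "m2"], ["A", "B", "C"])
        d = pav_distance(m)
        assert d.values[0, 1] == 0.0
        assert d.values[0, 2] == 1.0

    def test_zero_markers_rejected(self):
        with pytest.raises(ValueError):
            pav_distance(matrix(np.empty((0, 3), dtype=int), [], ["A", "B", "C"]))


class TestNjTree:
    def test_three_taxon_closed_form(self):
        d = DistanceMatrix(["A", "B", "C"],
                           np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float))
        tree = nj_tree(d)
        lengths = {leaf.taxon.label: leaf.edge.length
                   for leaf in tree.leaf_node_iter()}
        assert lengths == {"A": 1.0, "B": 1.0, "C": 3.0}

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["A", "B"], np.array([[0, 1], [1, 0]], float)))

    @pytest.mark.parametrize("seed", range(10))
    def test_additive_distances_recover_topology(self, seed):
        """NJ is consistent: exact additive distances give back the tree."""
        rng = np.random.default_rng(seed)
        n_leaves = int(rng.integers(6, 11))
        ids = [f"t{i}" for i in range(n_leaves)]
        # random binary topology by repeated joining, positive branch lengths
        newicks = [f"{t}:{rng.uniform(0.1, 1.0):.4f}" for t in ids]
        while len(newicks) > 2:
            i, j = sorted(rng.choice(len(newicks), size=2, replace=False))
            merged = (f"({newicks[i]},{newicks[j]}):{rng.uniform(0.1, 1.0):.4f}")
            newicks = [s for k, s in enumerate(newicks) if k not in (i, j)]
            newicks.append(merged)
        taxa = dendropy.TaxonNamespace(ids)
        true = dendropy.Tree.get(
            data=f"({newicks[0]},{newicks[1]});",
            schema="newick",
            taxon_namespace=taxa,
        )
        true.is_rooted = False
        pdm = true.phylogenetic_distance_matrix()
        D = np.zeros((n_leaves, n_leaves))
        for i, j in itertools.combinations(range(n_leaves), 2):
            t1 = taxa.get_taxon(ids[i])
            t2 = taxa.get_taxon(ids[j])
            D[i, j] = D[j, i] = pdm.distance(t1, t2)
        est = nj_tree(DistanceMatrix(ids, D))
        est.migrate_taxon_namespace(taxa)
        true.encode_bipartitions()
        est.encode_bipartitions()
        rf = dendropy.calculate.treecompare.symmetric_difference(true, est)
        assert rf == 0

    def test_equal_distances_total_length(self):
        n = 5
        D = np.ones((n, n)) - np.eye(n)
        tree = nj_tree(DistanceMatrix([f"t{i}" for i in range(n)], D))
        total = sum(e.length for e in tree.preorder_edge_iter()
                    if e.length is not None)
        # every pairwise path has length 1 => each leaf edge 0.5, internals 0
        assert total == pytest.approx(n * 0.5)


def _tree(newick, labels):
    taxa = dendropy.TaxonNamespace(labels)
    return dendropy.Tree.get(data=newick, schema="newick", taxon_namespace=taxa)


class TestFitchLength:
    def test_hand_examples(self):
        t = _tree("((A,B),(C,D));", ["A", "B", "C", "D"])
        m1 = matrix([[0, 0, 1, 1]], ["m"], ["A", "B", "C", "D"])
        assert fitch_length(t, m1) == 1
        m2 = matrix([[0, 1, 0, 1]], ["m"], ["A", "B", "C", "D"])
        assert fitch_length(t, m2) == 2
        m3 = matrix([[1, 1, 1, 1]], ["m"], ["A", "B", "C", "D"])
        assert fitch_length(t, m3) == 0

    def test_sums_over_markers(self):
        t = _tree("((A,B),(C,D));", ["A", "B", "C", "D"])
        m = matrix([[0, 0, 1, 1], [0, 1, 0, 1], [1, 1, 1, 1]],
                   ["m1", "m2", "m3"], ["A", "B", "C", "D"])
        assert fitch_length(t, m) == 3

    def test_leaf_mismatch_rejected(self):
        t = _tree("((A,B),(C,D));", ["A", "B", "C", "D"])
        with pytest.raises(ValueError):
            fitch_length(t, matrix([[0, 1]], ["m"], ["A", "B"]))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_minimization(self, seed):
        """Fitch equals brute force over all internal labelings (<=6 leaves)."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 7))
        labels = [f"L{i}" for i in range(n)]
        # random caterpillar topology over shuffled leaves
        order = list(rng.permutation(labels))
        newick = f"({order[0]},{order[1]})"
        for leaf in order[2:]:
            newick = f"({newick},{leaf})"
        tree = _tree(newick + ";", labels)
        states = rng.integers(0, 2, size=(3, n))
        m = matrix(states, [f"m{i}" for i in range(3)], labels)
        internals = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
        total_bf = 0
        for row in states:
            leaf_state = dict(zip(labels, row))
            best = np.inf
            for assign in itertools.product((0, 1), repeat=len(internals)):
                lab = {id(nd): s for nd, s in zip(internals, assign)}
                for nd in tree.leaf_node_iter():
                    lab[id(nd)] = leaf_state[nd.taxon.label]
                cost = sum(
                    lab[id(nd)] != lab[id(ch)]
                    for nd in tree.preorder_node_iter()
                    for ch in nd.child_nodes()
                )
                best = min(best, cost)
            total_bf += best
        assert fitch_length(tree, m) == total_bf


class TestGroupMonophyly:
    def test_split_detected(self):
        t = _tree("((A,B),(C,D));", ["A", "B", "C", "D"])
        assert group_monophyly(t, {"A": "x", "B": "x", "C": "y", "D": "y"})
        assert not group_monophyly(t, {"A": "x", "B": "y", "C": "x", "D": "y"})


class TestBnKinship:
    def test_single_marker_closed_form(self):
        K = bn_kinship(matrix([[1, 0]], ["m"], ["A", "B"]))
        np.testing.assert_allclose(K.values, [[1, -1], [-1, 1]])

    def test_identical_accessions(self):
        K = bn_kinship(matrix([[1, 1, 0], [0, 0, 1], [1, 1, 0]],
                              ["m1", "m2", "m3"], ["A", "B", "C"]))
        assert K.values[0, 1] == pytest.approx(K.values[0, 0])

    def test_monomorphic_markers_excluded(self):
        with_mono = matrix([[1, 0], [1, 1], [0, 0]], ["m1", "m2", "m3"], ["A", "B"])
        only_poly = matrix([[1, 0]], ["m1"], ["A", "B"])
        np.testing.assert_allclose(
            bn_kinship(with_mono).values, bn_kinship(only_poly).values
        )

    def test_all_monomorphic_rejected(self):
        with pytest.raises(ValueError):
            bn_kinship(matrix([[1, 1], [0, 0]], ["m1", "m2"], ["A", "B"]))

    def test_independent_markers_off_diagonal_small(self):
        # n large enough that the -1/(n-1) centering bias is negligible
        rng = np.random.default_rng(0)
        m_markers, n = 2000, 100
        X = rng.binomial(1, 0.5, size=(m_markers, n))
        K = bn_kinship(matrix(X, [f"m{i}" for i in range(m_markers)],
                              [f"a{i}" for i in range(n)]))
        off = K.values[~np.eye(n, dtype=bool)]
        assert abs(off.mean()) < 3 / np.sqrt(m_markers)

    def test_psd(self):
        rng = np.random.default_rng(1)
        X = rng.binomial(1, 0.3, size=(100, 15))
        X[0] = 1  # keep a monomorphic row in the mix
        K = bn_kinship(matrix(X, [f"m{i}" for i in range(100)],
                              [f"a{i}" for i in range(15)]))
        assert K.min_eigenvalue >= -1e-8


def _structured_kinship(rng, n, m_markers=300):
    """Kinship from group-structured binary markers (two populations with
    independent per-group frequencies), via the package's own estimator."""
    half = n // 2
    pA = rng.uniform(0.1, 0.9, size=(m_markers, 1))
    pB = rng.uniform(0.1, 0.9, size=(m_markers, 1))
    X = np.zeros((m_markers, n), dtype=int)
    X[:, :half] = rng.random((m_markers, half)) < pA
    X[:, half:] = rng.random((m_markers, n - half)) < pB
    return bn_kinship(matrix(X, [f"m{i}" for i in range(m_markers)],
                             [f"a{i}" for i in range(n)]))


def _family_kinship(rng, n, m_markers=300, fam_size=10, mut=0.1):
    """Kinship from families of near-identical marker profiles."""
    nf = n // fam_size
    founders = rng.random((m_markers, nf)) < rng.uniform(0.1, 0.9, size=(m_markers, 1))
    X = np.zeros((m_markers, n), dtype=int)
    for f in range(nf):
        for k in range(fam_size):
            flip = rng.random(m_markers) < mut
            X[:, f * fam_size + k] = np.where(
                flip, rng.random(m_markers) < 0.5, founders[:, f]
            )
    return bn_kinship(matrix(X, [f"m{i}" for i in range(m_markers)],
                             [f"a{i}" for i in range(n)]))


class TestEmmaReml:
    def test_identity_kinship_collapses_to_ols_variance(self):
        rng = np.random.default_rng(2)
        n = 150
        y = rng.normal(size=n)
        K = KinshipMatrix([f"a{i}" for i in range(n)], np.eye(n))
        vc = emma_reml(y, np.ones((n, 1)), K)
        assert not vc.delta_identifiable
        ols_var = float(((y - y.mean()) ** 2).sum() / (n - 1))
        assert vc.total == pytest.approx(ols_var, abs=1e-6)

    def test_delta_recovery_within_factor_two(self):
        n = 200
        ratios = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            K = _structured_kinship(rng, n)
            L = np.linalg.cholesky(K.values + 1e-8 * np.eye(n))
            y = L @ rng.normal(size=n) + rng.normal(size=n)  # true delta = 1
            vc = emma_reml(y, np.ones((n, 1)), K)
            ratios.append(vc.delta)
        med = float(np.median(ratios))
        assert 0.5 <= med <= 2.0

    def test_zero_genetic_variance_detected(self):
        """Null traits yield near-zero genetic variance when the kinship is
        informative (family blocks give the eigenvalue dispersion that
        variance-component precision requires)."""
        n = 200
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            K = _family_kinship(rng, n)
            y = rng.normal(size=n)  # sigma_g^2 = 0
            vc = emma_reml(y, np.ones((n, 1)), K)
            if vc.genetic <= 0.05 * vc.total:
                hits += 1
        assert hits >= 18

    def test_no_better_grid_point(self):
        """Optimizer sanity: returned delta beats a 50-point delta grid."""
        from panpav.popgen.mixedmodel import reml_profile

        rng = np.random.default_rng(5)
        n = 120
        K = _structured_kinship(rng, n)
        L = np.linalg.cholesky(K.values + 1e-8 * np.eye(n))
        y = L @ rng.normal(size=n) + 0.5 * rng.normal(size=n)
        X = np.ones((n, 1))
        vc = emma_reml(y, X, K)
        loglik, _ = reml_profile(y, X, K)
        grid_best = max(loglik(g) for g in np.linspace(-10, 10, 50))
        assert vc.reml_loglik >= grid_best - 1e-9

    def test_constant_trait_rejected(self):
        K = KinshipMatrix(["a", "b", "c"], np.eye(3))
        with pytest.raises(ValueError):
            emma_reml(np.ones(3), np.ones((3, 1)), K)


class TestEmmaxScan:
    def test_identity_kinship_reproduces_ols(self):
        from scipy import stats

        rng = np.random.default_rng(3)
        n = 120
        y = rng.normal(size=n)
        ids = [f"a{i}" for i in range(n)]
        K = KinshipMatrix(ids, np.eye(n))
        X = np.ones((n, 1))
        M = rng.binomial(1, 0.4, size=(30, n))
        pav = matrix(M, [f"m{i}" for i in range(30)], ids)
        ols_var = float(((y - y.mean()) ** 2).sum() / (n - 1))
        vc = VarianceComponents(genetic=0.0, residual=ols_var, delta=np.inf,
                                reml_loglik=0.0)
        scan = emmax_scan(y, X, pav, K, vc)
        for r in scan.results:
            x = M[int(r.marker[1:])].astype(float)
            A = np.column_stack([np.ones(n), x])
            beta, *_ = np.linalg.lstsq(A, y, rcond=None)
            resid = y - A @ beta
            s2 = float(resid @ resid) / (n - 2)
            se = np.sqrt(s2 * np.linalg.inv(A.T @ A)[1, 1])
            t = beta[1] / se
            p = float(2 * stats.t.sf(abs(t), n - 2))
            assert r.pvalue == pytest.approx(p, abs=1e-8)

    def test_null_pvalues_uniform(self):
        from scipy import stats

        rng = np.random.default_rng(4)
        n = 150
        ids = [f"a{i}" for i in range(n)]
        y = rng.normal(size=n)
        K = KinshipMatrix(ids, np.eye(n))
        M = rng.binomial(1, 0.5, size=(1000, n))
        pav = matrix(M, [f"m{i}" for i in range(1000)], ids)
        vc = VarianceComponents(genetic=0.0, residual=1.0, delta=np.inf,
                                reml_loglik=0.0)
        scan = emmax_scan(y, np.ones((n, 1)), pav, K, vc)
        pvals = [r.pvalue for r in scan.results]
        ks = stats.kstest(pvals, "uniform").statistic
        assert ks < 0.05

    def test_monomorphic_and_collinear_skipped(self):
        n = 50
        rng = np.random.default_rng(6)
        ids = [f"a{i}" for i in range(n)]
        y = rng.normal(size=n)
        K = KinshipMatrix(ids, np.eye(n))
        M = np.vstack([np.ones(n, dtype=int), np.ones(n, dtype=int)])
        M[1, :] = 1  # identical to the intercept after the monomorphic skip
        pav = matrix(M, ["mono", "copy"], ids)
        vc = VarianceComponents(genetic=0.0, residual=1.0, delta=np.inf,
                                reml_loglik=0.0)
        scan = emmax_scan(y, np.ones((n, 1)), pav, K, vc)
        assert scan.skipped["mono"] == "monomorphic"
        assert not scan.results


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha, m, expected", [(0.01, 20_000, 5e-7), (0.01, 1, 0.01), (0.05, 100, 5e-4)]
    )
    def test_examples(self, alpha, m, expected):
        assert bonferroni_threshold(alpha, m) == pytest.approx(expected)

    def test_zero_markers_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.01, 0)


class TestPhylipWriter:
    def test_shape_and_padding(self, tmp_path):
        m = matrix([[0, 1], [1, 0], [1, 1]], ["m1", "m2", "m3"],
                   ["longaccessionname", "B"])
        path = tmp_path / "chars.phy"
        popgen.write_phylip_characters(m, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "2 3"
        assert lines[1] == "longaccess011"
        assert lines[2] == "B         101"
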