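"""Distances, neighbor-joining and Fitch parsimony for 0/1 PAV matrices.

The phylogenies here serve one validation question: do presence/absence
characters alone separate known population groups into clean clades?  A
deterministic Saitou-Nei neighbor-joining tree is built from simple
mismatch-proportion distances and scored with Fitch small parsimony;
heuristic parsimony *search* is deliberately not attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
from scipy.spatial.distance import pdist, squareform

from ..covpav import PavMatrix

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix diagonal must be zero")
        if (v < 0).any():
            raise ValueError("distances must be non-negative")
        self.values = v


def pav_distance(matrix: PavMatrix) -> DistanceMatrix:
    """Pairwise distance between accessions: proportion of differing markers."""
    if matrix.shape[0] == 0:
        raise ValueError("cannot compute distances with zero markers")
    if matrix.shape[1] < 2:
        raise ValueError("need at least two accessions")
    X = matrix.values().T.astype(float)  # accessions x markers
    d = squareform(pdist(X, metric="hamming"))
    return DistanceMatrix(ids=matrix.accessions, values=d)


def nj_tree(d: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining, deterministic under ties.

    Ties in the Q criterion are broken by the smallest (i, j) index pair in
    the current node order.  Negative branch lengths are clamped to zero
    with a warning (standard practice).  The returned tree is unrooted,
    represented with a trifurcating seed node.
    """
    n = len(d.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    taxa = dendropy.TaxonNamespace(d.ids)
    nodes: list[dendropy.Node] = []
    for name in d.ids:
        node = dendropy.Node(taxon=taxa.get_taxon(name))
        nodes.append(node)
    D = d.values.copy()
    active = list(range(n))
    n_clamped = 0

    def set_len(node: dendropy.Node, length: float) -> None:
        nonlocal n_clamped
        if length < 0:
            n_clamped += 1
            length = 0.0
        node.edge.length = float(length)

    while len(active) > 3:
        m = len(active)
        r = np.array([sum(D[i][k] for k in active if k != i) for i in active])
        best = None
        best_q = np.inf
        for ai in range(m):
            for aj in range(ai + 1, m):
                q = (m - 2) * D[active[ai]][active[aj]] - r[ai] - r[aj]
                if q < best_q - 1e-12:
                    best_q = q
                    best = (ai, aj)
        ai, aj = best
        i, j = active[ai], active[aj]
        dij = D[i][j]
        li = dij / 2 + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        set_len(nodes[i], li)
        set_len(nodes[j], lj)
        # reuse slot i for the new node
        for k in active:
            if k not in (i, j):
                D[i][k] = D[k][i] = (D[i][k] + D[j][k] - dij) / 2
        nodes[i] = parent
        active.remove(j)

    i, j, k = active
    center = dendropy.Node()
    set_len(nodes[i], (D[i][j] + D[i][k] - D[j][k]) / 2)
    set_len(nodes[j], (D[i][j] + D[j][k] - D[i][k]) / 2)
    set_len(nodes[k], (D[i][k] + D[j][k] - D[i][j]) / 2)
    for node in (nodes[i], nodes[j], nodes[k]):
        center.add_child(node)
    if n_clamped:
        logger.warning("clamped %d negative branch lengths to zero", n_clamped)
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=center)
    tree.is_rooted = False
    return tree


def fitch_length(tree: dendropy.Tree, matrix: PavMatrix) -> int:
    """Total Fitch small-parsimony length of the 0/1 matrix on the tree.

    The unrooted tree is scored at its (arbitrary) seed node; children at
    a multifurcation are folded sequentially, which corresponds to rooting
    the unrooted topology along one of its edges and leaves the parsimony
    length unchanged.
    """
    leaf_names = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    if leaf_names != set(matrix.accessions):
        raise ValueError("tree leaves and matrix accessions differ")
    states = {a: matrix.df[a].to_numpy() for a in matrix.accessions}
    changes = np.zeros(matrix.shape[0], dtype=np.int64)
    masks: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            masks[id(node)] = (1 << states[node.taxon.label]).astype(np.uint8)
            continue
        children = node.child_nodes()
        acc = masks.pop(id(children[0]))
        for child in children[1:]:
            c = masks.pop(id(child))
            inter = acc & c
            empty = inter == 0
            changes += empty
            acc = np.where(empty, acc | c, inter)
        masks[id(node)] = acc
    return int(changes.sum())


def group_monophyly(tree: dendropy.Tree, groups: Mapping[str, str]) -> bool:
    """Does some edge of the unrooted tree split the leaves exactly by group?

    ``groups`` maps leaf label to group label; True iff every group is a
    clade on some rooting of the tree, i.e. for each group there is an
    edge whose leaf-side equals exactly that group.
    """
    all_leaves = frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())
    if set(groups) != all_leaves:
        raise ValueError("groups must label exactly the tree's leaves")
    group_sets = {}
    for leaf, g in groups.items():
        group_sets.setdefault(g, set()).add(leaf)
    clades: set[frozenset[str]] = set()
    below: dict[int, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            s = frozenset([node.taxon.label])
        else:
            s = frozenset().union(*(below[id(c)] for c in node.child_nodes()))
        below[id(node)] = s
        clades.add(s)
        clades.add(all_leaves - s)
    return all(frozenset(s) in clades for s in group_sets.values())


def write_phylip_characters(matrix: PavMatrix, path) -> None:
    """Write the 0/1 matrix as a PHYLIP discrete-character file.

    Names are padded/truncated to the classic 10 characters, for
    interoperability with phylip's parsimony tools.
    """
    with open(path, "w") as fh:
        fh.write(f"{matrix.shape[1]} {matrix.shape[0]}\n")
        for acc in matrix.accessions:
            name = acc[:10].ljust(10)
            fh.write(name + "".join(str(v) for v in matrix.df[acc]) + "\n")
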