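"""Neighbor-joining tree of cluster representatives.

Distances are 1 - global percent identity between representative protein
sequences. Neighbor joining (Saitou-Nei Q-criterion) is implemented here
with fixed tie-breaking (ties in Q resolved by the smallest (i, j) index
pair) and negative branch-length estimates clamped to 0, so runs are
bit-reproducible. The tree method is a pragmatic choice for desk-scale
determinism, not an attempt to match any published topology.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import dendropy
import numpy as np
from skbio import DistanceMatrix

from .cluster_patterns import pairwise_identity


def distance_matrix(representatives: Mapping[str, str]) -> DistanceMatrix:
    """All-vs-all 1 - identity distances between representative sequences."""
    labels = list(representatives)
    if len(labels) < 2:
        raise ValueError("need at least 2 sequences for a distance matrix")
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate labels in representative set")
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ident = pairwise_identity(
                representatives[labels[i]], representatives[labels[j]]
            ).identity
            d[i, j] = d[j, i] = 1.0 - ident
    return DistanceMatrix(d, ids=labels)


def _clamp(x: float) -> float:
    if x < 0:
        warnings.warn(f"negative NJ branch length {x:.3g} clamped to 0")
        return 0.0
    return x


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor joining on a distance matrix.

    For n == 2 the two leaves are joined by a single split edge, each
    branch d/2. For n >= 3, the standard agglomeration runs until three
    nodes remain, which are joined under an unrooted trifurcation by the
    three-point formula. Deterministic for a fixed label order.
    """
    labels = list(dm.ids)
    d = np.asarray(dm.data, dtype=float).copy()
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite distances in matrix")
    n = len(labels)

    taxa = dendropy.TaxonNamespace(labels)
    nodes: list[dendropy.Node] = []
    for label in labels:
        node = dendropy.Node()
        node.taxon = taxa.get_taxon(label)
        nodes.append(node)

    if n == 2:
        root = dendropy.Node()
        for node in nodes:
            node.edge.length = _clamp(d[0, 1] / 2.0)
            root.add_child(node)
        tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
        tree.is_rooted = False
        return tree

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        # Q(i, j) = (m - 2) d(i, j) - r_i - r_j; pick min, ties by (i, j)
        best = None
        best_q = np.inf
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if q < best_q:
                    best_q = q
                    best = (i, j)
        i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        parent = dendropy.Node()
        nodes[i].edge.length = _clamp(li)
        nodes[j].edge.length = _clamp(lj)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])

        new_d = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d2 = np.zeros((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = new_d[keep]
        d = d2
        nodes = [nodes[k] for k in keep] + [parent]

    # join the final three nodes under an unrooted trifurcation
    root = dendropy.Node()
    lengths = [
        0.5 * (d[0, 1] + d[0, 2] - d[1, 2]),
        0.5 * (d[0, 1] + d[1, 2] - d[0, 2]),
        0.5 * (d[0, 2] + d[1, 2] - d[0, 1]),
    ]
    for node, length in zip(nodes, lengths):
        node.edge.length = _clamp(length)
        root.add_child(node)
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = False
    return tree


def leaf_bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial leaf-set bipartitions (smaller side, by frozenset of labels).

    Computed directly by walking internal edges, independent of dendropy's
    bipartition encoding; used for topology comparison.
    """
    all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    splits: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        other = all_leaves - side
        if len(side) >= 2 and len(other) >= 2:
            splits.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return splits


def tree_distances_additive(tree: dendropy.Tree) -> DistanceMatrix:
    """Path-length (patristic) distance matrix of a tree's leaves.

    The independent generator for NJ recovery checks: NJ on this matrix
    must return the original topology when all branch lengths are positive.
    """
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(
                taxa[labels[i]], taxa[labels[j]]
            )
    return DistanceMatrix(d, ids=labels)
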