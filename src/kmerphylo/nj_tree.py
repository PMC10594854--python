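"""Neighbor-joining tree construction and Newick/Robinson–Foulds utilities.

The classic agglomerative algorithm of Saitou & Nei: repeatedly join the
pair (a, b) minimizing

    Q(a, b) = (m − 2)·d(a, b) − Σ_c d(a, c) − Σ_c d(b, c)

where m is the number of active nodes, assign branch lengths by the
standard formulas, and reduce the matrix. On an additive matrix NJ
recovers the generating tree exactly. Trees are returned as unrooted
:class:`dendropy.Tree` objects (trifurcating seed node).

Determinism contract: Q-ties are broken by the smallest (row, column)
index pair, and negative branch lengths are clamped to zero with the
deficit moved to the sister branch, so identical inputs give identical
Newick strings.
"""

from __future__ import annotations

import dendropy
import numpy as np
from dendropy.calculate import treecompare

from .features_distance import DistanceMatrix

__all__ = [
    "neighbor_joining",
    "to_newick",
    "read_newick",
    "robinson_foulds",
    "tree_distance_matrix",
    "NewickParseError",
]


class NewickParseError(ValueError):
    """Malformed Newick input."""


def _join_lengths(d_ab: float, r_a: float, r_b: float, m: int) -> tuple[float, float]:
    """Branch lengths from a joined pair to the new node, clamped >= 0."""
    if m > 2:
        la = 0.5 * d_ab + (r_a - r_b) / (2.0 * (m - 2))
    else:
        la = 0.5 * d_ab
    lb = d_ab - la
    if la < 0.0:
        la, lb = 0.0, d_ab
    elif lb < 0.0:
        la, lb = d_ab, 0.0
    return la, lb


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Build an unrooted NJ tree from a symmetric distance matrix (n >= 3)."""
    n = len(dm.taxa)
    if n < 3:
        raise ValueError(f"neighbor joining needs at least 3 taxa, got {n}")
    tns = dendropy.TaxonNamespace(list(dm.taxa))
    nodes: list[dendropy.Node] = []
    for label in dm.taxa:
        nd = dendropy.Node(taxon=tns.get_taxon(label))
        nodes.append(nd)
    D = dm.d.astype(np.float64, copy=True)

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=0)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        Q[np.tril_indices(m)] = np.inf
        # row-major argmin = lexicographically smallest (row, col) among ties
        i, j = np.unravel_index(int(np.argmin(Q)), Q.shape)
        la, lb = _join_lengths(float(D[i, j]), float(r[i]), float(r[j]), m)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = la
        parent.add_child(nodes[j])
        nodes[j].edge.length = lb
        d_new = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [x for x in range(m) if x not in (i, j)]
        D_next = np.empty((m - 1, m - 1), dtype=np.float64)
        D_next[: m - 2, : m - 2] = D[np.ix_(keep, keep)]
        D_next[: m - 2, m - 2] = D_next[m - 2, : m - 2] = d_new[keep]
        D_next[m - 2, m - 2] = 0.0
        nodes = [nodes[x] for x in keep] + [parent]
        D = D_next

    # terminal three-node star: closed-form lengths to the central node
    d01, d02, d12 = float(D[0, 1]), float(D[0, 2]), float(D[1, 2])
    lengths = [
        0.5 * (d01 + d02 - d12),
        0.5 * (d01 + d12 - d02),
        0.5 * (d02 + d12 - d01),
    ]
    center = dendropy.Node()
    for nd, ln in zip(nodes, lengths):
        center.add_child(nd)
        nd.edge.length = max(0.0, ln)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=center)
    tree.is_rooted = False
    return tree


def to_newick(tree: dendropy.Tree, precision: int = 6) -> str:
    """Serialize with branch lengths, unrooted, ';'-terminated."""
    s = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=f".{precision}f",
    )
    return s.strip()


def read_newick(source: str) -> dendropy.Tree:
    """Parse a Newick string into an unrooted tree."""
    try:
        tree = dendropy.Tree.get(data=source, schema="newick")
    except Exception as exc:  # dendropy raises several parse-error types
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    tree.is_rooted = False
    return tree


def tree_distance_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Leaf-to-leaf path-length (patristic) matrix, taxa in label order.

    The result is additive on the tree by construction; feeding it back
    to :func:`neighbor_joining` must reproduce the unrooted topology.
    """
    pdm = tree.phylogenetic_distance_matrix()
    taxa_objs = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = tuple(t.label for t in taxa_objs)
    n = len(labels)
    d = np.zeros((n, n), dtype=np.float64)
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa_objs[i], taxa_objs[j])
    return DistanceMatrix(taxa=labels, d=d)


def robinson_foulds(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Unweighted RF distance: bipartitions present in exactly one tree."""
    labels1 = {lf.taxon.label for lf in t1.leaf_node_iter()}
    labels2 = {lf.taxon.label for lf in t2.leaf_node_iter()}
    if labels1 != labels2:
        raise ValueError(
            f"trees have different leaf sets: "
            f"{sorted(labels1 ^ labels2)} not shared"
        )
    # re-read both onto one namespace so bipartitions are comparable
    tns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(data=t1.as_string(schema="newick"), schema="newick",
                          taxon_namespace=tns)
    b = dendropy.Tree.get(data=t2.as_string(schema="newick"), schema="newick",
                          taxon_namespace=tns)
    a.is_rooted = False
    b.is_rooted = False
    a.encode_bipartitions()
    b.encode_bipartitions()
    return int(treecompare.symmetric_difference(a, b))
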