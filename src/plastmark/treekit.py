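"""Tree handling: newick I/O, pruning, unrooting, bipartitions, RF distances,
and a neighbor-joining fallback builder.

Trees are :class:`dendropy.Tree` objects throughout.  A bipartition is
represented canonically as the frozenset of leaf labels on the side of the
split that contains the lexicographically smallest label; only nontrivial
splits (both sides with >= 2 leaves) are reported.

The normalized Robinson-Foulds distance (nRF) between two trees on the same
leaf set is the size of the symmetric difference of their nontrivial split
sets divided by the total number of nontrivial splits in both trees; it is 0
for topologically identical trees and 1 when no split is shared.  Before a
gene tree is compared against a target (genome) tree, the target is pruned
down to the gene tree's taxa and both trees are unrooted.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import dendropy
import numpy as np

from .alignment import Alignment
from .seqstats import p_distance_pair

__all__ = [
    "parse_newick",
    "write_newick",
    "leaf_labels",
    "prune_taxa",
    "unroot",
    "bipartitions",
    "rf_distance",
    "normalized_rf",
    "gene_to_target_nrf",
    "nj_tree",
    "jc_distance_matrix",
]


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a single newick string (branch lengths, quoted labels and
    internal-node support labels supported)."""
    try:
        return dendropy.Tree.get(data=text, schema="newick",
                                 suppress_internal_node_taxa=True)
    except Exception as exc:  # dendropy raises several DataError subclasses
        raise ValueError(f"malformed newick: {exc}") from exc


def write_newick(tree: dendropy.Tree) -> str:
    s = tree.as_string(schema="newick", suppress_rooting=True)
    return s.strip()


def read_newick_file(path) -> list[dendropy.Tree]:
    """Read one or more newick trees (one per line / concatenated)."""
    trees = dendropy.TreeList.get(path=str(path), schema="newick",
                                  suppress_internal_node_taxa=True)
    return list(trees)


def leaf_labels(tree: dendropy.Tree) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in tree.leaf_node_iter())


def _clone(tree: dendropy.Tree) -> dendropy.Tree:
    return tree.clone(depth=1)


def prune_taxa(tree: dendropy.Tree, keep: Iterable[str]) -> dendropy.Tree:
    """Restrict *tree* to the leaves in *keep*.

    Suppressed degree-2 nodes have their branch lengths summed.
    """
    keep = set(keep)
    labels = leaf_labels(tree)
    if not keep <= labels:
        missing = sorted(keep - labels)
        raise ValueError(f"labels not in tree: {missing}")
    if len(keep) < 3:
        raise ValueError("need at least 3 leaves to keep")
    out = _clone(tree)
    out.retain_taxa_with_labels(sorted(keep))
    return out


def unroot(tree: dendropy.Tree) -> dendropy.Tree:
    """Collapse a degree-2 root into a basal multifurcation.

    The bipartition set is unchanged; the operation is idempotent.
    """
    if sum(1 for _ in tree.leaf_node_iter()) < 3:
        raise ValueError("need at least 3 leaves to unroot")
    out = _clone(tree)
    out.deroot()
    out.is_rooted = False
    return out


def bipartitions(tree: dendropy.Tree) -> frozenset[frozenset[str]]:
    """Nontrivial splits of *tree*, rooting-independent.

    Each internal edge contributes the leaf set below it; the split is
    canonicalized to the block containing the smallest label.
    """
    all_labels = leaf_labels(tree)
    n = len(all_labels)
    anchor = min(all_labels)
    splits: set[frozenset[str]] = set()
    below: dict[int, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = frozenset([node.taxon.label])
        else:
            below[id(node)] = frozenset().union(
                *(below[id(c)] for c in node.child_nodes())
            )
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        block = below[id(node)]
        if len(block) < 2 or n - len(block) < 2:
            continue
        if anchor not in block:
            block = all_labels - block
        splits.add(block)
    return frozenset(splits)


def _check_same_leaves(t1: dendropy.Tree, t2: dendropy.Tree) -> None:
    l1, l2 = leaf_labels(t1), leaf_labels(t2)
    if l1 != l2:
        only1, only2 = sorted(l1 - l2), sorted(l2 - l1)
        raise ValueError(
            f"leaf sets differ: only in first {only1}, only in second {only2}"
        )


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Robinson-Foulds distance: |splits(t1) symmetric-difference splits(t2)|."""
    _check_same_leaves(t1, t2)
    return len(bipartitions(t1) ^ bipartitions(t2))


def normalized_rf(t1: dendropy.Tree, t2: dendropy.Tree) -> float:
    """RF distance divided by the total nontrivial split count of both trees.

    Defined as 0.0 when both trees are stars (no nontrivial splits).
    """
    _check_same_leaves(t1, t2)
    s1, s2 = bipartitions(t1), bipartitions(t2)
    denom = len(s1) + len(s2)
    if denom == 0:
        return 0.0
    return len(s1 ^ s2) / denom


def gene_to_target_nrf(gene_tree: dendropy.Tree,
                       target: dendropy.Tree) -> float:
    """nRF between a gene tree and the target tree pruned to its taxa.

    The target is pruned to the gene tree's leaf set and both trees are
    unrooted before comparison.  Requires >= 4 shared leaves (below that no
    nontrivial split exists and the distance is undefined).
    """
    gl, tl = leaf_labels(gene_tree), leaf_labels(target)
    if not gl <= tl:
        raise ValueError(
            f"gene tree labels absent from target: {sorted(gl - tl)}"
        )
    if len(gl) < 4:
        raise ValueError("need >= 4 shared leaves for a defined nRF")
    pruned = prune_taxa(target, gl)
    return normalized_rf(unroot(gene_tree), unroot(pruned))


def nj_tree(labels: Sequence[str], matrix: np.ndarray) -> dendropy.Tree:
    """Neighbor-joining tree from a symmetric distance matrix.

    Negative branch lengths produced by the agglomeration are clamped to 0.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj as _skbio_nj

    matrix = np.asarray(matrix, dtype=float)
    if len(labels) < 3:
        raise ValueError("need at least 3 labels")
    if matrix.shape != (len(labels), len(labels)):
        raise ValueError("matrix shape does not match labels")
    if not np.all(np.isfinite(matrix)):
        raise ValueError("distance matrix contains NaN/inf")
    if not np.allclose(matrix, matrix.T):
        raise ValueError("distance matrix is not symmetric")
    if np.any(np.diag(matrix) != 0):
        raise ValueError("distance matrix diagonal must be zero")
    if np.any(matrix < 0):
        raise ValueError("distances must be non-negative")
    skt = _skbio_nj(DistanceMatrix(matrix, list(labels)))
    tree = parse_newick(str(skt))
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
    return tree


_JC_MAX = 5.0  # distance assigned to saturated pairs (p >= 3/4)


def jc_distance_matrix(aln: Alignment) -> tuple[list[str], np.ndarray]:
    """Jukes-Cantor corrected pairwise distances from a nucleotide alignment.

    d = -(3/4) ln(1 - (4/3) p); saturated or incomparable pairs are capped at
    a large finite distance so NJ remains applicable.
    """
    n = aln.n_taxa
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = p_distance_pair(aln.rows[i], aln.rows[j])
            if math.isnan(p) or p >= 0.75:
                dij = _JC_MAX
            else:
                dij = min(-0.75 * math.log(1.0 - 4.0 * p / 3.0), _JC_MAX)
            d[i, j] = d[j, i] = dij
    return list(aln.taxa), d
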