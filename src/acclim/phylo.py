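"""Species-relatedness diagnostic for the meta-regression.

Separating phylogenetic from nonphylogenetic species-level variance is
only reliable when species in the data are, on average, reasonably
related: a mean off-diagonal relatedness below 0.2 makes the split
arbitrary.  This module parses a Newick tree over the analysed species,
imposes Grafen-style ultrametric branch lengths (node heights proportional
to the number of descendant tips minus one, normalized to unit depth),
builds the relatedness variance-covariance matrix (shared root-to-MRCA
path length), and evaluates that criterion.
"""

from __future__ import annotations


import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "parse_newick",
    "grafen_brlen",
    "relatedness_matrix",
    "mean_offdiag",
    "RELIABILITY_THRESHOLD",
]

#: mean off-diagonal relatedness below this makes phylogenetic vs
#: nonphylogenetic variance separation unreliable
RELIABILITY_THRESHOLD = 0.2


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string into a rooted tree; polytomies are allowed."""
    try:
        tree = dendropy.Tree.get(data=text, schema="newick")
    except Exception as err:
        raise ValueError(f"Newick parse error: {err}") from err
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()
              if leaf.taxon is not None]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate tip labels in tree: {dupes}")
    return tree


def grafen_brlen(tree: dendropy.Tree, rho: float = 1.0) -> dendropy.Tree:
    """Assign Grafen branch lengths: ultrametric with root-to-tip depth 1.

    Each node's height is ((number of descendant tips - 1)/(n_tips - 1))**rho;
    tips sit at height 0 and each branch length is the height difference
    between parent and child.
    """
    tree = tree.clone(depth=1)
    n_tips = len(tree.leaf_nodes())
    if n_tips < 2:
        raise ValueError("Grafen branch lengths need at least 2 tips")
    heights: dict[int, float] = {}
    for node in tree.postorder_node_iter():
        k = len(node.leaf_nodes()) if not node.is_leaf() else 1
        heights[id(node)] = ((k - 1) / (n_tips - 1)) ** rho if k > 1 else 0.0
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            node.edge.length = None
        else:
            node.edge.length = heights[id(node.parent_node)] - heights[id(node)]
    return tree


def _tip_depths(tree: dendropy.Tree) -> dict[str, float]:
    depths = {}
    for leaf in tree.leaf_node_iter():
        d = 0.0
        node = leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        depths[leaf.taxon.label] = d
    return depths


def relatedness_matrix(tree: dendropy.Tree, atol: float = 1e-8) -> pd.DataFrame:
    """Species relatedness matrix from an ultrametric, depth-1 tree.

    Entry (i, j) is the shared root-to-MRCA path length; the diagonal is 1.
    """
    depths = _tip_depths(tree)
    labels = sorted(depths)
    depth_vals = np.array([depths[l] for l in labels])
    if depth_vals.size < 2:
        raise ValueError("need at least 2 tips")
    depth = float(depth_vals.mean())
    if depth <= 0 or np.max(np.abs(depth_vals - depth)) > atol * max(depth, 1.0):
        raise ValueError("tree is not ultrametric; apply grafen_brlen first")

    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    m = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            dist = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
            # shared path = depth - height(MRCA) = depth - dist/2, scaled to 1
            m[i, j] = m[j, i] = (depth - dist / 2.0) / depth
    return pd.DataFrame(m, index=labels, columns=labels)


def mean_offdiag(m: pd.DataFrame) -> tuple[float, bool]:
    """Mean of the strictly off-diagonal relatedness entries and its verdict.

    The flag is True when the mean is at least 0.2, i.e., when separately
    estimating phylogenetic and nonphylogenetic species variances would be
    considered reliable.
    """
    a = np.asarray(m, float)
    n = a.shape[0]
    if a.ndim != 2 or a.shape[1] != n:
        raise ValueError("relatedness matrix must be square")
    if n < 2:
        raise ValueError("need at least a 2x2 matrix")
    off = a[~np.eye(n, dtype=bool)]
    value = float(off.mean())
    return value, value >= RELIABILITY_THRESHOLD
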