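"""Tree helpers: patristic distance matrices and root-to-tip depths.

Patristic distances are assembled in a single postorder pass: at each
internal node the tip-pair distances across its child clades are
``depth_i + depth_j - 2 * depth_node``, filled with numpy outer sums.  This is
O(n^2) overall and fast enough for trees with thousands of tips, unlike a
per-pair path walk.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import dendropy

__all__ = ["patristic_matrix", "tip_depths"]


def _edge_len(node) -> float:
    return node.edge.length if node.edge.length is not None else 0.0


def tip_depths(tree: dendropy.Tree) -> pd.Series:
    """Root-to-tip path lengths, indexed by tip label."""
    depth = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        d = (depth[id(parent)] if parent is not None else 0.0) + (
            _edge_len(node) if parent is not None else 0.0
        )
        depth[id(node)] = d
    out = {
        leaf.taxon.label: depth[id(leaf)] for leaf in tree.leaf_node_iter()
    }
    return pd.Series(out, dtype=float)


def patristic_matrix(tree: dendropy.Tree, taxon_order=None) -> pd.DataFrame:
    """Symmetric patristic (branch-length path) distance matrix between tips.

    Parameters
    ----------
    tree :
        Rooted tree with branch lengths.
    taxon_order :
        Optional tip-label ordering for the result; every requested label
        must be a tip of the tree.
    """
    leaves = list(tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    index = {id(lf): i for i, lf in enumerate(leaves)}
    n = len(leaves)

    depth = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        depth[id(node)] = (
            0.0 if parent is None else depth[id(parent)] + _edge_len(node)
        )
    tipdepth = np.array([depth[id(lf)] for lf in leaves])

    D = np.zeros((n, n))
    below = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = np.array([index[id(node)]])
            continue
        kids = [below.pop(id(c)) for c in node.child_nodes()]
        for a in range(len(kids)):
            for b in range(a + 1, len(kids)):
                ia, ib = kids[a], kids[b]
                d = (
                    tipdepth[ia][:, None]
                    + tipdepth[ib][None, :]
                    - 2.0 * depth[id(node)]
                )
                D[np.ix_(ia, ib)] = d
                D[np.ix_(ib, ia)] = d.T
        below[id(node)] = np.concatenate(kids)

    df = pd.DataFrame(D, index=labels, columns=labels)
    if taxon_order is not None:
        missing = set(taxon_order) - set(labels)
        if missing:
            raise ValueError(f"taxa absent from tree: {sorted(missing)}")
        df = df.loc[list(taxon_order), list(taxon_order)]
    return df
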