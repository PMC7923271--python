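"""Clustering of CBC dissimilarities and congruence with a phylogeny.

A hierarchical clustering of pairwise compensatory-change counts is
compared against an independently estimated species tree with Baker's
gamma: for every unordered leaf pair, rank the depth at which the pair
coalesces in each tree and take the Spearman correlation of the two rank
vectors.  Gamma is 1 for topologically identical hierarchies and is
invariant to monotone transformations of merge heights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

from .ancestry import RootedTree, TreeNode

__all__ = ["Dendrogram", "hierarchical_cluster", "bakers_gamma", "tanglegram_export"]


@dataclass
class Dendrogram:
    """Agglomerative merge tree: scipy linkage matrix plus leaf labels."""
    linkage: np.ndarray
    labels: list[str]

    def cophenetic(self) -> pd.DataFrame:
        d = squareform(hierarchy.cophenet(self.linkage))
        return pd.DataFrame(d, index=self.labels, columns=self.labels)

    def merge_rank_matrix(self) -> pd.DataFrame:
        """For each leaf pair, the merge step (0-based) at which they join."""
        n = len(self.labels)
        member: dict[int, list[int]] = {i: [i] for i in range(n)}
        out = np.zeros((n, n))
        for step, (a, b, _h, _c) in enumerate(self.linkage):
            ma, mb = member.pop(int(a)), member.pop(int(b))
            for x in ma:
                for y in mb:
                    out[x, y] = out[y, x] = step
            member[n + step] = ma + mb
        return pd.DataFrame(out, index=self.labels, columns=self.labels)


def hierarchical_cluster(matrix: pd.DataFrame, linkage: str = "complete",
                         similarity: bool = False) -> Dendrogram:
    """Agglomerative clustering of a symmetric matrix.

    With ``similarity=True`` the matrix is converted to a dissimilarity as
    max(matrix) - value before clustering (the convention used for
    compensatory-change *occurrence* matrices, which are similarity-like).
    """
    if linkage not in ("complete", "average", "single"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    labels = [str(x) for x in matrix.index]
    m = matrix.to_numpy(dtype=float)
    if m.shape[0] != m.shape[1] or not np.allclose(m, m.T, equal_nan=True):
        raise ValueError("matrix must be square and symmetric")
    if similarity:
        m = m.max() - m
    np.fill_diagonal(m, 0.0)
    z = hierarchy.linkage(squareform(m, checks=False), method=linkage)
    return Dendrogram(linkage=z, labels=labels)


def _tree_pair_depths(tree: RootedTree, labels: list[str]) -> np.ndarray:
    """LCA depth (internal nodes on the root path) for each leaf pair."""
    n = len(labels)
    out = np.zeros(n * (n - 1) // 2)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            out[k] = tree.node_depth(tree.lca(labels[i], labels[j]))
            k += 1
    return out


def _pair_vector(obj: Union[Dendrogram, RootedTree], labels: list[str]) -> np.ndarray:
    """Per-pair coalescence ranks, oriented so larger = merges closer to tips."""
    n = len(labels)
    if isinstance(obj, Dendrogram):
        mr = obj.merge_rank_matrix().loc[labels, labels].to_numpy()
        vec = np.array([mr[i, j] for i in range(n) for j in range(i + 1, n)])
        return -vec  # earlier merge = closer to the tips
    return _tree_pair_depths(obj, labels)


def bakers_gamma(d1: Union[Dendrogram, RootedTree],
                 d2: Union[Dendrogram, RootedTree]) -> float:
    """Baker's gamma between two hierarchies over the same leaf set.

    Spearman rank correlation (average ranks for ties) of the per-pair
    coalescence depths.
    """
    l1 = set(d1.labels if isinstance(d1, Dendrogram) else d1.leaf_labels())
    l2 = set(d2.labels if isinstance(d2, Dendrogram) else d2.leaf_labels())
    if l1 != l2:
        raise ValueError("leaf sets differ between the two hierarchies")
    labels = sorted(l1)
    v1 = _pair_vector(d1, labels)
    v2 = _pair_vector(d2, labels)
    rho = spearmanr(v1, v2).statistic
    return float(rho)


# ---------------------------------------------------------------------------
# tanglegram

def _to_nested(obj: Union[Dendrogram, RootedTree]):
    """Convert either hierarchy into a nested list-of-lists over leaf labels."""
    if isinstance(obj, RootedTree):
        def rec_t(n: TreeNode):
            if n.is_leaf:
                return n.id
            return [rec_t(c) for c in n.children]
        return rec_t(obj.root)
    node, _ = hierarchy.to_tree(obj.linkage, rd=False), None

    def rec(nd):
        if nd.is_leaf():
            return obj.labels[nd.id]
        return [rec(nd.left), rec(nd.right)]

    return rec(node)


def _leaf_order(nested) -> list[str]:
    if isinstance(nested, str):
        return [nested]
    out = []
    for child in nested:
        out.extend(_leaf_order(child))
    return out


def _internal_nodes(nested, path=()):
    if isinstance(nested, str):
        return
    yield path
    for k, child in enumerate(nested):
        yield from _internal_nodes(child, path + (k,))


def _flip(nested, path):
    if not path:
        return list(reversed(nested))
    out = list(nested)
    out[path[0]] = _flip(out[path[0]], path[1:])
    return out


def _crossings(left: list[str], right: list[str]) -> int:
    pos = {t: i for i, t in enumerate(right)}
    seq = [pos[t] for t in left]
    n = 0
    for i in range(len(seq)):
        for j in range(i + 1, len(seq)):
            if seq[i] > seq[j]:
                n += 1
    return n


def tanglegram_export(d1: Union[Dendrogram, RootedTree],
                      d2: Union[Dendrogram, RootedTree]) -> tuple[pd.DataFrame, int]:
    """Leaf matching table and crossing count after greedy untangling.

    Internal nodes of both hierarchies are flipped greedily (first
    improving flip, repeated to a fixed point) to reduce line crossings.
    Returns (table with columns taxon/left_position/right_position,
    crossing count).
    """
    t1, t2 = _to_nested(d1), _to_nested(d2)
    if set(_leaf_order(t1)) != set(_leaf_order(t2)):
        raise ValueError("leaf sets differ between the two hierarchies")
    improved = True
    best = _crossings(_leaf_order(t1), _leaf_order(t2))
    while improved and best > 0:
        improved = False
        for which in (0, 1):
            tree = t1 if which == 0 else t2
            for path in list(_internal_nodes(tree)):
                cand = _flip(tree, path)
                c1, c2 = (cand, t2) if which == 0 else (t1, cand)
                score = _crossings(_leaf_order(c1), _leaf_order(c2))
                if score < best:
                    best = score
                    if which == 0:
                        t1 = cand
                    else:
                        t2 = cand
                    improved = True
    left, right = _leaf_order(t1), _leaf_order(t2)
    rpos = {t: i for i, t in enumerate(right)}
    table = pd.DataFrame({
        "taxon": left,
        "left_position": range(len(left)),
        "right_position": [rpos[t] for t in left],
    })
    return table, best
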