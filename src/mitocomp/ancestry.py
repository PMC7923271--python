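"""Rooted trees and Fitch parsimony ancestral reconstruction.

Ancestral states are assigned on a fixed topology by the two-pass Fitch
algorithm with uniform substitution cost and the alignment gap treated as
a fifth character state (so indels are reconstructed and countable).
Ties at the root are broken by a fixed alphabet order (A < C < G < T/U <
gap), which makes the reconstruction fully deterministic.  This
parsimony reconstruction is adequate at the shallow within-genus
divergences the package targets; at high divergence it undercounts
changes, which the synthetic-data tests quantify.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import dendropy
import pandas as pd

__all__ = [
    "TreeNode",
    "RootedTree",
    "AncestralAlignment",
    "read_newick",
    "fitch_ancestral",
    "branch_substitutions",
]

# fixed tie-break order; characters not listed sort after, alphabetically
_ALPHA_ORDER = {c: i for i, c in enumerate("ACGTU-")}


def _state_key(c: str):
    return (_ALPHA_ORDER.get(c, len(_ALPHA_ORDER)), c)


@dataclass
class TreeNode:
    id: str
    children: list["TreeNode"] = field(default_factory=list)
    parent: Optional["TreeNode"] = None
    length: Optional[float] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children


class RootedTree:
    """A rooted tree with uniquely labelled leaves and stable internal ids.

    Internal nodes get deterministic ids N1, N2, ... in preorder (the root
    is N1) unless the source newick labels them.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        labels = [n.id for n in self.leaves()]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate leaf labels")

    # -- traversal ---------------------------------------------------------
    def preorder(self) -> Iterable[TreeNode]:
        stack = [self.root]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(reversed(n.children))

    def postorder(self) -> Iterable[TreeNode]:
        out = list(self.preorder())
        return reversed(out)

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.id for n in self.leaves()]

    def nodes(self) -> list[TreeNode]:
        return list(self.preorder())

    def branch_class(self, node: TreeNode) -> str:
        """'external' when the child end of the branch is a leaf."""
        return "external" if node.is_leaf else "internal"

    def node_depth(self, node: TreeNode) -> int:
        """Number of internal nodes strictly above, i.e. edges to the root."""
        d = 0
        while node.parent is not None:
            node = node.parent
            d += 1
        return d

    def lca(self, a: str, b: str) -> TreeNode:
        by_id = {n.id: n for n in self.preorder()}
        anc = set()
        n = by_id[a]
        while n is not None:
            anc.add(id(n))
            n = n.parent
        n = by_id[b]
        while n is not None:
            if id(n) in anc:
                return n
            n = n.parent
        raise ValueError("disconnected nodes")  # pragma: no cover

    # -- newick ------------------------------------------------------------
    def to_newick(self) -> str:
        def rec(n: TreeNode) -> str:
            ln = "" if n.length is None else f":{n.length:g}"
            if n.is_leaf:
                return f"{n.id}{ln}"
            return "(" + ",".join(rec(c) for c in n.children) + ")" + (n.id or "") + ln

        return rec(self.root) + ";"

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "RootedTree":
        counter = [0]

        def conv(dn) -> TreeNode:
            if dn.is_leaf():
                name = dn.taxon.label if dn.taxon else (dn.label or "?")
                node = TreeNode(id=name.replace(" ", "_"))
            else:
                counter[0] += 1
                node = TreeNode(id=dn.label or f"N{counter[0]}")
            node.length = dn.edge.length
            for c in dn.child_nodes():
                ch = conv(c)
                ch.parent = node
                node.children.append(ch)
            return node

        return cls(conv(tree.seed_node))


def read_newick(text_or_path, outgroup: Optional[str] = None) -> RootedTree:
    """Parse newick text (or a file path) into a RootedTree.

    With ``outgroup`` the tree is rerooted so the named taxon branches off
    adjacent to the root.
    """
    text = str(text_or_path)
    if "(" not in text:  # path
        with open(text) as fh:
            text = fh.read()
    tree = dendropy.Tree.get(data=text, schema="newick")
    if outgroup is not None:
        taxon = None
        for t in tree.taxon_namespace:
            if t.label.replace(" ", "_") == outgroup.replace(" ", "_"):
                taxon = t
                break
        if taxon is None:
            raise ValueError(f"outgroup {outgroup!r} not in tree")
        node = tree.find_node_with_taxon_label(taxon.label)
        tree.to_outgroup_position(node, update_bipartitions=False)
    return RootedTree.from_dendropy(tree)


# ---------------------------------------------------------------------------
# Fitch

@dataclass
class AncestralAlignment:
    """Leaf alignment extended with reconstructed internal-node rows."""
    sequences: dict[str, str]      # leaf labels + internal node ids
    scores: list[int]              # per-column parsimony score
    tree: RootedTree

    @property
    def n_columns(self) -> int:
        return len(self.scores)

    def total_score(self) -> int:
        return sum(self.scores)


def fitch_ancestral(alignment: dict[str, str], tree: RootedTree) -> AncestralAlignment:
    """Two-pass Fitch reconstruction over a five-state alphabet.

    Bottom-up: leaf sets are singletons; an internal set is the
    intersection of its children's sets when non-empty, else the union
    (each union costs one change).  Top-down: a child keeps the parent
    state when possible, else takes the first state of its own set in
    alphabet order.  A root tie prefers states shared with the root's
    leftmost child, then alphabet order: a purely alphabetical root
    tie-break would resolve the two columns of a paired stem site toward
    different root children, systematically splitting one compensatory
    double change into two apparent single changes; preferring one fixed
    child keeps co-occurring changes on a single branch while remaining
    fully deterministic.
    """
    leaves = tree.leaf_labels()
    missing = [l for l in leaves if l not in alignment]
    if missing:
        raise ValueError(f"alignment missing leaf rows: {missing}")
    lengths = {len(alignment[l]) for l in leaves}
    if len(lengths) != 1:
        raise ValueError("alignment rows have unequal lengths")
    ncol = lengths.pop()

    nodes = list(tree.postorder())
    recon: dict[str, list[str]] = {n.id: [] for n in tree.preorder()}
    scores: list[int] = []

    for col in range(ncol):
        sets: dict[str, frozenset] = {}
        score = 0
        for n in nodes:
            if n.is_leaf:
                sets[n.id] = frozenset(alignment[n.id][col].upper())
            else:
                # multifurcations handled pairwise left-to-right
                acc = sets[n.children[0].id]
                for c in n.children[1:]:
                    nxt = acc & sets[c.id]
                    if nxt:
                        acc = nxt
                    else:
                        acc = acc | sets[c.id]
                        score += 1
                sets[n.id] = acc
        scores.append(score)
        # top-down
        for n in tree.preorder():
            if n.parent is None:
                pref = sets[n.id] & sets[n.children[0].id] if n.children else sets[n.id]
                state = min(pref if pref else sets[n.id], key=_state_key)
            else:
                pstate = recon[n.parent.id][col]
                state = pstate if pstate in sets[n.id] else min(sets[n.id], key=_state_key)
            recon[n.id].append(state)

    seqs = {nid: "".join(chars) for nid, chars in recon.items()}
    return AncestralAlignment(sequences=seqs, scores=scores, tree=tree)


def branch_substitutions(aa: AncestralAlignment, tree: Optional[RootedTree] = None) -> pd.DataFrame:
    """One record per (branch, column) where parent and child states differ.

    Changes to or from the gap state are flagged as indels.  The branch is
    identified by its child node id; the root has no branch.
    """
    tree = tree or aa.tree
    rows = []
    for n in tree.preorder():
        if n.parent is None:
            continue
        p, c = aa.sequences[n.parent.id], aa.sequences[n.id]
        for col in range(aa.n_columns):
            if p[col] != c[col]:
                rows.append({
                    "branch": n.id,
                    "branch_class": tree.branch_class(n),
                    "site": col,
                    "parent_state": p[col],
                    "child_state": c[col],
                    "is_indel": "-" in (p[col], c[col]),
                })
    return pd.DataFrame(rows, columns=["branch", "branch_class", "site",
                                       "parent_state", "child_state", "is_indel"])
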