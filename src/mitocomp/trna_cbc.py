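"""Cloverleaf stem maps and compensatory base-change classification.

tRNA stems hold paired sites; of the 16 possible base duples only six are
stable (the Watson-Crick pairs AU, UA, GC, CG and the wobble pairs GU,
UG).  A change at a paired site between a parent and child sequence is a
full compensatory base change (FCBC) when both bases changed, a
hemi-compensatory change (HCBC) when exactly one changed, and an indel
event when a gap is involved; subtypes record whether the outcome is
Watson-Crick, wobble, or a mismatch.  Tallies are split by tRNA arm and
by internal versus external branch of the reconstruction tree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .ancestry import AncestralAlignment, RootedTree
from .composition import BaseStats, base_stats

__all__ = [
    "WATSON_CRICK",
    "WOBBLE",
    "STABLE_PAIRS",
    "CloverleafMap",
    "pair_class",
    "classify_pair_change",
    "build_consensus_structure",
    "tally_cbc",
    "pairwise_cbc_matrix",
    "stem_loop_stats",
    "DEFAULT_EXCLUDED_TRNAS",
]

WATSON_CRICK = frozenset(["AU", "UA", "GC", "CG"])
WOBBLE = frozenset(["GU", "UG"])
#: the six stable pairings out of the sixteen possible
STABLE_PAIRS = WATSON_CRICK | WOBBLE

#: tRNAs adjacent to repeat-rich control regions are frequently
#: unrecoverable across taxa and are excluded from cross-species tallies
DEFAULT_EXCLUDED_TRNAS = ("trnC", "trnY", "trnM")

ARMS = ("acceptor", "D", "anticodon", "T")


def _norm(base: str) -> str:
    b = base.upper()
    return "U" if b == "T" else b


def pair_class(duple: str) -> str:
    """Stability class of an ordered base duple: WC, wobble, mismatch, gapped."""
    d = _norm(duple[0]) + _norm(duple[1])
    if "-" in d:
        return "gapped"
    if d in WATSON_CRICK:
        return "WC"
    if d in WOBBLE:
        return "wobble"
    return "mismatch"


@dataclass
class CloverleafMap:
    """Paired-column stem map of one tRNA family over its alignment.

    ``pairs`` lists aligned column pairs (i, j, arm) with i < j.  The
    acceptor stem always holds 7 pairs and the anticodon stem 5 (enforced
    even across mismatches); D- and T-arms carry 0-4 pairs and may be
    absent entirely.
    """

    trna: str
    pairs: list[tuple[int, int, str]]
    anticodon_cols: Optional[tuple[int, int, int]] = None
    d_arm: bool = True
    t_arm: bool = True

    def __post_init__(self) -> None:
        seen = set()
        for i, j, arm in self.pairs:
            if arm not in ARMS:
                raise ValueError(f"unknown arm {arm!r}")
            if i >= j:
                raise ValueError(f"pair columns must satisfy i < j: ({i}, {j})")
            if i in seen or j in seen:
                raise ValueError(f"column appears in two pairs: ({i}, {j})")
            seen.update((i, j))
        counts = self.arm_pair_counts()
        if counts["acceptor"] != 7:
            raise ValueError(f"acceptor stem must have 7 pairs, got {counts['acceptor']}")
        if counts["anticodon"] != 5:
            raise ValueError(f"anticodon stem must have 5 pairs, got {counts['anticodon']}")
        for arm in ("D", "T"):
            if counts[arm] > 4:
                raise ValueError(f"{arm}-arm may have at most 4 pairs")

    def arm_pair_counts(self) -> dict[str, int]:
        c = {a: 0 for a in ARMS}
        for _, _, arm in self.pairs:
            c[arm] += 1
        return c

    def paired_columns(self) -> set[int]:
        return {i for i, _, _ in self.pairs} | {j for _, j, _ in self.pairs}

    def max_column(self) -> int:
        return max(max(i, j) for i, j, _ in self.pairs)


def build_consensus_structure(alignment: Mapping[str, str],
                              template: CloverleafMap) -> CloverleafMap:
    """Majority-rule (50%) consensus structure for one tRNA family.

    The template fixes the arm layout on the alignment's columns.
    Acceptor and anticodon stems are kept at their template positions
    unconditionally; each candidate D-/T-arm pair is retained only when at
    least half of the sequences have both of its positions ungapped, and
    an arm is marked absent when no pair survives.
    """
    seqs = list(alignment.values())
    if not seqs:
        raise ValueError("empty alignment")
    ncol = len(seqs[0])
    if template.max_column() >= ncol:
        raise ValueError("alignment shorter than the template's forced stems")
    half = len(seqs) / 2.0
    pairs = []
    kept = {"D": 0, "T": 0}
    for i, j, arm in template.pairs:
        if arm in ("acceptor", "anticodon"):
            pairs.append((i, j, arm))
            continue
        n_ok = sum(1 for s in seqs if s[i] != "-" and s[j] != "-")
        if n_ok >= half:
            pairs.append((i, j, arm))
            kept[arm] += 1
    return CloverleafMap(
        trna=template.trna,
        pairs=pairs,
        anticodon_cols=template.anticodon_cols,
        d_arm=kept["D"] > 0,
        t_arm=kept["T"] > 0,
    )


# ---------------------------------------------------------------------------
# change classification

def classify_pair_change(parent: str, child: str) -> tuple[str, str, str]:
    """Classify one stem-pair change: (category, subtype, substitution type).

    Categories: FCBC (both bases changed, no gaps), HCBC (one base
    changed, no gaps), indel (any gap involved), none (no change).  FCBC
    subtypes distinguish Watson-Crick switches from stability gains and
    losses; HCBC subtypes record the resulting pair class.  Substitution
    types are rendered as "AU -> GC" (FCBC) and "A -> G vs U" (HCBC).
    """
    p = _norm(parent[0]) + _norm(parent[1])
    c = _norm(child[0]) + _norm(child[1])
    if p == c:
        return ("none", "", "")
    if "-" in p or "-" in c:
        if "-" in p and "-" not in c:
            sub = "gap_loss"
        elif "-" not in p and "-" in c:
            sub = "gap_gain"
        else:
            sub = "gap_change"
        return ("indel", sub, f"{p} -> {c}")
    changed = [k for k in (0, 1) if p[k] != c[k]]
    pc, cc = pair_class(p), pair_class(c)
    if len(changed) == 2:
        if pc == "WC" and cc == "WC":
            sub = "wc_switch"
        elif pc in ("WC", "wobble") and cc in ("WC", "wobble"):
            sub = "stable_switch"
        elif pc == "mismatch" and cc in ("WC", "wobble"):
            sub = "mismatch_to_match"
        elif pc in ("WC", "wobble") and cc == "mismatch":
            sub = "match_to_mismatch"
        else:
            sub = "mismatch_to_mismatch"
        return ("FCBC", sub, f"{p} -> {c}")
    k = changed[0]
    partner = c[1 - k]
    sub = {"WC": "result_wc", "wobble": "result_wobble", "mismatch": "result_mismatch"}[cc]
    return ("HCBC", sub, f"{p[k]} -> {c[k]} vs {partner}")


# ---------------------------------------------------------------------------
# tallies over a reconstruction

@dataclass
class CBCTallies:
    """Per-branch classified stem-pair changes plus loop-change counts."""
    records: pd.DataFrame        # one row per changed stem pair per branch
    loop_changes: pd.DataFrame   # per-branch-class loop substitution/indel counts

    def by_category(self) -> pd.DataFrame:
        if self.records.empty:
            return pd.DataFrame()
        t = self.records.pivot_table(index="category", columns="branch_class",
                                     values="trna", aggfunc="count", fill_value=0)
        t["total"] = t.sum(axis=1)
        return t

    def by_arm(self, category: Optional[str] = None) -> pd.DataFrame:
        df = self.records
        if category is not None:
            df = df[df["category"] == category]
        if df.empty:
            return pd.DataFrame()
        return df.pivot_table(index="arm", columns="branch_class",
                              values="trna", aggfunc="count", fill_value=0)

    def by_type(self, category: str = "FCBC") -> pd.DataFrame:
        df = self.records[self.records["category"] == category]
        if df.empty:
            return pd.DataFrame()
        return df.pivot_table(index="subst_type", columns="branch_class",
                              values="trna", aggfunc="count", fill_value=0)

    def stem_change_total(self) -> int:
        """Events; one FCBC counts once (changes = 2 x FCBC + HCBC...)."""
        return len(self.records)

    def change_count(self) -> int:
        """Base changes: FCBC contributes two, HCBC/indel/other one."""
        if self.records.empty:
            return 0
        return int((self.records["category"] == "FCBC").sum()) + len(self.records)


def tally_cbc(ancestral: Mapping[str, AncestralAlignment],
              maps: Mapping[str, CloverleafMap],
              tree: Optional[RootedTree] = None,
              exclude: Sequence[str] = ()) -> CBCTallies:
    """Classify every stem-pair change on every branch, once.

    ``ancestral`` and ``maps`` are keyed by tRNA token.  Changes at
    unpaired (loop) columns are counted separately.  Gap-involving pair
    changes are indels and never FCBC/HCBC; a pair with both a gap event
    and a base change counts once, as an indel.
    """
    rows = []
    loop_rows = []
    for trna, aa in ancestral.items():
        if trna in exclude or trna not in maps:
            continue
        cmap = maps[trna]
        t = tree or aa.tree
        paired = cmap.paired_columns()
        loop_cols = [k for k in range(aa.n_columns) if k not in paired]
        if cmap.max_column() >= aa.n_columns:
            raise ValueError(f"{trna}: structure map exceeds alignment width")
        for n in t.preorder():
            if n.parent is None:
                continue
            pseq, cseq = aa.sequences[n.parent.id], aa.sequences[n.id]
            bclass = t.branch_class(n)
            for i, j, arm in cmap.pairs:
                cat, sub, typ = classify_pair_change(pseq[i] + pseq[j], cseq[i] + cseq[j])
                if cat == "none":
                    continue
                rows.append({
                    "trna": trna, "branch": n.id, "branch_class": bclass,
                    "arm": arm, "col_i": i, "col_j": j,
                    "parent_pair": _norm(pseq[i]) + _norm(pseq[j]),
                    "child_pair": _norm(cseq[i]) + _norm(cseq[j]),
                    "category": cat, "subtype": sub, "subst_type": typ,
                })
            n_sub = n_indel = 0
            for k in loop_cols:
                if pseq[k] != cseq[k]:
                    if "-" in (pseq[k], cseq[k]):
                        n_indel += 1
                    else:
                        n_sub += 1
            if n_sub or n_indel:
                loop_rows.append({"trna": trna, "branch": n.id, "branch_class": bclass,
                                  "substitutions": n_sub, "indels": n_indel})
    rec_cols = ["trna", "branch", "branch_class", "arm", "col_i", "col_j",
                "parent_pair", "child_pair", "category", "subtype", "subst_type"]
    loop_cols_ = ["trna", "branch", "branch_class", "substitutions", "indels"]
    return CBCTallies(
        records=pd.DataFrame(rows, columns=rec_cols),
        loop_changes=pd.DataFrame(loop_rows, columns=loop_cols_),
    )


# ---------------------------------------------------------------------------
# tree-free pairwise matrix

def pairwise_cbc_matrix(alignments: Mapping[str, Mapping[str, str]],
                        maps: Mapping[str, CloverleafMap],
                        fcbc_only: bool = True,
                        exclude: Sequence[str] = DEFAULT_EXCLUDED_TRNAS) -> pd.DataFrame:
    """Symmetric taxon-by-taxon matrix of pairwise compensatory changes.

    For every taxon pair and paired column: with ``fcbc_only`` a site
    counts when both positions differ and both duples are stable pairs
    (no gaps); otherwise any difference between two stable duples counts.
    Summed over the non-excluded tRNA families.
    """
    taxa = sorted(set.intersection(*[set(a) for t, a in alignments.items()
                                     if t not in exclude])) if alignments else []
    m = pd.DataFrame(0, index=taxa, columns=taxa, dtype=int)
    for trna, aln in alignments.items():
        if trna in exclude or trna not in maps:
            continue
        cmap = maps[trna]
        for xi, tx in enumerate(taxa):
            for ty in taxa[xi + 1:]:
                sx, sy = aln[tx], aln[ty]
                n = 0
                for i, j, _ in cmap.pairs:
                    dx = _norm(sx[i]) + _norm(sx[j])
                    dy = _norm(sy[i]) + _norm(sy[j])
                    if dx == dy or dx not in STABLE_PAIRS or dy not in STABLE_PAIRS:
                        continue
                    both_changed = dx[0] != dy[0] and dx[1] != dy[1]
                    if both_changed or not fcbc_only:
                        n += 1
                m.loc[tx, ty] += n
                m.loc[ty, tx] += n
    return m


def stem_loop_stats(alignments: Mapping[str, Mapping[str, str]],
                    maps: Mapping[str, CloverleafMap]) -> tuple[BaseStats, BaseStats]:
    """Pooled composition over paired (stem) vs unpaired (loop) columns.

    Gaps are excluded from the counts (base_stats ignores non-ACGT).
    """
    stem_chars, loop_chars = [], []
    for trna, aln in alignments.items():
        if trna not in maps:
            continue
        paired = maps[trna].paired_columns()
        for seq in aln.values():
            for k, ch in enumerate(seq):
                (stem_chars if k in paired else loop_chars).append(ch)
    return base_stats("".join(stem_chars)), base_stats("".join(loop_chars))
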