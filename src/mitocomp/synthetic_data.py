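"""Synthetic mitogenomic data with logged ground truth.

Every analysis stage in this package is exercised against data simulated
here: a Yule tree, tRNA alignments whose stem pairs evolve as 25-state
duples under explicit compensatory/hemi-compensatory/mismatch/indel
events, codon sequences with controlled third-position composition and
strand skews, annotated toy mitogenomes, and gene orders scrambled by
known rearrangement events.  All randomness flows from the single seed
in :class:`SimConfig`, and every applied event is logged so pipeline
output can be compared against the generating truth.

Default parameters mirror the compositional regime reported for
amphipod mitogenomes: ~16 taxa, shallow divergence, third-codon-position
A+T around 72% with negative AT-skew and positive GC-skew on the plus
strand, AT-rich loops (~78%) versus stems (~66%), and a two-event
rearrangement between gene orders.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .ancestry import RootedTree, TreeNode
from .gene_order import RearrangementEvent, SignedGeneOrder, apply_event
from .genome_io import GeneFeature, Mitogenome, PCG_TOKENS
from .trna_cbc import (CloverleafMap, STABLE_PAIRS, WATSON_CRICK,
                       classify_pair_change)

__all__ = [
    "SimConfig",
    "TruthLog",
    "simulate_tree",
    "default_trna_template",
    "simulate_trna",
    "simulate_cds",
    "evolve_cds",
    "generate_toy_mitogenome",
    "scramble_gene_order",
    "DEFAULT_GENE_ORDER",
]

#: realistic per-gene lengths (nt, codon multiples) for the 13 PCGs
DEFAULT_GENE_LENGTHS = {
    "cox1": 1536, "cox2": 687, "cox3": 789, "cob": 1137,
    "nad1": 936, "nad2": 978, "nad3": 351, "nad4": 1338, "nad4L": 297,
    "nad5": 1719, "nad6": 501, "atp6": 675, "atp8": 159,
}

#: the ancestral pancrustacean arrangement (sign = coding strand)
DEFAULT_GENE_ORDER = (
    ("cox1", 1), ("trnL2", 1), ("cox2", 1), ("trnK", 1), ("trnD", 1),
    ("atp8", 1), ("atp6", 1), ("cox3", 1), ("trnG", 1), ("nad3", 1),
    ("trnA", 1), ("trnR", 1), ("trnN", 1), ("trnS1", 1), ("trnE", 1),
    ("trnF", -1), ("nad5", -1), ("trnH", -1), ("nad4", -1), ("nad4L", -1),
    ("trnT", 1), ("trnP", -1), ("nad6", 1), ("cob", 1), ("trnS2", 1),
    ("nad1", -1), ("trnL1", -1), ("rrnL", -1), ("trnV", -1), ("rrnS", -1),
    ("CR1", 1), ("trnI", 1), ("trnQ", -1), ("trnM", 1), ("nad2", 1),
    ("trnW", 1), ("CR2", 1), ("trnC", -1), ("trnY", -1),
)


@dataclass
class SimConfig:
    """All simulation knobs; the seed fixes every random stream."""
    seed: int = 1
    # tree
    n_taxa: int = 16
    birth_rate: float = 1.0
    tree_depth: float = 0.08           # root-to-tip; the validated low-divergence regime
    # tRNA stems (events per pair per unit branch length)
    fcbc_rate: float = 0.4
    hcbc_rate: float = 0.8
    mismatch_rate: float = 0.15
    indel_rate: float = 0.03
    stem_at: float = 0.66              # A+U fraction among root stem pairs
    # tRNA loops
    loop_rate: float = 1.2
    loop_at_bias: float = 0.78         # P(new loop base is A or U)
    # codon model
    gc3: float = 0.28
    at_skew3: float = -0.17
    gc_skew3: float = 0.135
    at12: float = 0.62                 # A+T content of codon positions 1-2
    gene_lengths: dict = field(default_factory=lambda: dict(DEFAULT_GENE_LENGTHS))
    # gene-order scrambling
    n_order_events: int = 2
    order_event_kinds: tuple = ("reverse_transposition", "reversal")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class TruthLog:
    """Everything needed to replay or verify a simulation."""
    stem_events: list = field(default_factory=list)
    loop_events: list = field(default_factory=list)
    order_events: list = field(default_factory=list)
    cds_events: list = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def stem_event_count(self, category: Optional[str] = None) -> int:
        if category is None:
            return len(self.stem_events)
        return sum(1 for e in self.stem_events if e["category"] == category)


# ---------------------------------------------------------------------------
# tree

def simulate_tree(cfg: SimConfig, rng: Optional[np.random.Generator] = None) -> RootedTree:
    """Yule (pure-birth) tree on cfg.n_taxa leaves, scaled to cfg.tree_depth."""
    if cfg.n_taxa < 2:
        raise ValueError("need at least two taxa")
    rng = rng or cfg.rng()
    width = len(str(cfg.n_taxa))
    root = TreeNode(id="N1")
    a, b = TreeNode(id="L0", parent=root, length=0.0), TreeNode(id="L1", parent=root, length=0.0)
    root.children = [a, b]
    tips = [a, b]
    counter = [1]
    while len(tips) < cfg.n_taxa:
        wait = rng.exponential(1.0 / (cfg.birth_rate * len(tips)))
        for t in tips:
            t.length += wait
        k = int(rng.integers(len(tips)))
        parent = tips.pop(k)
        counter[0] += 1
        parent_internal_id = f"N{counter[0]}"
        c1 = TreeNode(id=parent.id + "a", parent=parent, length=0.0)
        c2 = TreeNode(id=parent.id + "b", parent=parent, length=0.0)
        parent.children = [c1, c2]
        parent.id = parent_internal_id
        tips.extend([c1, c2])
    wait = rng.exponential(1.0 / (cfg.birth_rate * len(tips)))
    for t in tips:
        t.length += wait
    # rename tips deterministically left-to-right and rescale depth
    tree = RootedTree(root)
    for i, leaf in enumerate(tree.leaves()):
        leaf.id = f"t{i + 1:0{width}d}"
    depth = max(_root_to_tip(leaf) for leaf in tree.leaves())
    scale = cfg.tree_depth / depth if depth > 0 else 1.0
    for n in tree.preorder():
        if n.length is not None:
            n.length *= scale
    # re-id internal nodes in preorder for stability
    k = 0
    for n in tree.preorder():
        if not n.is_leaf:
            k += 1
            n.id = f"N{k}"
    return tree


def _root_to_tip(node: TreeNode) -> float:
    d = 0.0
    while node.parent is not None:
        d += node.length or 0.0
        node = node.parent
    return d


# ---------------------------------------------------------------------------
# tRNA families

def default_trna_template(trna: str, n_d: int = 4, n_t: int = 4) -> CloverleafMap:
    """A 69-column cloverleaf layout: acceptor 7, D up to 4, anticodon 5, T up to 4.

    Pass ``n_d=0`` for families without a D-arm (e.g. tRNA-S1, tRNA-V).
    """
    pairs = []
    for k in range(7):
        pairs.append((k, 68 - k, "acceptor"))
    for k in range(n_d):
        pairs.append((9 + k, 24 - k, "D"))
    for k in range(5):
        pairs.append((26 + k, 42 - k, "anticodon"))
    for k in range(n_t):
        pairs.append((47 + k, 61 - k, "T"))
    return CloverleafMap(trna=trna, pairs=sorted(pairs), anticodon_cols=(33, 34, 35),
                         d_arm=n_d > 0, t_arm=n_t > 0)


_STABLE = sorted(STABLE_PAIRS)
_WC = sorted(WATSON_CRICK)


def _root_sequence(cmap: CloverleafMap, ncol: int, cfg: SimConfig,
                   rng: np.random.Generator) -> list[str]:
    seq = [""] * ncol
    at = cfg.stem_at
    wc_weights = {"AU": at / 2, "UA": at / 2, "GC": (1 - at) / 2, "CG": (1 - at) / 2}
    duples = list(wc_weights)
    w = np.array([wc_weights[d] for d in duples])
    w = w / w.sum()
    for i, j, _ in cmap.pairs:
        d = duples[int(rng.choice(len(duples), p=w))]
        seq[i], seq[j] = d[0], d[1]
    loop_letters = ["A", "U", "G", "C"]
    lp = np.array([cfg.loop_at_bias / 2, cfg.loop_at_bias / 2,
                   (1 - cfg.loop_at_bias) / 2, (1 - cfg.loop_at_bias) / 2])
    for k in range(ncol):
        if not seq[k]:
            seq[k] = loop_letters[int(rng.choice(4, p=lp))]
    return seq


def _mutate_pair(duple: str, kind: str, rng: np.random.Generator) -> Optional[str]:
    """One stem-pair event; None when the event is inapplicable."""
    if "-" in duple:
        return None
    if kind == "fcbc":
        targets = [d for d in _STABLE if d[0] != duple[0] and d[1] != duple[1]]
    elif kind == "hcbc":
        targets = []
        for pos in (0, 1):
            for b in "ACGU":
                if b == duple[pos]:
                    continue
                cand = b + duple[1] if pos == 0 else duple[0] + b
                if cand in STABLE_PAIRS:
                    targets.append(cand)
    elif kind == "mismatch":
        targets = []
        for pos in (0, 1):
            for b in "ACGU":
                if b == duple[pos]:
                    continue
                cand = b + duple[1] if pos == 0 else duple[0] + b
                if cand not in STABLE_PAIRS:
                    targets.append(cand)
    elif kind == "indel":
        targets = ["-" + duple[1], duple[0] + "-"]
    else:  # pragma: no cover
        raise ValueError(kind)
    if not targets:
        return None
    return targets[int(rng.integers(len(targets)))]


def simulate_trna(cfg: SimConfig, tree: RootedTree, cmap: CloverleafMap,
                  rng: Optional[np.random.Generator] = None,
                  ncol: int = 69) -> tuple[dict[str, str], TruthLog]:
    """Evolve one tRNA family along the tree; stems as paired duples.

    Event counts per pair per branch are Poisson(rate x branch length)
    for each event kind; loops evolve site-independently with an A/U
    bias.  Every applied event is logged with the same category labels
    the analysis pipeline assigns.
    """
    rng = rng or cfg.rng()
    log = TruthLog(params={"trna": cmap.trna, "fcbc_rate": cfg.fcbc_rate,
                           "hcbc_rate": cfg.hcbc_rate})
    root_seq = _root_sequence(cmap, ncol, cfg, rng)
    states: dict[str, list[str]] = {tree.root.id: root_seq}
    rates = (("fcbc", cfg.fcbc_rate), ("hcbc", cfg.hcbc_rate),
             ("mismatch", cfg.mismatch_rate), ("indel", cfg.indel_rate))
    loop_cols = [k for k in range(ncol) if k not in cmap.paired_columns()]
    loop_letters = ["A", "U", "G", "C"]
    lp = np.array([cfg.loop_at_bias / 2, cfg.loop_at_bias / 2,
                   (1 - cfg.loop_at_bias) / 2, (1 - cfg.loop_at_bias) / 2])

    for node in tree.preorder():
        if node.parent is None:
            continue
        seq = list(states[node.parent.id])
        t = node.length or 0.0
        for i, j, arm in cmap.pairs:
            events = []
            for kind, rate in rates:
                events.extend([kind] * int(rng.poisson(rate * t)))
            if len(events) > 1:
                rng.shuffle(events)
            for kind in events:
                before = seq[i] + seq[j]
                after = _mutate_pair(before, kind, rng)
                if after is None:
                    continue
                seq[i], seq[j] = after[0], after[1]
                cat, sub, typ = classify_pair_change(before, after)
                log.stem_events.append({
                    "branch": node.id, "trna": cmap.trna, "arm": arm,
                    "pair": (i, j), "before": before, "after": after,
                    "kind": kind, "category": cat, "subtype": sub,
                    "subst_type": typ,
                })
        for k in loop_cols:
            n_ev = int(rng.poisson(cfg.loop_rate * t))
            for _ in range(n_ev):
                cur = seq[k]
                if cur == "-":
                    continue
                choices = [b for b in loop_letters if b != cur]
                wts = np.array([lp[loop_letters.index(b)] for b in choices])
                new = choices[int(rng.choice(len(choices), p=wts / wts.sum()))]
                log.loop_events.append({"branch": node.id, "trna": cmap.trna,
                                        "col": k, "before": cur, "after": new})
                seq[k] = new
        states[node.id] = seq
    alignment = {leaf.id: "".join(states[leaf.id]) for leaf in tree.leaves()}
    return alignment, log


# ---------------------------------------------------------------------------
# codon sequences

_P12_LETTERS = ["A", "T", "G", "C"]


def _pos12_probs(cfg: SimConfig) -> np.ndarray:
    return np.array([cfg.at12 / 2, cfg.at12 / 2, (1 - cfg.at12) / 2, (1 - cfg.at12) / 2])


def simulate_cds(cfg: SimConfig, rng: Optional[np.random.Generator] = None
                 ) -> tuple[dict[str, str], TruthLog]:
    """Codon sequences with exact target GC3 and third-position skews.

    Third positions are drawn G/C with probability ``gc3`` and the letter
    within each class follows the configured skew.  First/second
    positions are composition-driven with the TA dicodon prefix excluded,
    which rules out every stop codon of the invertebrate mitochondrial
    code by construction.
    """
    rng = rng or cfg.rng()
    for gene, ln in cfg.gene_lengths.items():
        if ln % 3:
            raise ValueError(f"gene length for {gene} not a codon multiple")
    if not (0 <= cfg.gc3 <= 1):
        raise ValueError("gc3 must be in [0, 1]")
    p12 = _pos12_probs(cfg)
    p_a = (1 + cfg.at_skew3) / 2      # P(A | third is A/T)
    p_g = (1 + cfg.gc_skew3) / 2      # P(G | third is G/C)
    out: dict[str, str] = {}
    for gene in sorted(cfg.gene_lengths):
        n = cfg.gene_lengths[gene] // 3
        chars = []
        for _ in range(n):
            c1 = _P12_LETTERS[int(rng.choice(4, p=p12))]
            if c1 == "T":
                # exclude A at position 2 (TA* prefix would allow stops)
                w = p12.copy()
                w[0] = 0.0
                w = w / w.sum()
                c2 = _P12_LETTERS[int(rng.choice(4, p=w))]
            else:
                c2 = _P12_LETTERS[int(rng.choice(4, p=p12))]
            if rng.random() < cfg.gc3:
                c3 = "G" if rng.random() < p_g else "C"
            else:
                c3 = "A" if rng.random() < p_a else "T"
            chars.append(c1 + c2 + c3)
        out[gene] = "".join(chars)
    log = TruthLog(params={"gc3": cfg.gc3, "at_skew3": cfg.at_skew3,
                           "gc_skew3": cfg.gc_skew3, "at12": cfg.at12})
    return out, log


def evolve_cds(cfg: SimConfig, tree: RootedTree, root_cds: str,
               rng: Optional[np.random.Generator] = None,
               subst_rate: float = 0.5) -> tuple[dict[str, str], TruthLog]:
    """Evolve a coding sequence along the tree by point mutations.

    Mutations are Poisson(subst_rate x branch length) per site; a mutation
    that would create an in-frame stop codon is discarded (purifying
    selection against nonsense changes).  Every fixed nonsynonymous
    replacement is logged with its branch, codon site and amino acids, so
    replacement-detection can be scored against ground truth.
    """
    if len(root_cds) % 3:
        raise ValueError("root CDS length must be a codon multiple")
    rng = rng or cfg.rng()
    from Bio.Data import CodonTable
    fwd = CodonTable.unambiguous_dna_by_id[5].forward_table
    states = {tree.root.id: root_cds}
    log = TruthLog(params={"subst_rate": subst_rate, "length": len(root_cds)})
    for node in tree.preorder():
        if node.parent is None:
            continue
        seq = list(states[node.parent.id])
        t = node.length or 0.0
        n_mut = int(rng.poisson(subst_rate * t * len(seq)))
        for _ in range(n_mut):
            k = int(rng.integers(len(seq)))
            old = seq[k]
            new = "ACGT"[int(rng.integers(4))]
            if new == old:
                continue
            site = k // 3
            codon_old = "".join(seq[3 * site:3 * site + 3])
            codon_new = codon_old[:k % 3] + new + codon_old[k % 3 + 1:]
            if codon_new not in fwd:
                continue  # would create a stop
            seq[k] = new
            aa_old, aa_new = fwd[codon_old], fwd[codon_new]
            log.cds_events.append({
                "branch": node.id, "site": site, "pos_in_codon": k % 3,
                "from": codon_old, "to": codon_new,
                "aa_from": aa_old, "aa_to": aa_new,
                "nonsynonymous": aa_old != aa_new,
            })
        states[node.id] = "".join(seq)
    alignment = {leaf.id: states[leaf.id] for leaf in tree.leaves()}
    return alignment, log


# ---------------------------------------------------------------------------
# whole toy genome

def _random_at_rich(n: int, at: float, rng: np.random.Generator) -> str:
    p = np.array([at / 2, at / 2, (1 - at) / 2, (1 - at) / 2])
    idx = rng.choice(4, size=n, p=p)
    return "".join("ATGC"[k] for k in idx)


def generate_toy_mitogenome(cfg: SimConfig,
                            order: Sequence[tuple[str, int]] = DEFAULT_GENE_ORDER,
                            rng: Optional[np.random.Generator] = None
                            ) -> tuple[Mitogenome, TruthLog]:
    """A fully annotated 37-gene circular genome with known content.

    PCGs come from :func:`simulate_cds` wrapped in ATG...TAA; tRNA genes
    are single cloverleaf-constrained sequences; rRNAs and control
    regions are AT-rich filler.  Minus-strand genes are stored reverse
    complemented so each feature's sense strand matches its annotation.
    """
    rng = rng or cfg.rng()
    cds, _ = simulate_cds(cfg, rng)
    gene_seqs: dict[str, str] = {g: "ATG" + s + "TAA" for g, s in cds.items()}
    for token, _sign in order:
        if token.startswith("trn"):
            n_d = 0 if token in ("trnS1", "trnV") else 4
            cmap = default_trna_template(token, n_d=n_d)
            seq = "".join(_root_sequence(cmap, 69, cfg, rng)).replace("U", "T")
            gene_seqs[token] = seq
    gene_seqs["rrnS"] = _random_at_rich(700, 0.70, rng)
    gene_seqs["rrnL"] = _random_at_rich(1000, 0.72, rng)
    gene_seqs["CR1"] = _random_at_rich(600, 0.80, rng)
    gene_seqs["CR2"] = _random_at_rich(300, 0.80, rng)

    from Bio.Seq import Seq
    parts = []
    feats = []
    pos = 0
    for token, sign in order:
        s = gene_seqs[token]
        stored = str(Seq(s).reverse_complement()) if sign < 0 else s
        kind = ("PCG" if token in PCG_TOKENS else
                "tRNA" if token.startswith("trn") else
                "rRNA" if token.startswith("rrn") else "CR")
        feats.append(GeneFeature(token, pos, pos + len(s), "-" if sign < 0 else "+", kind))
        parts.append(stored)
        pos += len(s)
    genome = Mitogenome(id="SYN1", taxon="synthetic toy mitogenome",
                        sequence="".join(parts), circular=True, complete=True,
                        features=feats)
    log = TruthLog(params={"order": tuple(order), "gene_seqs": gene_seqs})
    return genome, log


# ---------------------------------------------------------------------------
# gene-order scrambling

def _random_event(order: SignedGeneOrder, kind: str,
                  rng: np.random.Generator) -> RearrangementEvent:
    n = len(order)
    if kind in ("reversal", "transposition", "reverse_transposition"):
        while True:
            i = int(rng.integers(n))
            j = int(rng.integers(i + 1, n + 1))
            if kind == "reversal":
                if j - i < n:  # not the whole circle
                    return RearrangementEvent("reversal", (i, j))
                continue
            m = n - (j - i)
            if m == 0:
                continue
            d = int(rng.integers(m + 1))
            if kind == "transposition" and d == i:
                continue
            return RearrangementEvent(kind, (i, j), d)
    if kind == "tdrl":
        while True:
            mask = rng.random(n) < 0.5
            if 0 < mask.sum() < n:
                part = tuple(int(k) for k in np.flatnonzero(mask))
                ev = RearrangementEvent("tdrl", partition=part)
                if not apply_event(order, ev).tokens == order.tokens:
                    return ev
    raise ValueError(kind)  # pragma: no cover


def scramble_gene_order(order: SignedGeneOrder, cfg: SimConfig,
                        rng: Optional[np.random.Generator] = None
                        ) -> tuple[SignedGeneOrder, TruthLog]:
    """Apply cfg.n_order_events random events of the configured kinds."""
    rng = rng or cfg.rng()
    log = TruthLog(params={"kinds": cfg.order_event_kinds})
    cur = order
    for k in range(cfg.n_order_events):
        kind = cfg.order_event_kinds[k % len(cfg.order_event_kinds)]
        ev = _random_event(cur, kind, rng)
        cur = apply_event(cur, ev)
        log.order_events.append(ev)
    return cur, log
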