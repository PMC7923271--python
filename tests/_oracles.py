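"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written as naive enumeration, separate
from the package's implementations, so that agreement between the two
routes is meaningful.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter

from Bio.Data import CodonTable


# ---------------------------------------------------------------------------
# Fitch parsimony by exhaustive labelling

def exhaustive_parsimony_score(tree, column_states: dict[str, str],
                               alphabet: str = "ACGU-") -> int:
    """Minimum change count over all internal-node labelings of one column."""
    internals = [n for n in tree.preorder() if not n.is_leaf]
    best = math.inf
    for combo in itertools.product(alphabet, repeat=len(internals)):
        lab = {n.id: s for n, s in zip(internals, combo)}
        lab.update(column_states)
        changes = 0
        for n in tree.preorder():
            if n.parent is not None and lab[n.id] != lab[n.parent.id]:
                changes += 1
        best = min(best, changes)
    return int(best)


# ---------------------------------------------------------------------------
# circular signed orders

def circular_adjacencies(tokens) -> set:
    n = len(tokens)
    out = set()
    for i in range(n):
        x, y = tokens[i], tokens[(i + 1) % n]
        out.add(min((x, y), ((y[0], -y[1]), (x[0], -x[1]))))
    return out


def breakpoints_by_enumeration(a_tokens, b_tokens) -> int:
    return len(circular_adjacencies(a_tokens) - circular_adjacencies(b_tokens))


def _interval_appears_in(interval, b_tokens) -> bool:
    """Does the signed interval appear contiguously (circularly) in b,
    forward with equal signs or reversed with flipped signs?"""
    n = len(b_tokens)
    m = len(interval)
    doubled = list(b_tokens) + list(b_tokens)
    rev = [(t, -s) for t, s in reversed(interval)]
    for k in range(n):
        win = doubled[k:k + m]
        if win == list(interval) or win == rev:
            return True
    return False


def conserved_blocks_by_enumeration(a_tokens, b_tokens):
    """Maximal circular intervals of `a` appearing contiguously in `b`.

    O(n^3)-ish direct enumeration; returns the same representation the
    package uses (tuples of (token, sign) in a's order).
    """
    n = len(a_tokens)
    doubled = list(a_tokens) + list(a_tokens)
    if _interval_appears_in(tuple(a_tokens), b_tokens):
        return [tuple(a_tokens)]
    blocks = []
    for start in range(n):
        for m in range(1, n):
            iv = tuple(doubled[start:start + m])
            if not _interval_appears_in(iv, b_tokens):
                continue
            left = tuple(doubled[(start - 1) % n: (start - 1) % n + m + 1])
            right = tuple(doubled[start:start + m + 1])
            if len(left) == m + 1 and _interval_appears_in(left, b_tokens):
                continue
            if _interval_appears_in(right, b_tokens):
                continue
            blocks.append(iv)
    return blocks


# ---------------------------------------------------------------------------
# pairwise compensatory changes

_STABLE = {"AU", "UA", "GC", "CG", "GU", "UG"}


def _u(ch: str) -> str:
    return "U" if ch.upper() == "T" else ch.upper()


def pairwise_cbc_by_enumeration(aln: dict[str, str], pairs) -> dict:
    """Per taxon pair, count paired columns where both bases differ and
    both duples are stable."""
    taxa = sorted(aln)
    out = {}
    for x, y in itertools.combinations(taxa, 2):
        n = 0
        for i, j, _arm in pairs:
            dx = _u(aln[x][i]) + _u(aln[x][j])
            dy = _u(aln[y][i]) + _u(aln[y][j])
            if dx in _STABLE and dy in _STABLE:
                if dx[0] != dy[0] and dx[1] != dy[1]:
                    n += 1
        out[(x, y)] = n
    return out


# ---------------------------------------------------------------------------
# magnitude-category baseline

def magnitude_baseline_by_enumeration(prop_values: dict[str, float],
                                      code: int = 5, n_cat: int = 8):
    """Category probabilities from a flat loop over all codon mutations."""
    fwd = CodonTable.unambiguous_dna_by_id[code].forward_table
    deltas = []
    for codon in fwd:
        for pos in range(3):
            for b in "ACGT":
                mutant = codon[:pos] + b + codon[pos + 1:]
                if mutant == codon or mutant not in fwd:
                    continue
                if fwd[mutant] == fwd[codon]:
                    continue
                deltas.append(abs(prop_values[fwd[codon]] - prop_values[fwd[mutant]]))
    lo, hi = min(deltas), max(deltas)
    if hi <= lo:
        probs = [0.0] * n_cat
        probs[0] = 1.0
        return probs
    width = (hi - lo) / n_cat
    counts = [0] * n_cat
    for d in deltas:
        k = min(int((d - lo) / width), n_cat - 1)
        counts[k] += 1
    return [c / len(deltas) for c in counts]


# ---------------------------------------------------------------------------
# NG86 dN/dS, written as one long literal loop

def ng86_by_enumeration(seq_a: str, seq_b: str, code: int = 5):
    """(dn, ds) by direct Nei-Gojobori counting; independent route."""
    table = CodonTable.unambiguous_dna_by_id[code]
    fwd = table.forward_table
    stops = set(table.stop_codons)

    def sites(codon):
        syn = 0.0
        non = 0.0
        for pos in range(3):
            muts = [codon[:pos] + b + codon[pos + 1:] for b in "ACGT"
                    if b != codon[pos]]
            muts = [m for m in muts if m not in stops]
            if not muts:
                continue
            k = sum(1 for m in muts if fwd[m] == fwd[codon])
            syn += k / len(muts)
            non += (len(muts) - k) / len(muts)
        return syn, non

    def diffs(ca, cb):
        positions = [p for p in range(3) if ca[p] != cb[p]]
        paths = []
        for order in itertools.permutations(positions):
            cur = ca
            steps = []
            bad = False
            for p in order:
                nxt = cur[:p] + cb[p] + cur[p + 1:]
                steps.append((cur, nxt))
                if nxt != cb and nxt in stops:
                    bad = True
                cur = nxt
            paths.append((bad, steps))
        usable = [s for bad, s in paths if not bad] or [s for _, s in paths]
        sd = nd = 0.0
        for steps in usable:
            for x, y in steps:
                if x in fwd and y in fwd and fwd[x] == fwd[y]:
                    sd += 1
                else:
                    nd += 1
        return sd / len(usable), nd / len(usable)

    S = N = Sd = Nd = 0.0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i:i + 3], seq_b[i:i + 3]
        if ca not in fwd or cb not in fwd:
            continue
        s1, n1 = sites(ca)
        s2, n2 = sites(cb)
        S += (s1 + s2) / 2
        N += (n1 + n2) / 2
        if ca != cb:
            sd, nd = diffs(ca, cb)
            Sd += sd
            Nd += nd
    ps, pn = Sd / S, Nd / N

    def jc(p):
        return math.nan if p >= 0.75 else -0.75 * math.log(1 - 4 * p / 3)

    return jc(pn), jc(ps)
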