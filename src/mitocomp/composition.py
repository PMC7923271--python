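"""Nucleotide composition, strand skews, and codon-usage statistics.

Skews follow the standard strand-asymmetry definitions
AT-skew = (A - T)/(A + T) and GC-skew = (G - C)/(G + C); an undefined skew
(zero denominator) is reported as NaN.  Codon-usage bias is summarized by
Wright's effective number of codons (ENC, generalized to the invertebrate
mitochondrial code where serine has an eight-codon family) and by MILC, a
length- and composition-corrected statistic.  All statistics for
minus-strand genes are computed on the gene's sense (coding) strand.
"""

from __future__ import annotations

import math
from collections import Counter
from typing import Iterable, Mapping, NamedTuple, Optional

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .genome_io import CDSRecord, Mitogenome

__all__ = [
    "BaseStats",
    "base_stats",
    "partitioned_composition",
    "codon_counts",
    "sense_codons",
    "enc",
    "milc",
    "gc3_fourfold",
    "aa_frequencies",
    "gene_codon_usage",
]


class BaseStats(NamedTuple):
    at_percent: float
    at_skew: float
    gc_skew: float
    n_sites: int


def base_stats(seq: str) -> BaseStats:
    """A+T percentage and AT/GC skews of a nucleotide string.

    Ambiguity codes and gaps are excluded from all counts.
    """
    c = Counter(seq.upper().replace("U", "T"))
    a, t, g, cc = c["A"], c["T"], c["G"], c["C"]
    n = a + t + g + cc
    if n == 0:
        return BaseStats(math.nan, math.nan, math.nan, 0)
    at = math.nan if a + t == 0 else (a - t) / (a + t)
    gc = math.nan if g + cc == 0 else (g - cc) / (g + cc)
    return BaseStats(100.0 * (a + t) / n, at, gc, n)


# ---------------------------------------------------------------------------
# genetic code helpers

def _code(code: int):
    return CodonTable.unambiguous_dna_by_id[code]


def sense_codons(code: int = 5) -> list[str]:
    """The sense codons of the code, in lexicographic order (62 for code 5)."""
    return sorted(_code(code).forward_table)


def _families(code: int = 5) -> dict[str, list[str]]:
    fams: dict[str, list[str]] = {}
    for codon, aa in _code(code).forward_table.items():
        fams.setdefault(aa, []).append(codon)
    return {aa: sorted(cs) for aa, cs in fams.items()}


def _fourfold_codons(code: int = 5) -> set[str]:
    """Codons whose third position is free (all 4 thirds give the same aa)."""
    fwd = _code(code).forward_table
    out = set()
    for codon, aa in fwd.items():
        box = [codon[:2] + b for b in "ACGT"]
        if all(fwd.get(c) == aa for c in box):
            out.add(codon)
    return out


# ---------------------------------------------------------------------------
# codon counting

def codon_counts(cds_set: Iterable[CDSRecord] | Iterable[str], code: int = 5) -> pd.Series:
    """Codon count table over the sense codons of the code.

    Stop codons and codons with ambiguity characters are excluded.
    """
    sense = sense_codons(code)
    counts = Counter()
    for item in cds_set:
        seq = item.seq if isinstance(item, CDSRecord) else item
        seq = seq.upper().replace("U", "T")
        for i in range(0, len(seq) - len(seq) % 3, 3):
            codon = seq[i:i + 3]
            if codon in _code(code).forward_table:
                counts[codon] += 1
    return pd.Series({c: counts.get(c, 0) for c in sense}, name="count")


def enc(counts: Mapping[str, int] | pd.Series, code: int = 5) -> float:
    """Wright's effective number of codons, generalized to the active code.

    Per amino-acid family with n >= 2 codons observed, the homozygosity is
    F = (n * sum(p_i^2) - 1) / (n - 1); families are pooled into
    family-size classes and ENC sums (class size) / mean(F) over classes,
    plus one per single-codon family.  A class with no computable F is
    imputed by interpolating 1/F linearly between neighbouring classes
    (falling back to the uniform expectation 1/size).  The result is
    capped at the number of sense codons.
    """
    counts = dict(counts)
    if sum(counts.values()) == 0:
        return math.nan
    fams = _families(code)
    by_size: dict[int, list[float]] = {}
    sizes: dict[int, int] = {}
    for aa, codons in fams.items():
        r = len(codons)
        sizes[r] = sizes.get(r, 0) + 1
        if r == 1:
            continue
        n = sum(counts.get(c, 0) for c in codons)
        if n < 2:
            continue
        s = sum((counts.get(c, 0) / n) ** 2 for c in codons)
        f = (n * s - 1) / (n - 1)
        if f > 0:
            by_size.setdefault(r, []).append(f)

    total = 0.0
    size_list = sorted(s for s in sizes if s > 1)
    mean_f = {s: float(np.mean(by_size[s])) for s in by_size}
    for s in size_list:
        if s in mean_f:
            fbar = mean_f[s]
        else:
            # reciprocal-mean interpolation between computed classes
            lower = [t for t in mean_f if t < s]
            upper = [t for t in mean_f if t > s]
            if lower and upper:
                lo, hi = max(lower), min(upper)
                w = (s - lo) / (hi - lo)
                inv = (1 - w) / mean_f[lo] + w / mean_f[hi]
                fbar = 1.0 / inv
            else:
                fbar = 1.0 / s
        total += sizes[s] / fbar
    total += sizes.get(1, 0)
    n_sense = len(_code(code).forward_table)
    return min(total, float(n_sense))


def milc(counts: Mapping[str, int] | pd.Series,
         expected: Optional[Mapping[str, float]] = None,
         code: int = 5) -> float:
    """MILC codon-usage statistic against an expected within-family model.

    M_a = 2 * sum_c o_c * ln(f_c / g_c) over the codons of amino acid a,
    with o observed counts, f observed within-family frequencies and g the
    expected within-family frequencies (uniform by default).  MILC is
    sum(M_a)/L minus the correction C = (sum_a (r_a - 1))/L - 0.5 with L
    the total codon count; families with no observations drop out of both
    sums.
    """
    counts = dict(counts)
    L = sum(counts.values())
    if L == 0:
        return math.nan
    fams = _families(code)
    total_m = 0.0
    corr_df = 0
    for aa, codons in fams.items():
        n = sum(counts.get(c, 0) for c in codons)
        if n == 0:
            continue
        r = len(codons)
        corr_df += r - 1
        for c in codons:
            o = counts.get(c, 0)
            if o == 0:
                continue
            f = o / n
            g = (1.0 / r) if expected is None else expected[c]
            if g == 0:
                raise ValueError(f"observed codon {c} has zero expected frequency")
            total_m += 2.0 * o * math.log(f / g)
    correction = corr_df / L - 0.5
    return total_m / L - correction


def gc3_fourfold(cds_set: Iterable[CDSRecord] | Iterable[str], code: int = 5) -> float:
    """G+C fraction at third positions of fourfold-degenerate codons."""
    ff = _fourfold_codons(code)
    gc = tot = 0
    for item in cds_set:
        seq = item.seq if isinstance(item, CDSRecord) else item
        seq = seq.upper().replace("U", "T")
        for i in range(0, len(seq) - len(seq) % 3, 3):
            codon = seq[i:i + 3]
            if codon in ff:
                tot += 1
                if codon[2] in "GC":
                    gc += 1
    return math.nan if tot == 0 else gc / tot


def aa_frequencies(cds_set: Iterable[CDSRecord], code: int = 5) -> pd.DataFrame:
    """Amino-acid frequencies per coding-strand class and pooled.

    Stops are excluded; each column sums to 1 (when any codons counted).
    """
    classes = {"plus": Counter(), "minus": Counter(), "pooled": Counter()}
    fwd = _code(code).forward_table
    for c in cds_set:
        strand_class = "minus" if c.strand == "-" else "plus"
        for codon in c.codons():
            aa = fwd.get(codon)
            if aa is None:
                continue
            classes[strand_class][aa] += 1
            classes["pooled"][aa] += 1
    aas = sorted(set(fwd.values()))
    data = {}
    for name, ctr in classes.items():
        tot = sum(ctr.values())
        data[name] = [ctr.get(a, 0) / tot if tot else math.nan for a in aas]
    return pd.DataFrame(data, index=aas)


def gene_codon_usage(cds_set: Iterable[CDSRecord], code: int = 5) -> pd.DataFrame:
    """Per-gene codon-usage summary: ENC, MILC, fourfold GC3, codon total."""
    rows = []
    for c in cds_set:
        counts = codon_counts([c], code)
        rows.append({
            "gene": c.gene, "taxon": c.taxon, "strand": c.strand,
            "n_codons": int(counts.sum()),
            "enc": enc(counts, code),
            "milc": milc(counts, code=code),
            "gc3_4fold": gc3_fourfold([c], code),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# genome partition report

def _report_row(partition: str, seq_or_concat: str) -> dict:
    s = base_stats(seq_or_concat)
    return {"partition": partition, "at_percent": s.at_percent,
            "at_skew": s.at_skew, "gc_skew": s.gc_skew, "n_sites": s.n_sites}


def partitioned_composition(g: Mitogenome, structures: Optional[dict] = None) -> pd.DataFrame:
    """Composition report across the standard partitions of a mitogenome.

    One row per: whole genome (plus strand); each gene on its sense
    strand; codon positions 1/2/3 pooled over the PCGs of each coding
    strand; the rRNA pool; the tRNA pool (plus stem and loop sub-pools
    when cloverleaf ``structures`` keyed by tRNA token are supplied; their
    column pairs are interpreted on the gene's own sense sequence); and
    each control region.
    """
    rows = [_report_row("whole_genome", g.sequence)]
    for f in sorted(g.features, key=lambda x: (x.kind, x.token)):
        label = f"CR:{f.token}" if f.kind == "CR" else f"gene:{f.token}"
        rows.append(_report_row(label, g.feature_seq(f)))
    # codon positions by strand class
    for strand, sname in (("+", "plus"), ("-", "minus")):
        pos_pool = {1: [], 2: [], 3: []}
        for f in g.features:
            if f.kind != "PCG" or f.strand != strand:
                continue
            s = g.feature_seq(f)
            s = s[: len(s) - len(s) % 3]
            for p in (1, 2, 3):
                pos_pool[p].append(s[p - 1::3])
        for p in (1, 2, 3):
            if pos_pool[p]:
                rows.append(_report_row(f"codon_pos{p}:{sname}", "".join(pos_pool[p])))
    for kind, label in (("rRNA", "rRNA"), ("tRNA", "tRNA")):
        pool = [g.feature_seq(f) for f in g.features if f.kind == kind]
        if pool:
            rows.append(_report_row(label, "".join(pool)))
    if structures:
        stems, loops = [], []
        for f in g.features:
            if f.kind != "tRNA" or f.token not in structures:
                continue
            s = g.feature_seq(f)
            cmap = structures[f.token]
            paired = {i for i, j, _ in cmap.pairs} | {j for i, j, _ in cmap.pairs}
            stems.append("".join(s[k] for k in sorted(paired) if k < len(s)))
            loops.append("".join(s[k] for k in range(len(s)) if k not in paired))
        if stems:
            rows.append(_report_row("tRNA_stems", "".join(stems)))
            rows.append(_report_row("tRNA_loops", "".join(loops)))
    return pd.DataFrame(rows)
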