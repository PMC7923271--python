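"""Physicochemical selection scans and counting-method dN/dS.

The property scan classifies every inferred nonsynonymous replacement by
the magnitude of the physicochemical change it causes: for each property,
the absolute property differences of all amino-acid replacements
reachable by one nucleotide change under the genetic code are split into
eight equal-width categories, and the enumeration itself provides the
neutral expectation p_k of each category.  Observed replacements on the
tree are binned the same way; the per-category z-score
(o_k - N p_k) / sqrt(N p_k (1 - p_k)) flags positive destabilizing
selection when z > 3.09 (one-sided P ~ 0.001) in the most radical
categories 7 and 8.  dN/dS (omega) is estimated by Nei-Gojobori (1986)
counting with a Jukes-Cantor correction.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from importlib import resources
from io import StringIO
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .ancestry import RootedTree, fitch_ancestral

__all__ = [
    "Z_THRESHOLD",
    "load_property_table",
    "MagnitudeModel",
    "build_magnitude_model",
    "branch_aa_substitutions",
    "ZReport",
    "z_scan",
    "DnDsEstimate",
    "ng86_dnds",
]

#: one-sided normal quantile for P = 0.001; the significance threshold
Z_THRESHOLD = 3.09
N_CATEGORIES = 8


def load_property_table() -> pd.DataFrame:
    """The shipped amino-acid property table (20 rows, one column per property)."""
    text = resources.files("mitocomp.data").joinpath("aa_properties.csv").read_text()
    df = pd.read_csv(StringIO(text), comment="#").set_index("aa")
    if sorted(df.index) != sorted("ACDEFGHIKLMNPQRSTVWY"):
        raise ValueError("property table must cover exactly the 20 amino acids")
    return df


def _code(code: int):
    return CodonTable.unambiguous_dna_by_id[code]


def _single_step_pairs(code: int) -> list[tuple[str, str]]:
    """All ordered (codon, mutant) sense pairs differing at one position,
    with different encoded amino acids."""
    fwd = _code(code).forward_table
    out = []
    for codon, aa in fwd.items():
        for pos in range(3):
            for b in "ACGT":
                if b == codon[pos]:
                    continue
                mut = codon[:pos] + b + codon[pos + 1:]
                aa2 = fwd.get(mut)
                if aa2 is not None and aa2 != aa:
                    out.append((codon, mut))
    return out


@dataclass
class MagnitudeModel:
    """Equal-width magnitude categories and their neutral baseline.

    ``edges[prop]`` holds the 9 bin edges over the enumeration range of
    |delta property|; ``probs[prop]`` the baseline probability of each of
    the 8 categories under uniform weighting of single-nucleotide
    nonsynonymous codon changes.
    """
    edges: dict[str, np.ndarray]
    probs: dict[str, np.ndarray]
    code: int

    def categorize(self, prop: str, delta: float) -> int:
        """1-based category of an absolute property change."""
        e = self.edges[prop]
        k = int(np.searchsorted(e, abs(delta), side="right")) - 1
        return int(np.clip(k, 0, N_CATEGORIES - 1)) + 1


def build_magnitude_model(code: int = 5,
                          props: Optional[pd.DataFrame] = None) -> MagnitudeModel:
    """Enumerate single-step nonsynonymous changes and bin |delta| 8 ways.

    Every (codon, single-nucleotide mutant) pair gets equal weight.  A
    property that never changes puts all mass in category 1.
    """
    if props is None:
        props = load_property_table()
    fwd = _code(code).forward_table
    pairs = _single_step_pairs(code)
    edges: dict[str, np.ndarray] = {}
    probs: dict[str, np.ndarray] = {}
    for prop in props.columns:
        vals = props[prop]
        deltas = np.array([abs(vals[fwd[a]] - vals[fwd[b]]) for a, b in pairs])
        lo, hi = float(deltas.min()), float(deltas.max())
        if hi <= lo:
            e = np.linspace(0.0, 1.0, N_CATEGORIES + 1)
            p = np.zeros(N_CATEGORIES)
            p[0] = 1.0
        else:
            e = np.linspace(lo, hi, N_CATEGORIES + 1)
            idx = np.clip(np.searchsorted(e, deltas, side="right") - 1, 0, N_CATEGORIES - 1)
            p = np.bincount(idx, minlength=N_CATEGORIES) / len(deltas)
        edges[prop] = e
        probs[prop] = p
    return MagnitudeModel(edges=edges, probs=probs, code=code)


# ---------------------------------------------------------------------------
# substitutions on the tree

def _codon_paths(a: str, b: str, fwd) -> list[list[tuple[str, str]]]:
    """Minimal single-step mutational paths a -> b avoiding stop codons.

    Returns a list of paths; each path is the list of (codon, codon)
    steps.  If every ordering passes through a stop, all orderings are
    returned anyway (the standard pathway-averaging fallback).
    """
    diff = [k for k in range(3) if a[k] != b[k]]
    clean, everything = [], []
    for perm in itertools.permutations(diff):
        cur = a
        path = []
        ok = True
        for pos in perm:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            path.append((cur, nxt))
            if nxt != b and nxt not in fwd:
                ok = False  # intermediate stop codon
            cur = nxt
        everything.append(path)
        if ok:
            clean.append(path)
    return clean if clean else everything


def branch_aa_substitutions(codon_alignment: Mapping[str, str],
                            tree: RootedTree,
                            code: int = 5) -> pd.DataFrame:
    """Nonsynonymous replacements per branch from codon-wise Fitch states.

    Ancestral nucleotides are reconstructed column-wise; parent and child
    codons are compared per site.  Codons touched by gaps are skipped.  A
    multi-nucleotide codon change is decomposed over its minimal
    single-step paths and each path's replacements carry weight
    1/n_paths.
    """
    for label, seq in codon_alignment.items():
        if len(seq) % 3:
            raise ValueError(f"row {label} length not a codon multiple")
    fwd = _code(code).forward_table
    aa = fitch_ancestral(dict(codon_alignment), tree)
    rows = []
    for n in tree.preorder():
        if n.parent is None:
            continue
        p, c = aa.sequences[n.parent.id], aa.sequences[n.id]
        bclass = tree.branch_class(n)
        for site in range(len(p) // 3):
            cp, cc = p[3 * site:3 * site + 3], c[3 * site:3 * site + 3]
            if cp == cc or "-" in cp or "-" in cc:
                continue
            if cp not in fwd and cp not in _code(code).stop_codons:
                continue
            paths = _codon_paths(cp, cc, fwd)
            w = 1.0 / len(paths)
            for path in paths:
                for x, y in path:
                    ax, ay = fwd.get(x), fwd.get(y)
                    if ax is None or ay is None or ax == ay:
                        continue
                    rows.append({"branch": n.id, "branch_class": bclass,
                                 "site": site, "aa_from": ax, "aa_to": ay,
                                 "weight": w})
    return pd.DataFrame(rows, columns=["branch", "branch_class", "site",
                                       "aa_from", "aa_to", "weight"])


# ---------------------------------------------------------------------------
# z-scan

@dataclass
class ZReport:
    """Gene-wide and sliding-window property z-scores."""
    gene_table: pd.DataFrame     # property, category, observed, expected, z, significant
    site_tracks: pd.DataFrame    # property, window_start, category, z, significant
    n_substitutions: float
    window: int

    def significant_properties(self) -> list[str]:
        g = self.gene_table
        hits = g[(g["significant"]) & (g["category"] >= 7)]
        return sorted(hits["property"].unique())


def _cat_z(obs: np.ndarray, n: float, p: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (obs - n * p) / np.sqrt(n * p * (1 - p))
    return np.where((p > 0) & (p < 1) & (n > 0), z, 0.0)


def z_scan(subs: pd.DataFrame, model: MagnitudeModel,
           props: Optional[pd.DataFrame] = None,
           window: int = 20) -> ZReport:
    """Bin observed replacements per property and score each category.

    Gene-wide z per category plus a sliding-window track (codon-site
    windows of ``window``, step 1) for the radical categories.  Only
    counts enter the statistic, so splitting substitutions across
    branches leaves the gene-level result unchanged.
    """
    if props is None:
        props = load_property_table()
    if subs.empty:
        return ZReport(pd.DataFrame(), pd.DataFrame(), 0.0, window)
    n_total = float(subs["weight"].sum())
    gene_rows = []
    site_rows = []
    max_site = int(subs["site"].max())
    for prop in props.columns:
        vals = props[prop]
        cats = np.array([model.categorize(prop, vals[r.aa_to] - vals[r.aa_from])
                         for r in subs.itertuples()])
        w = subs["weight"].to_numpy()
        obs = np.zeros(N_CATEGORIES)
        for k in range(N_CATEGORIES):
            obs[k] = w[cats == k + 1].sum()
        z = _cat_z(obs, n_total, model.probs[prop])
        for k in range(N_CATEGORIES):
            gene_rows.append({"property": prop, "category": k + 1,
                              "observed": obs[k],
                              "expected": n_total * model.probs[prop][k],
                              "z": z[k],
                              "significant": z[k] > Z_THRESHOLD})
        sites = subs["site"].to_numpy()
        for start in range(0, max_site + 1):
            sel = (sites >= start) & (sites < start + window)
            if not sel.any():
                continue
            nw = float(w[sel].sum())
            for k in (6, 7):  # categories 7 and 8
                ow = float(w[sel & (cats == k + 1)].sum())
                pk = model.probs[prop][k]
                zk = float(_cat_z(np.array([ow]), nw, np.array([pk]))[0])
                site_rows.append({"property": prop, "window_start": start,
                                  "category": k + 1, "z": zk,
                                  "significant": zk > Z_THRESHOLD})
    return ZReport(
        gene_table=pd.DataFrame(gene_rows),
        site_tracks=pd.DataFrame(site_rows),
        n_substitutions=n_total, window=window,
    )


# ---------------------------------------------------------------------------
# NG86 dN/dS

@dataclass
class DnDsEstimate:
    dn: float
    ds: float
    omega: float           # NaN when dS == 0 or correction saturates
    n_sites: float
    s_sites: float
    n_diffs: float
    s_diffs: float


def _site_fractions(codon: str, fwd, stops) -> tuple[float, float]:
    """Synonymous/nonsynonymous site counts of one codon (stops excluded
    from the mutational opportunities, per the counting method)."""
    s = 0.0
    n = 0.0
    aa = fwd[codon]
    for pos in range(3):
        alts = [codon[:pos] + b + codon[pos + 1:] for b in "ACGT" if b != codon[pos]]
        valid = [m for m in alts if m not in stops]
        if not valid:
            continue
        syn = sum(1 for m in valid if fwd[m] == aa)
        s += syn / len(valid)
        n += (len(valid) - syn) / len(valid)
    return s, n


def _path_diffs(a: str, b: str, fwd, stops) -> tuple[float, float]:
    """Pathway-averaged synonymous/nonsynonymous differences of a codon pair."""
    paths = _codon_paths(a, b, fwd)
    sd = nd = 0.0
    for path in paths:
        for x, y in path:
            ax, ay = fwd.get(x), fwd.get(y)
            if ax is None or ay is None:
                nd += 1  # steps through a stop count as nonsynonymous
            elif ax == ay:
                sd += 1
            else:
                nd += 1
    k = len(paths)
    return sd / k, nd / k


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log(1 - 4 * p / 3)


def ng86_dnds(seq_a: str, seq_b: str, code: int = 5) -> DnDsEstimate:
    """Nei-Gojobori (1986) counting estimate of dN, dS and omega.

    Codon sites with a gap or a non-sense codon in either sequence are
    stripped pairwise.  Site counts are averaged over the two sequences;
    differences are pathway-averaged; proportions are Jukes-Cantor
    corrected.  omega is NaN when dS is 0 or a correction saturates.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal length")
    if len(seq_a) % 3:
        raise ValueError("sequence length must be a codon multiple")
    fwd = _code(code).forward_table
    stops = set(_code(code).stop_codons)
    sa = na = sb = nb = sd = nd = 0.0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i:i + 3].upper(), seq_b[i:i + 3].upper()
        if ca not in fwd or cb not in fwd:
            continue
        s1, n1 = _site_fractions(ca, fwd, stops)
        s2, n2 = _site_fractions(cb, fwd, stops)
        sa += s1
        na += n1
        sb += s2
        nb += n2
        if ca != cb:
            ds_, dn_ = _path_diffs(ca, cb, fwd, stops)
            sd += ds_
            nd += dn_
    s_sites = (sa + sb) / 2.0
    n_sites = (na + nb) / 2.0
    if s_sites == 0 or n_sites == 0:
        return DnDsEstimate(math.nan, math.nan, math.nan, n_sites, s_sites, nd, sd)
    ps, pn = sd / s_sites, nd / n_sites
    ds = _jukes_cantor(ps)
    dn = _jukes_cantor(pn)
    omega = math.nan
    if not math.isnan(ds) and not math.isnan(dn) and ds > 0:
        omega = dn / ds
    return DnDsEstimate(dn=dn, ds=ds, omega=omega, n_sites=n_sites,
                        s_sites=s_sites, n_diffs=nd, s_diffs=sd)
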