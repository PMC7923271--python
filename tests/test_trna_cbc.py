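"""Cloverleaf maps and compensatory base-change classification and tallies."""

import itertools

import numpy as np
import pytest

from mitocomp.ancestry import AncestralAlignment, fitch_ancestral, read_newick
from mitocomp.composition import base_stats
from mitocomp.trna_cbc import (STABLE_PAIRS, CloverleafMap, build_consensus_structure,
                               classify_pair_change, pair_class, pairwise_cbc_matrix,
                               stem_loop_stats, tally_cbc)
from mitocomp.synthetic_data import SimConfig, default_trna_template, simulate_tree, simulate_trna
from _oracles import pairwise_cbc_by_enumeration


def test_exactly_six_stable_pairs():
    stable = {a + b for a, b in itertools.product("ACGU", repeat=2)
              if pair_class(a + b) in ("WC", "wobble")}
    assert stable == STABLE_PAIRS and len(stable) == 6


@pytest.mark.parametrize("parent,child,category,subtype", [
    ("AU", "GC", "FCBC", "wc_switch"),
    ("GU", "UA", "FCBC", "stable_switch"),
    ("AU", "GU", "HCBC", "result_wobble"),
    ("GU", "GC", "HCBC", "result_wc"),
    ("AU", "AC", "HCBC", "result_mismatch"),
    ("AC", "GU", "FCBC", "mismatch_to_match"),
    ("GC", "AC", "HCBC", "result_mismatch"),
    ("AU", "AU", "none", ""),
    ("AU", "A-", "indel", "gap_gain"),
    ("-U", "GU", "indel", "gap_loss"),
])
def test_pair_change_classification(parent, child, category, subtype):
    cat, sub, _typ = classify_pair_change(parent, child)
    assert (cat, sub) == (category, subtype)


def test_pair_change_type_strings():
    assert classify_pair_change("AU", "GC")[2] == "AU -> GC"
    assert classify_pair_change("AU", "GU")[2] == "A -> G vs U"


def test_classification_partition_is_exhaustive_and_symmetric():
    alphabet = ["A", "C", "G", "U", "-"]
    for p in itertools.product(alphabet, repeat=2):
        for c in itertools.product(alphabet, repeat=2):
            dp, dc = "".join(p), "".join(c)
            cat, _, _ = classify_pair_change(dp, dc)
            changed = sum(x != y for x, y in zip(dp, dc))
            has_gap = "-" in dp + dc
            if dp == dc:
                assert cat == "none"
            elif has_gap:
                assert cat == "indel"
            elif changed == 2:
                assert cat == "FCBC"
            else:
                assert cat == "HCBC"
            # information symmetry: FCBC/HCBC are preserved when reversed
            rcat, _, _ = classify_pair_change(dc, dp)
            if cat in ("FCBC", "HCBC"):
                assert rcat == cat


# ---------------------------------------------------------------------------
# consensus structure

def test_consensus_structure_keeps_template_when_all_match(template):
    aln = {f"t{i}": "A" * 69 for i in range(4)}
    cons = build_consensus_structure(aln, template)
    assert cons.pairs == template.pairs and cons.d_arm and cons.t_arm


def test_consensus_majority_drops_gapped_d_arm(template):
    row_nod = list("A" * 69)
    for i, j, arm in template.pairs:
        if arm == "D":
            row_nod[i] = row_nod[j] = "-"
    aln = {"t1": "".join(row_nod), "t2": "".join(row_nod), "t3": "A" * 69}
    cons = build_consensus_structure(aln, template)
    assert not cons.d_arm
    assert cons.arm_pair_counts()["D"] == 0
    assert cons.arm_pair_counts() == {"acceptor": 7, "D": 0, "anticodon": 5, "T": 4}


def test_consensus_mixed_d_arm_majority_layout(template):
    """60% of rows keep the full D-arm; 40% lack it -> template layout kept."""
    row_full = "A" * 69
    row_nod = list(row_full)
    for i, j, arm in template.pairs:
        if arm == "D":
            row_nod[i] = row_nod[j] = "-"
    aln = {f"f{i}": row_full for i in range(3)}
    aln.update({f"n{i}": "".join(row_nod) for i in range(2)})
    cons = build_consensus_structure(aln, template)
    assert cons.d_arm and cons.arm_pair_counts()["D"] == 4


def test_consensus_short_alignment_rejected(template):
    with pytest.raises(ValueError):
        build_consensus_structure({"t1": "ACGU"}, template)


def test_forced_stem_sizes_enforced():
    with pytest.raises(ValueError, match="acceptor"):
        CloverleafMap(trna="trnA", pairs=[(0, 10, "acceptor")] * 1)


# ---------------------------------------------------------------------------
# tallies

def _manual_quartet_reconstruction():
    """Hand-built ancestral alignment over one 14-column mini-cloverleaf.

    Uses a map with only the forced stems (7 acceptor + 5 anticodon
    pairs); columns 0..6 pair with 27..21, columns 8..12 with 19..15.
    """
    tree = read_newick("((A,B)N2,(C,D)N3)N1;")
    pairs = [(k, 27 - k, "acceptor") for k in range(7)] + \
            [(8 + k, 19 - k, "anticodon") for k in range(5)]
    cmap = CloverleafMap(trna="trnX", pairs=pairs, d_arm=False, t_arm=False)
    base = list("AAAAAAA" + "U" + "GGGGG" + "UU" + "CCCCC" + "U" + "UUUUUUU")
    assert len(base) == 28
    root = "".join(base)
    # N2 subtree gains an FCBC at acceptor pair (0, 27): A:U -> G:C
    n2 = list(root)
    n2[0], n2[27] = "G", "C"
    # D gains an HCBC at anticodon pair (8, 19): G:C -> U:C? no, make G:C -> G:U
    d_row = list(n2)
    d_seq = list(root)
    d_seq[19] = "U"
    seqs = {
        "N1": root, "N2": "".join(n2), "N3": root,
        "A": "".join(n2), "B": "".join(n2),
        "C": root, "D": "".join(d_seq),
    }
    aa = AncestralAlignment(sequences=seqs, scores=[0] * 28, tree=tree)
    return tree, cmap, aa


def test_tally_hand_constructed_case():
    tree, cmap, aa = _manual_quartet_reconstruction()
    tal = tally_cbc({"trnX": aa}, {"trnX": cmap}, tree)
    recs = tal.records
    assert len(recs) == 2
    fcbc = recs[recs.category == "FCBC"].iloc[0]
    assert fcbc.branch == "N2" and fcbc.branch_class == "internal"
    assert fcbc.subst_type == "AU -> GC" and fcbc.arm == "acceptor"
    hcbc = recs[recs.category == "HCBC"].iloc[0]
    assert hcbc.branch == "D" and hcbc.branch_class == "external"
    assert hcbc.subtype == "result_wobble" and hcbc.arm == "anticodon"
    assert tal.change_count() == 2 * 1 + 1  # FCBC counts two base changes
    assert tal.loop_changes.empty


def test_tally_no_changes_is_empty(quartet_tree):
    aln = {l: "A" * 69 for l in "ABCD"}
    aa = fitch_ancestral(aln, quartet_tree)
    tal = tally_cbc({"trnA": aa}, {"trnA": default_trna_template("trnA")}, quartet_tree)
    assert tal.records.empty and tal.loop_changes.empty


def test_tally_category_partition_on_simulated_data(cfg, template):
    rng = cfg.rng()
    tree = simulate_tree(cfg, rng)
    aln, _log = simulate_trna(cfg, tree, template, rng)
    aa = fitch_ancestral(aln, tree)
    tal = tally_cbc({"trnA": aa}, {"trnA": template}, tree)
    # every record is exactly one category
    assert set(tal.records.category) <= {"FCBC", "HCBC", "indel"}
    cat_totals = tal.by_category()
    if not cat_totals.empty:
        assert cat_totals["total"].sum() == len(tal.records)


def test_excluded_trnas_are_skipped(cfg, template):
    rng = cfg.rng()
    tree = simulate_tree(cfg, rng)
    aln, _ = simulate_trna(cfg, tree, template, rng)
    aa = fitch_ancestral(aln, tree)
    tal = tally_cbc({"trnA": aa}, {"trnA": template}, tree, exclude=("trnA",))
    assert tal.records.empty


# ---------------------------------------------------------------------------
# pairwise matrix

def test_pairwise_identical_sequences_zero(template):
    aln = {"x": "A" * 69, "y": "A" * 69}
    m = pairwise_cbc_matrix({"trnA": aln}, {"trnA": template}, exclude=())
    assert (m.values == 0).all()


def test_pairwise_engineered_single_swap(template):
    i, j, _ = template.pairs[0]
    sx = list("A" * 69)
    sy = list("A" * 69)
    sx[i], sx[j] = "A", "U"
    sy[i], sy[j] = "G", "C"
    m = pairwise_cbc_matrix({"trnA": {"x": "".join(sx), "y": "".join(sy)}},
                            {"trnA": template}, exclude=())
    assert m.loc["x", "y"] == 1 and m.loc["y", "x"] == 1


def test_pairwise_matrix_matches_enumeration_oracle(cfg, template):
    rng = cfg.rng()
    tree = simulate_tree(cfg, rng)
    aln, _ = simulate_trna(cfg, tree, template, rng)
    m = pairwise_cbc_matrix({"trnA": aln}, {"trnA": template}, exclude=())
    oracle = pairwise_cbc_by_enumeration(aln, template.pairs)
    for (x, y), v in oracle.items():
        assert m.loc[x, y] == v
    assert (np.diag(m.values) == 0).all()
    assert (m.values == m.values.T).all()


def test_duplicate_taxon_gives_zero_row(template):
    rng = np.random.default_rng(2)
    cfg = SimConfig(seed=2, n_taxa=5)
    tree = simulate_tree(cfg, rng)
    aln, _ = simulate_trna(cfg, tree, template, rng)
    taxon = sorted(aln)[0]
    aln2 = dict(aln)
    aln2["dup"] = aln[taxon]
    m = pairwise_cbc_matrix({"trnA": aln2}, {"trnA": template}, exclude=())
    assert m.loc["dup", taxon] == 0


# ---------------------------------------------------------------------------
# stems vs loops

def test_stem_loop_stats_match_base_stats(template):
    rng = np.random.default_rng(3)
    aln = {f"t{i}": "".join(rng.choice(list("ACGU"), size=69)) for i in range(5)}
    stems, loops = stem_loop_stats({"trnA": aln}, {"trnA": template})
    paired = template.paired_columns()
    stem_chars = "".join(s[k] for s in aln.values() for k in sorted(paired))
    loop_chars = "".join(s[k] for s in aln.values() for k in range(69) if k not in paired)
    assert stems == base_stats(stem_chars)
    assert loops == base_stats(loop_chars)


def test_simulated_loops_are_at_richer_than_stems(cfg, template):
    rng = cfg.rng()
    tree = simulate_tree(cfg, rng)
    aln, _ = simulate_trna(cfg, tree, template, rng)
    stems, loops = stem_loop_stats({"trnA": aln}, {"trnA": template})
    assert loops.at_percent > stems.at_percent
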