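"""Composition statistics: skews, ENC, MILC, GC3, amino-acid frequencies."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from Bio.Seq import Seq

from mitocomp import composition as comp
from mitocomp.genome_io import CDSRecord, extract_cds
from mitocomp.synthetic_data import SimConfig, generate_toy_mitogenome

SENSE = comp.sense_codons(5)


@pytest.mark.parametrize("seq,at_skew", [("AATT", 0.0), ("AAAT", 0.5)])
def test_at_skew_examples(seq, at_skew):
    assert comp.base_stats(seq).at_skew == pytest.approx(at_skew)


def test_base_stats_against_letter_counts():
    rng = np.random.default_rng(42)
    seq = "".join(rng.choice(list("ACGTN"), size=1000))
    c = Counter(seq)
    s = comp.base_stats(seq)
    assert s.at_percent == pytest.approx(
        100 * (c["A"] + c["T"]) / (c["A"] + c["C"] + c["G"] + c["T"]))
    assert s.at_skew == pytest.approx((c["A"] - c["T"]) / (c["A"] + c["T"]))
    assert s.gc_skew == pytest.approx((c["G"] - c["C"]) / (c["G"] + c["C"]))
    assert s.n_sites == c["A"] + c["C"] + c["G"] + c["T"]


def test_base_stats_empty_is_missing():
    s = comp.base_stats("NNN-")
    assert math.isnan(s.at_skew) and math.isnan(s.gc_skew) and s.n_sites == 0


@settings(max_examples=60, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=4, max_size=200))
def test_reverse_complement_negates_skews(seq):
    fwd = comp.base_stats(seq)
    rev = comp.base_stats(str(Seq(seq).reverse_complement()))
    assert rev.at_percent == pytest.approx(fwd.at_percent)
    if not math.isnan(fwd.at_skew):
        assert rev.at_skew == pytest.approx(-fwd.at_skew)
    if not math.isnan(fwd.gc_skew):
        assert rev.gc_skew == pytest.approx(-fwd.gc_skew)


# ---------------------------------------------------------------------------
# ENC

def test_enc_uniform_usage_is_62():
    counts = {c: 1000 for c in SENSE}
    assert comp.enc(counts) == pytest.approx(62.0)


def test_enc_one_codon_per_family_equals_family_count():
    fams = comp._families(5)
    counts = {codons[0]: 500 for codons in fams.values()}
    assert comp.enc(counts) == pytest.approx(len(fams), abs=1e-9)


def _enc_oracle(counts):
    """Independent transcription of the homozygosity formula."""
    fams = comp._families(5)
    f_by_size = {}
    n_fams_by_size = {}
    for aa, codons in fams.items():
        size = len(codons)
        n_fams_by_size[size] = n_fams_by_size.get(size, 0) + 1
        n = sum(counts.get(c, 0) for c in codons)
        if n >= 2:
            ssq = sum((counts.get(c, 0) / n) ** 2 for c in codons)
            f = (n * ssq - 1) / (n - 1)
            if f > 0:
                f_by_size.setdefault(size, []).append(f)
    total = 0.0
    for size, nf in n_fams_by_size.items():
        fs = f_by_size.get(size)
        assert fs, "oracle only covers fully observed tables"
        total += nf / (sum(fs) / len(fs))
    return min(total, 62.0)


def test_enc_matches_independent_formula_on_random_tables():
    rng = np.random.default_rng(7)
    for _ in range(10):
        counts = {c: int(rng.integers(2, 50)) for c in SENSE}
        assert comp.enc(counts) == pytest.approx(_enc_oracle(counts))


def test_enc_decreases_with_codon_bias():
    """Concentrating usage within families lowers ENC monotonically."""
    fams = comp._families(5)
    values = []
    for bias in (0.0, 0.3, 0.6, 0.9):
        counts = {}
        for codons in fams.values():
            r = len(codons)
            share = [(1 - bias) / r] * r
            share[0] += bias
            for c, p in zip(codons, share):
                counts[c] = int(round(6000 * p / r))
        values.append(comp.enc(counts))
    assert all(a >= b for a, b in zip(values, values[1:]))
    assert values[0] > values[-1]


# ---------------------------------------------------------------------------
# MILC

def test_milc_uniform_usage_near_half():
    counts = {c: 1000 for c in SENSE}
    assert comp.milc(counts) == pytest.approx(0.5, abs=0.02)


def test_milc_single_family_observed_equals_expected():
    fams = comp._families(5)
    leu = fams["L"]
    counts = {c: 120 for c in leu}  # observed == uniform expectation: sum M_a = 0
    L = 120 * len(leu)
    expected_correction = (len(leu) - 1) / L - 0.5
    assert comp.milc(counts) == pytest.approx(0.0 - expected_correction)


def _milc_oracle(counts, fams):
    L = sum(counts.values())
    m = 0.0
    dof = 0
    for aa, codons in fams.items():
        n = sum(counts.get(c, 0) for c in codons)
        if n == 0:
            continue
        dof += len(codons) - 1
        for c in codons:
            o = counts.get(c, 0)
            if o:
                m += 2 * o * math.log((o / n) / (1 / len(codons)))
    return m / L - (dof / L - 0.5)


def test_milc_matches_direct_formula_on_biased_tables():
    rng = np.random.default_rng(3)
    fams = comp._families(5)
    for _ in range(10):
        counts = {c: int(rng.integers(0, 40)) for c in SENSE}
        if sum(counts.values()) == 0:
            continue
        assert comp.milc(counts) == pytest.approx(_milc_oracle(counts, fams))


def test_milc_zero_expected_frequency_rejected():
    counts = {"TTA": 5}
    expected = {"TTA": 0.0}
    with pytest.raises(ValueError):
        comp.milc(counts, expected=expected)


# ---------------------------------------------------------------------------
# GC3 / amino acids

def test_gc3_fourfold_extremes():
    # GCx: alanine, fourfold under the invertebrate mitochondrial code
    assert comp.gc3_fourfold(["GCTGCT"]) == 0.0
    assert comp.gc3_fourfold(["GCGGCG"]) == 1.0
    assert math.isnan(comp.gc3_fourfold(["TTTAAA"]))  # Phe/Lys are twofold


def test_aa_frequencies_leucine_only():
    rec = CDSRecord(gene="x", taxon="t", seq="TTATTA", strand="+")
    freqs = comp.aa_frequencies([rec])
    assert freqs.loc["L", "pooled"] == pytest.approx(1.0)


def test_aa_frequencies_match_translation_counts():
    rng = np.random.default_rng(5)
    codons = [SENSE[k] for k in rng.integers(0, len(SENSE), size=300)]
    rec = CDSRecord(gene="x", taxon="t", seq="".join(codons), strand="+")
    freqs = comp.aa_frequencies([rec])
    translated = str(Seq(rec.seq).translate(table=5))
    counts = Counter(translated)
    for aa, n in counts.items():
        assert freqs.loc[aa, "pooled"] == pytest.approx(n / len(translated))
    assert freqs["pooled"].sum() == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# genome partition report

def test_partition_report_conserves_letter_counts(toy_genome):
    genome, _ = toy_genome
    rep = comp.partitioned_composition(genome).set_index("partition")
    gene_rows = rep[rep.index.str.startswith(("gene:", "CR:"))]
    # toy features tile the genome exactly
    assert gene_rows.n_sites.sum() == len(genome.sequence)
    whole = rep.loc["whole_genome"]
    pooled_at = (gene_rows.at_percent * gene_rows.n_sites).sum() / gene_rows.n_sites.sum()
    assert pooled_at == pytest.approx(whole.at_percent)


def test_partition_report_third_positions_track_gc3(toy_genome):
    genome, _ = toy_genome
    rep = comp.partitioned_composition(genome).set_index("partition")
    at3 = rep.loc["codon_pos3:plus"].at_percent
    assert at3 == pytest.approx(100 * (1 - SimConfig().gc3), abs=4.0)


def test_codon_usage_table_per_gene(toy_genome):
    genome, _ = toy_genome
    table = comp.gene_codon_usage(extract_cds(genome))
    assert len(table) == 13
    assert ((table.enc > 20) & (table.enc <= 62)).all()
    assert table.gc3_4fold.between(0, 1).all()
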