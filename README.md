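# mitocomp

Comparative mitogenomics for small clades: nucleotide composition and
codon usage partitioned by gene, codon position and coding strand;
rearrangement analysis of circular signed gene orders; compensatory base
changes (CBCs) in tRNA stems over a phylogeny; congruence between
CBC-derived clustering and the species tree; and physicochemical
selection scans on protein-coding genes.

The package targets the kind of question raised by intrageneric
mitogenome datasets — for example freshwater amphipods, where a handful
of closely related mitogenomes differ by one or two gene-order events,
tRNA stems accumulate paired substitutions, and a few oxidative
phosphorylation genes show signatures of positive selection.  Every
analysis stage is paired with a seeded synthetic-data generator that
logs its ground truth, so the whole pipeline is testable without any
sequence downloads.

## What it computes

**Composition and codon usage.** Strand asymmetry as
AT-skew = (A−T)/(A+T) and GC-skew = (G−C)/(G+C), with A+T% per gene,
codon position × strand, rRNA/tRNA pools and control regions.  Codon
usage bias via Wright's effective number of codons generalized to the
invertebrate mitochondrial code (ENC = 62 means all sense codons used
equally), MILC (≈0.5 under uniform usage; larger is more biased), and
G+C at third positions of fourfold-degenerate codons (GC3).

**Gene orders.** A genome's 37 genes form a circular signed permutation
(sign = coding strand).  The package computes signed breakpoint
distances, maximal conserved blocks, and shortest rearrangement
scenarios over four event types — reversal, transposition, reverse
transposition (block moves to the opposite strand) and tandem
duplication–random loss (TDRL) — by exhaustive circular search up to a
small event bound.

**tRNA stem CBCs.** Cloverleaf maps pair alignment columns into
acceptor, D, anticodon and T arms (acceptor 7 pairs, anticodon stem 5;
D/T arms by 50% majority rule).  Of the 16 base duples only six are
stable (Watson–Crick AU, UA, GC, CG and wobble GU, UG).  After Fitch
parsimony reconstruction on a fixed rooted tree, every changed stem
pair on every branch is classified as a full compensatory change (FCBC,
both bases changed, e.g. AU → GC), a hemi-compensatory change (HCBC,
one base changed, e.g. AU → GU), or an indel, with subtypes for the
resulting pair class, tallied by arm and by internal/external branch.
A tree-free pairwise CBC matrix supports hierarchical clustering, whose
agreement with the species tree is scored by Baker's γ (Spearman
correlation of pairwise coalescence depths; 1 = identical hierarchies)
and visualized as a tanglegram.

**Selection.** Amino-acid replacements inferred per branch are binned
into 8 equal-width magnitude categories of physicochemical property
change (per property: pK1 of the α-COOH group, isoelectric point,
solvent-accessibility reduction, buriedness, surrounding
hydrophobicity, non-bonded energy, surrounding residues).  The neutral
baseline p_k comes from enumerating every single-nucleotide
nonsynonymous codon change; categories with
z = (o_k − Np_k)/√(Np_k(1−p_k)) > 3.09 in the radical categories 7–8
flag positive destabilizing selection.  ω = dN/dS is estimated by
Nei–Gojobori (1986) counting with Jukes–Cantor correction.

## Worked example

The numbered scripts under `analysis/` run the full study on synthetic
data (seed 1 by default) and write tables under `results/`:

```
python analysis/01_simulate_dataset.py
python analysis/02_composition_analysis.py
python analysis/03_gene_order_analysis.py
python analysis/04_trna_cbc_analysis.py
python analysis/05_congruence_analysis.py
python analysis/06_selection_analysis.py
```

Output from a run at seed 1:

```
wrote results/simdata: 22 tRNA alignments (288 logged stem events), tree with
  16 taxa, toy genome of 15299 bp, 2 gene-order events
whole-genome A+T 65.8%; third codon positions (plus strand) A+T 72.1%,
  AT-skew -0.186, GC-skew +0.179
breakpoint distance 4; 4 conserved blocks; shortest scenario: 2 events
  (reversal, reverse_transposition); replay check passed
recovered 79 FCBC (truth 84, ratio 0.94) and 195 HCBC (truth 204, ratio 0.96)
Baker's gamma (CBC clustering vs species tree): 0.923; tanglegram crossings
  after untangling: 0
detected 205 nonsynonymous replacements (truth 211); properties flagged in
  radical categories 7-8: none (neutral simulation)
```

Reading these numbers: the generator planted 2 rearrangement events and
the search recovers a valid 2-event scenario; parsimony re-detects 94%
of the planted full-compensatory and 96% of the hemi-compensatory stem
events at the default shallow divergence; clustering the pairwise CBC
counts reproduces the species tree closely (γ = 0.92); and on neutral
simulations the 3.09 z-threshold flags nothing, as it should.

## Layout

```
src/mitocomp/      library: genome_io, composition, gene_order, ancestry,
                   trna_cbc, congruence, selection_props, synthetic_data
analysis/          numbered narrative drivers over the library
tests/             pytest suite incl. brute-force oracle comparisons
scripts/           acceptance script
docs/methods.md    models, assumptions, parameter choices, limitations
```
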