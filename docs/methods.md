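# Methods

This note documents the models, conventions and numerical choices behind
`mitocomp`, what the synthetic-data generator does and does not emulate,
and the known limitations of each stage.

## Coordinates, tokens and gene orders

Internally all feature coordinates are 0-based half-open on the plus
strand; GenBank and feature-table interchange is 1-based inclusive.  A
feature spanning the origin of the circular molecule stores end < start
with a wrap flag and counts as one feature.  Gene names are normalized
through an editable synonym table (`data/gene_synonyms.tsv`) onto a
fixed 37-token vocabulary (13 protein-coding genes, 22 tRNAs with
trnL1/trnL2 and trnS1/trnS2, 2 rRNAs) plus CR1/CR2 for control regions.

A gene order is a circular signed permutation.  The canonical
representative rotates cox1 to the front, flipping every sign first if
cox1 is on the minus strand.  The sign flip is a *reporting* convention
(published gene maps start at plus-strand cox1), not a biological
symmetry of the oriented circle, and is applied consistently on both
sides of every comparison.  Strand counts exclude control regions, so a
complete genome always splits its 37 genes between the strands.

## Rearrangement model

Events are reversal, transposition, reverse transposition, and tandem
duplication–random loss (TDRL).  An event record carries a rotation
offset plus linear indices, so a single event can act on any circular
block, including blocks spanning the chosen origin; classification
enumerates circular candidates exhaustively (reversals by
rotation × length; transpositions as swaps of adjacent circular blocks;
reverse transpositions in both moved-block variants).

Single-TDRL reachability uses the concatenation criterion: duplicating
the whole circle in tandem and deleting one copy of each gene yields
the concatenation of two subsequences that are each increasing in the
source order, i.e. the target (written in source positions after
linearizing at the canonical origin) has at most one descent.  Signs
are unchanged by TDRL.

Scenario search is exact for 0–1 events over all four kinds.  Two-event
scenarios use meet-in-the-middle over the enumerable kinds with a
terminal TDRL test on both frontiers; two-TDRL scenarios are therefore
not found (TDRL neighborhoods grow exponentially), which matters little
in practice because a TDRL pair at this scale is indistinguishable from
shorter explanations.  Three/four-event search is plain BFS and is
limited to ≤ 8 tokens; at 37 genes the two-event search completes in a
few seconds on one CPU.  Equally short scenarios are reported with the
fixed priority reversal > transposition > reverse transposition > TDRL
and leftmost-block tie-break, so output is deterministic.

## Composition and codon-usage statistics

Skews are (A−T)/(A+T) and (G−C)/(G+C); ambiguity codes and gaps are
excluded from every count, and a zero denominator reports NaN rather
than a value.  Statistics for minus-strand genes are computed on the
gene's sense strand; genome-level partitions use the plus strand.
Codon-position pools are split by coding strand.

ENC follows Wright's homozygosity estimator, generalized to the actual
synonymous-family structure of the genetic code in use — under the
invertebrate mitochondrial code (translation table 5) serine has eight
codons and leucine six, so the uniform-usage ceiling is exactly 62, the
number of sense codons.  Families with fewer than two observed codons
are omitted from their family-size class; an empty class is imputed by
reciprocal-mean interpolation between neighbouring classes (uniform
1/size as a last resort).  The estimate is capped at the sense-codon
count.

MILC sums, per amino-acid family, 2·Σ o_c·ln(f_c/g_c) over observed
codons (f observed within-family frequencies, g expected) and applies
the length correction Σ(r_a−1)/L − 0.5.  The default expectation is
uniform within each family, under which uniform usage scores ≈ 0.5; a
background-frequency expectation can be supplied instead.  GC3 is the
G+C fraction at third positions of codons whose whole third-position
box is synonymous.  Stop codons are excluded from usage tables and
translations.

## Ancestral reconstruction

Ancestral states on the fixed rooted topology use two-pass Fitch
parsimony with uniform cost and the gap as a fifth character state, so
stem indels are reconstructed and countable.  Determinism comes from
fixed tie-breaks: a non-root node keeps its parent's state when
possible, otherwise takes the first state of its own set in the order
A < C < G < T/U < gap.  A root tie prefers states shared with the
root's leftmost child, then alphabet order.  The child-preferring root
policy matters for paired sites: a purely alphabetical choice can
resolve the two columns of one stem pair toward *different* root
children, splitting a single compensatory double change into two
apparent single changes on opposite root branches; anchoring both
columns to the same child keeps co-occurring changes on one branch.
Either policy yields the same parsimony score.

Parsimony undercounts on long branches and cannot place changes more
finely than the tree resolves; the package treats shallow intrageneric
divergence as its validated regime and measures the bias against
simulations (below).  Branch classes follow the child endpoint:
external when the child is a leaf, internal otherwise.

## tRNA structures and CBC classification

Cloverleaf maps pair alignment columns with arm labels.  Acceptor (7
pairs) and anticodon (5 pairs) stems are fixed at template positions
even across mismatches; each D-/T-arm candidate pair is kept only when
at least 50% of sequences have both positions ungapped, and an arm with
no surviving pairs is absent (as for the D-arm of tRNA-S1 and tRNA-V).

A changed stem pair on a branch is classified once: FCBC when both
bases changed and no gap is involved, HCBC when exactly one changed,
indel when any gap is involved (an indel-plus-substitution pair change
counts as indel).  Subtypes record Watson–Crick switches versus
stability gains/losses for FCBCs and the resulting pair class for
HCBCs; a single-base change producing a mismatch (e.g. AU → AC) is an
HCBC with subtype `result_mismatch`, so both the inclusive and the
strict readings of "hemi-compensatory" are recoverable.  One FCBC is
one event; the convenience count of base changes weighs it twice.
Changes at unpaired columns are loop changes.  Cross-species analyses
exclude tRNA-C, tRNA-Y and tRNA-M by default (families that commonly
abut repeat-rich control regions and drop out of assemblies); the
exclusion list is a parameter.

The tree-free pairwise matrix counts, per taxon pair and paired column,
sites where both bases differ and both duples are stable (FCBC-only
default; a flag admits any stable-to-stable difference).  This matrix
is a divergence measure and is clustered directly as a dissimilarity;
a similarity flag (max − value conversion) exists for matrices that are
genuinely similarity-like.

## Congruence

Hierarchical clustering is standard agglomerative linkage (complete by
default, the common default of heatmap tooling; average and single
available).  Baker's γ correlates, over all leaf pairs, the depth at
which the pair coalesces in each hierarchy: merge-step ranks for
dendrograms, topological node depth (internal nodes on the root path)
for phylogenies, so branch lengths are never required.  Spearman ties
get average ranks.  Because merge steps are all distinct while
topological depths tie, a dendrogram compared against an identical
*topology* scores slightly below 1; two identical dendrograms score
exactly 1.  Tanglegram untangling greedily flips internal nodes on both
sides until no flip reduces crossings; with ≤ 20 leaves this reaches
the optimum or close to it, and the crossing count is reported with the
matched leaf orders.

## Selection scan and dN/dS

The magnitude model enumerates every (sense codon, single-nucleotide
sense mutant) pair with different encoded amino acids under translation
table 5, uniformly weighted, and splits the |Δproperty| range into 8
equal-width categories; the enumeration frequencies are the neutral
category probabilities p_k.  A constant property degenerates to all
mass in category 1.  Property values ship in `data/aa_properties.csv`
with provenance notes in its header; the two energy-like columns are
approximate literature compilations, and every downstream statistic is
computed from whatever table is shipped, so substituting a different
compilation is safe.

Branch replacements come from codon-wise Fitch states; codons touched
by gaps are skipped, and multi-nucleotide codon changes are decomposed
over minimal single-step paths avoiding stops where possible, each path
weighted equally.  The per-category z-score uses the binomial normal
approximation; 3.09 corresponds to one-sided P ≈ 0.001.  At realistic
substitution counts (N p_k of order 10) the binomial's right skew
inflates the realized false-positive rate to 1–3 × 10⁻³; the
Monte-Carlo calibration in the acceptance suite pins this, and the
statistic becomes indistinguishable from standard normal at large
counts.  The sliding-window track (default 20 codons, step 1) applies
the same statistic within windows for the radical categories only.

ω uses Nei–Gojobori counting: per-codon synonymous/nonsynonymous site
fractions (mutations to stops excluded from the opportunities),
pathway-averaged differences, Jukes–Cantor correction, ω = dN/dS.  ω is
NaN when dS = 0 or a correction saturates (p ≥ 3/4).  The
implementation agrees to machine precision with an independent
enumeration and with Biopython's NG86 routine.  Likelihood-based
branch-site models are out of scope; branch labels only partition the
z-scan.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the analyses consume,
under one seed that fixes every stream:

- **Tree**: Yule pure-birth on 16 taxa by default, rescaled to
  root-to-tip depth 0.08 substitutions/site — the shallow intrageneric
  regime in which parsimony reconstruction is validated.
- **tRNA stems** evolve as paired duples: FCBC events jump between
  stable pairs changing both bases, HCBC events change one base to a
  stable pair, mismatch events change one base to an unstable pair,
  indel events gap one position; counts are Poisson(rate × branch
  length) per pair with defaults 0.4/0.8/0.15/0.03 per unit length.
  Loops evolve independently with an A/U bias of 0.78, against a stem
  A+U of 0.66 — reproducing the ~10–15 point stem/loop A+T contrast
  reported for crustacean mitochondrial tRNAs.
- **Codon sequences** draw third positions G/C with probability GC3
  (default 0.28, i.e. third-position A+T ≈ 72%) and skews
  AT₃ = −0.17, GC₃ = +0.135; first/second positions are
  composition-driven with the TA dicodon prefix excluded, which makes
  stop codons impossible by construction and the realized GC3 exactly
  the target.  The cost is that synthetic proteins contain no tyrosine
  — irrelevant for composition statistics, visible in amino-acid
  frequency tables.
- **Toy genomes** assemble 37 genes plus two control regions in the
  ancestral pancrustacean arrangement (23 plus- and 14 minus-strand
  genes), with realistic gene lengths; **gene orders** are scrambled by
  a configurable event mix, two events (a reverse transposition plus a
  reversal) by default.
- **Codon alignments** evolve by uniform point mutation with nonsense
  changes rejected, each fixed replacement logged.

Not emulated: realistic indel length spectra, rate heterogeneity among
sites or lineages, selection-driven codon usage, saturated divergence,
and alignment error (the generator emits true alignments).  Passing
tests therefore demonstrate correctness of the *measurement* machinery
and its calibration at shallow divergence, not robustness to alignment
or saturation artifacts in real data.

Measured against the truth logs at the default conditions: FCBC and
HCBC tallies recover 91–97% of planted events (residual loss is
multiple hits on the same pair, which parsimony cannot separate);
amino-acid replacement recovery exceeds 95%; γ between CBC clustering
and the generating tree is strongly positive (typically 0.6–1.0); and
planted two-event rearrangements always admit a valid two-event
scenario.

## Interfaces and problem sizes

The library is the interface: the numbered scripts under `analysis/`
are thin drivers over it, and all formats are plain text (GenBank,
FASTA, tab-separated tables, newick, JSON).  No console-script entry
point is installed.  Default problem sizes — 16 taxa, 22 tRNA families
of ~69 columns, a 1.7 kb codon alignment, 37-gene circles, 10⁴
Monte-Carlo replicates — run the whole pipeline, test suite and
acceptance script in well under a minute each on one CPU.
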