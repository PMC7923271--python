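"""Reading, writing and dissecting annotated mitochondrial genomes.

Internal coordinates are 0-based half-open on the plus strand; GenBank and
feature-table input/output is 1-based inclusive.  A feature that spans the
origin of the circular molecule carries ``wraps=True`` and has end < start
after normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, CompoundLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .gene_order import SignedGeneOrder

__all__ = [
    "GeneFeature",
    "Mitogenome",
    "GENE_TOKENS",
    "PCG_TOKENS",
    "TRNA_TOKENS",
    "RRNA_TOKENS",
    "CR_TOKENS",
    "read_genbank",
    "write_genbank",
    "read_fasta_features",
    "write_fasta_features",
    "extract_gene_order",
    "extract_cds",
    "audit_start_stop_codons",
]

PCG_TOKENS = frozenset(
    ["cox1", "cox2", "cox3", "cob", "atp6", "atp8",
     "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6"]
)
RRNA_TOKENS = frozenset(["rrnS", "rrnL"])
TRNA_TOKENS = frozenset(
    "trn" + x for x in
    ["A", "C", "D", "E", "F", "G", "H", "I", "K", "L1", "L2", "M",
     "N", "P", "Q", "R", "S1", "S2", "T", "V", "W", "Y"]
)
CR_TOKENS = frozenset(["CR1", "CR2"])
#: the fixed 37-gene mitochondrial vocabulary (control regions excluded)
GENE_TOKENS = PCG_TOKENS | RRNA_TOKENS | TRNA_TOKENS

CANONICAL_STARTS = frozenset(["ATG", "ATA"])
ALTERNATIVE_STARTS = frozenset(["ATT", "ATC", "GTG", "TTG", "CTG", "GTA"])
COMPLETE_STOPS = frozenset(["TAA", "TAG"])


def _kind_of(token: str) -> str:
    if token in PCG_TOKENS:
        return "PCG"
    if token in TRNA_TOKENS:
        return "tRNA"
    if token in RRNA_TOKENS:
        return "rRNA"
    if token in CR_TOKENS:
        return "CR"
    return "other"


@dataclass
class GeneFeature:
    token: str
    start: int  # 0-based
    end: int    # half-open; end < start iff wraps
    strand: str  # '+' or '-'
    kind: str
    wraps: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not self.wraps and not (0 <= self.start < self.end):
            raise ValueError(f"bad coordinates for {self.token}: [{self.start}, {self.end})")

    def length(self, genome_length: int) -> int:
        if self.wraps:
            return genome_length - self.start + self.end
        return self.end - self.start


@dataclass
class Mitogenome:
    id: str
    taxon: str
    sequence: str
    circular: bool = True
    complete: bool = True
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty genome sequence")
        n = len(self.sequence)
        for f in self.features:
            hi = f.start if f.wraps else f.end
            if not (0 <= f.start <= n and 0 <= f.end <= n):
                raise ValueError(f"feature {f.token} outside genome bounds")
        non_cr = [f.token for f in self.features if f.kind != "CR"]
        if len(set(non_cr)) != len(non_cr):
            dup = sorted({t for t in non_cr if non_cr.count(t) > 1})
            raise ValueError(f"duplicate gene features: {dup}")

    def feature_seq(self, f: GeneFeature) -> str:
        """Sense-strand (coding) sequence of a feature, unwrapping the origin."""
        if f.wraps:
            raw = self.sequence[f.start:] + self.sequence[:f.end]
        else:
            raw = self.sequence[f.start:f.end]
        if f.strand == "-":
            return str(Seq(raw).reverse_complement())
        return raw

    def get(self, token: str) -> GeneFeature:
        for f in self.features:
            if f.token == token:
                return f
        raise KeyError(token)

    def has_all_37(self) -> bool:
        return GENE_TOKENS <= {f.token for f in self.features}


# ---------------------------------------------------------------------------
# synonym table

def _load_synonyms() -> dict[str, str]:
    text = resources.files("mitocomp.data").joinpath("gene_synonyms.tsv").read_text()
    table: dict[str, str] = {}
    for line in text.splitlines():
        if not line or line.startswith("#") or line.startswith("synonym\t"):
            continue
        syn, token = line.split("\t")
        table[syn] = token
    return table


_SYNONYMS: Optional[dict[str, str]] = None


def _normalize_label(label: str) -> str:
    out = []
    for ch in label.lower():
        if ch.isalnum():
            out.append(ch)
    return "".join(out)


def map_gene_label(label: str) -> Optional[str]:
    """Map an annotation label (gene/product qualifier) to a standard token."""
    global _SYNONYMS
    if _SYNONYMS is None:
        _SYNONYMS = _load_synonyms()
    return _SYNONYMS.get(_normalize_label(label))


# ---------------------------------------------------------------------------
# GenBank

_GB_KIND = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA",
            "D-loop": "CR", "misc_feature": "CR"}


def read_genbank(path) -> list[Mitogenome]:
    """Parse a GenBank flat file of mitogenome records.

    Feature labels are mapped through the synonym table; unmappable
    features trigger a warning and are kept with the kind implied by the
    feature key and their raw label as token.
    """
    genomes = []
    for rec in SeqIO.parse(str(path), "genbank"):
        seq = str(rec.seq).upper()
        if len(seq) == 0:
            raise ValueError(f"zero-length record {rec.id}")
        feats: list[GeneFeature] = []
        cr_seen = 0
        for ft in rec.features:
            if ft.type not in _GB_KIND:
                continue
            label = (ft.qualifiers.get("gene") or ft.qualifiers.get("product")
                     or ft.qualifiers.get("note") or ["?"])[0]
            token = map_gene_label(label)
            kind = _GB_KIND[ft.type]
            if token is None:
                warnings.warn(f"{rec.id}: unmappable feature label {label!r}; kept as-is")
                token = label
            if token in CR_TOKENS:
                kind = "CR"
                cr_seen += 1
                if cr_seen == 2 and token == "CR1":
                    token = "CR2"
            else:
                kind = _kind_of(token) if token in GENE_TOKENS else kind
            loc = ft.location
            strand = "-" if loc.strand == -1 else "+"
            wraps = False
            if isinstance(loc, CompoundLocation) and len(loc.parts) == 2:
                p1, p2 = sorted(loc.parts, key=lambda p: int(p.start))
                if int(p2.end) == len(seq) and int(p1.start) == 0:
                    feats.append(GeneFeature(token, int(p2.start), int(p1.end), strand, kind, wraps=True))
                    continue
            feats.append(GeneFeature(token, int(loc.start), int(loc.end), strand, kind))
        feats.sort(key=lambda f: f.start)
        complete = GENE_TOKENS <= {f.token for f in feats}
        genomes.append(Mitogenome(
            id=rec.id, taxon=rec.annotations.get("organism", rec.description),
            sequence=seq,
            circular=rec.annotations.get("topology", "circular") == "circular",
            complete=complete, features=feats))
    if not genomes:
        raise ValueError(f"no GenBank records parsed from {path}")
    return genomes


def write_genbank(genomes: Iterable[Mitogenome], path) -> None:
    records = []
    for g in genomes:
        rec = SeqRecord(Seq(g.sequence), id=g.id, name=g.id[:16], description=g.taxon)
        rec.annotations["molecule_type"] = "DNA"
        rec.annotations["topology"] = "circular" if g.circular else "linear"
        rec.annotations["organism"] = g.taxon
        for f in g.features:
            strand = -1 if f.strand == "-" else 1
            ftype = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "CR": "misc_feature"}.get(f.kind, "misc_feature")
            if f.wraps:
                loc = CompoundLocation([
                    FeatureLocation(f.start, len(g.sequence), strand),
                    FeatureLocation(0, f.end, strand),
                ])
            else:
                loc = FeatureLocation(f.start, f.end, strand)
            rec.features.append(SeqFeature(loc, type=ftype, qualifiers={"gene": [f.token]}))
        records.append(rec)
    SeqIO.write(records, str(path), "genbank")


# ---------------------------------------------------------------------------
# FASTA + feature table

def read_fasta_features(fasta_path, table_path) -> Mitogenome:
    """Read one genome from a FASTA file plus a tab-separated feature table.

    Table columns: token, start, end, strand, kind; coordinates 1-based
    inclusive.  A row with start > end denotes an origin-wrapping feature.
    """
    rec = next(SeqIO.parse(str(fasta_path), "fasta"))
    seq = str(rec.seq).upper()
    tab = pd.read_csv(table_path, sep="\t", comment="#")
    feats = []
    for _, row in tab.iterrows():
        s1, e1 = int(row["start"]), int(row["end"])
        wraps = s1 > e1
        start, end = s1 - 1, e1  # to 0-based half-open
        hi = max(s1, e1)
        if hi > len(seq) or s1 < 1:
            raise ValueError(f"feature {row['token']} out of bounds 1..{len(seq)}")
        feats.append(GeneFeature(str(row["token"]), start, end, str(row["strand"]),
                                 str(row["kind"]), wraps=wraps))
    feats.sort(key=lambda f: f.start)
    taxon = rec.description.split(None, 1)[1] if " " in rec.description else rec.id
    complete = GENE_TOKENS <= {f.token for f in feats}
    return Mitogenome(id=rec.id, taxon=taxon, sequence=seq, complete=complete, features=feats)


def write_fasta_features(g: Mitogenome, fasta_path, table_path) -> None:
    SeqIO.write([SeqRecord(Seq(g.sequence), id=g.id, description=g.taxon)], str(fasta_path), "fasta")
    rows = []
    for f in g.features:
        rows.append({"token": f.token, "start": f.start + 1, "end": f.end,
                     "strand": f.strand, "kind": f.kind})
    pd.DataFrame(rows).to_csv(table_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# derived records

def extract_gene_order(g: Mitogenome, include_cr: bool = False) -> SignedGeneOrder:
    """Signed gene order around the circle, canonically rotated to cox1."""
    feats = [f for f in g.features if include_cr or f.kind != "CR"]
    if len(feats) < 1:
        raise ValueError("no features to order")
    feats = sorted(feats, key=lambda f: f.start)
    toks = tuple((f.token, -1 if f.strand == "-" else 1) for f in feats)
    return SignedGeneOrder(toks).canonicalize()


@dataclass
class CDSRecord:
    """One framed protein-coding sequence on its sense strand."""
    gene: str
    taxon: str
    seq: str
    strand: str
    truncated: bool = False  # length not a codon multiple: incomplete stop

    def codons(self) -> list[str]:
        n = len(self.seq) - len(self.seq) % 3
        return [self.seq[i:i + 3] for i in range(0, n, 3)]


def extract_cds(g: Mitogenome, code: int = 5) -> list[CDSRecord]:
    """Sense-strand coding sequences for every PCG feature.

    Minus-strand genes are reverse-complemented.  An in-frame internal stop
    raises a warning record but is not fatal (annotation slips happen).
    """
    from Bio.Data import CodonTable
    stops = set(CodonTable.unambiguous_dna_by_id[code].stop_codons)
    out = []
    for f in g.features:
        if f.kind != "PCG":
            continue
        s = g.feature_seq(f)
        rec = CDSRecord(gene=f.token, taxon=g.taxon, seq=s, strand=f.strand,
                        truncated=(len(s) % 3 != 0))
        for k, codon in enumerate(rec.codons()[:-1]):
            if codon in stops:
                warnings.warn(f"{g.id}:{f.token}: internal stop {codon} at codon {k}")
                break
        out.append(rec)
    return out


def audit_start_stop_codons(cds_set: Iterable[CDSRecord]) -> pd.DataFrame:
    """Tabulate start/stop codon usage across genes and taxa.

    Canonical starts are ATG/ATA; alternatives seen in invertebrate
    mitogenomes (ATT, ATC, GTG, TTG, CTG, GTA) are reported verbatim.
    Truncated stops are the 3'-terminal T or TA completed by
    polyadenylation.
    """
    rows = []
    for c in cds_set:
        start = c.seq[:3]
        rem = len(c.seq) % 3
        stop = c.seq[-3:] if rem == 0 else c.seq[-rem:]
        rows.append({
            "gene": c.gene, "taxon": c.taxon,
            "start_codon": start, "stop_codon": stop,
            "canonical_start": start in CANONICAL_STARTS,
            "canonical_stop": stop in COMPLETE_STOPS,
            "truncated_stop": rem != 0,
        })
    return pd.DataFrame(rows)
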