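#!/usr/bin/env python
"""Generate the synthetic study dataset.

Emits, under results/simdata/: an annotated toy mitogenome (GenBank and
FASTA + feature table), the species tree (newick), 22 tRNA family
alignments with their ground-truth event logs, a codon alignment evolved
along the tree, scrambled gene orders, and a truth summary (JSON) that
the downstream analysis steps are scored against.
"""

import argparse
import json
from pathlib import Path

from mitocomp import genome_io
from mitocomp.synthetic_data import (SimConfig, default_trna_template, evolve_cds,
                                     generate_toy_mitogenome, scramble_gene_order,
                                     simulate_cds, simulate_tree, simulate_trna)

TRNAS = sorted("trn" + x for x in
               ["A", "C", "D", "E", "F", "G", "H", "I", "K", "L1", "L2", "M",
                "N", "P", "Q", "R", "S1", "S2", "T", "V", "W", "Y"])


def write_fasta(path: Path, rows: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in sorted(rows.items()):
            fh.write(f">{name}\n{seq}\n")


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results/simdata"))
    args = ap.parse_args()
    out = args.outdir
    (out / "trna").mkdir(parents=True, exist_ok=True)

    cfg = SimConfig(seed=args.seed)
    rng = cfg.rng()

    genome, genome_log = generate_toy_mitogenome(cfg, rng=rng)
    genome_io.write_genbank([genome], out / "toy_mitogenome.gb")
    genome_io.write_fasta_features(genome, out / "toy_mitogenome.fa",
                                   out / "toy_mitogenome_features.tsv")

    tree = simulate_tree(cfg, rng)
    (out / "tree.nwk").write_text(tree.to_newick() + "\n")

    truth = {"seed": args.seed, "trna": {}, "order_events": [],
             "codon": {"gc3": cfg.gc3, "at_skew3": cfg.at_skew3,
                       "gc_skew3": cfg.gc_skew3}}
    for trna in TRNAS:
        template = default_trna_template(trna, n_d=0 if trna in ("trnS1", "trnV") else 4)
        aln, log = simulate_trna(cfg, tree, template, rng)
        write_fasta(out / "trna" / f"{trna}.fasta", aln)
        truth["trna"][trna] = {
            "fcbc": log.stem_event_count("FCBC"),
            "hcbc": log.stem_event_count("HCBC"),
            "indel": log.stem_event_count("indel"),
            "loop_events": len(log.loop_events),
        }

    cds, _ = simulate_cds(cfg, rng)
    codon_aln, cds_log = evolve_cds(cfg, tree, cds["nad5"], rng)
    write_fasta(out / "nad5_codon_alignment.fasta", codon_aln)
    truth["codon"]["nad5_true_nonsyn"] = sum(
        1 for e in cds_log.cds_events if e["nonsynonymous"])

    order = genome_io.extract_gene_order(genome)
    scrambled, order_log = scramble_gene_order(order, cfg, rng)
    (out / "gene_orders.txt").write_text(order.to_text() + "\n" +
                                         scrambled.to_text() + "\n")
    truth["order_events"] = [e.kind for e in order_log.order_events]

    (out / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    n_events = sum(v["fcbc"] + v["hcbc"] for v in truth["trna"].values())
    print(f"wrote {out}: 22 tRNA alignments ({n_events} logged stem events), "
          f"tree with {len(tree.leaves())} taxa, toy genome of "
          f"{len(genome.sequence)} bp, {len(truth['order_events'])} gene-order events")


if __name__ == "__main__":
    main()
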