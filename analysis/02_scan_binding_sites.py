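#!/usr/bin/env python
"""Scan every circRNA for miRNA binding sites below -20 kcal/mol.

Reads the simulated FASTA inputs, runs the seed-anchored duplex-energy
scan for every (miRNA, circRNA) pair, and writes the retained sites to
results/screen/hits.tsv (and BED).
"""

import argparse
from pathlib import Path

from circsponge import scan_sites
from circsponge.energy import default_table
from circsponge.io import read_fasta, write_hits


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--indir", type=Path, default=Path("results/screen/inputs"))
    ap.add_argument("--outdir", type=Path, default=Path("results/screen"))
    ap.add_argument("--dg", type=float, default=-20.0)
    args = ap.parse_args()

    circs = read_fasta(args.indir / "circrnas.fasta")
    mirnas = read_fasta(args.indir / "mirnas.fasta")
    table = default_table()
    hits = []
    for circ in circs:
        for m in mirnas:
            hits.extend(scan_sites(m, circ, table, dg_threshold=args.dg))
    write_hits(hits, args.outdir / "hits.tsv", args.outdir / "hits.bed")

    print(f"{len(hits)} binding sites with dG < {args.dg} kcal/mol")
    if hits:
        best = min(hits, key=lambda h: h.dG)
        print(f"strongest site: {best.mirna_id} on {best.target_id} at "
              f"{best.target_span} (dG = {best.dG:.2f} kcal/mol, "
              f"{best.seed_class.value})")


if __name__ == "__main__":
    main()
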