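#!/usr/bin/env python
"""Differential expression, co-expression, and candidate nomination.

Contrasts the two cell-line groups at |log2FC| > 1.5 and P < 0.05,
selects positively co-expressed genes at Pearson r > 0.1, and
intersects the differentially expressed miRNAs with the predicted
sponge targets of the top-ranked circRNA.
"""

import argparse
from pathlib import Path

import pandas as pd

from circsponge.expression import (
    coexpression_edges,
    de_to_frame,
    differential_expression,
    intersect_candidates,
)
from circsponge.io import read_expression_tsv


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--indir", type=Path, default=Path("results/screen/inputs"))
    ap.add_argument("--outdir", type=Path, default=Path("results/screen"))
    args = ap.parse_args()

    mat = read_expression_tsv(
        args.indir / "mirna_matrix.tsv", args.indir / "mirna_groups.tsv"
    )
    de = differential_expression(mat, group_order=("TN", "luminal_her2"))
    de_to_frame(de).to_csv(args.outdir / "de_mirna.tsv", sep="\t")
    up = [r.feature_id for r in de if r.passed and r.direction == "up"]
    down = [r.feature_id for r in de if r.passed and r.direction == "down"]
    print(f"differential expression: {len(up)} miRNAs higher and "
          f"{len(down)} lower in the TN group")

    mr = read_expression_tsv(
        args.indir / "mrna_matrix.tsv", args.indir / "mrna_groups.tsv"
    )
    anchor = pd.read_csv(args.indir / "anchor_profile.tsv", sep="\t", index_col=0).iloc[:, 0]
    edges = coexpression_edges(anchor, mr, r_threshold=0.1)
    print(f"co-expression: kept {sum(e.kept for e in edges)}/{len(edges)} "
          "genes at r > 0.1")

    ranking = pd.read_csv(args.outdir / "ranking.tsv", sep="\t")
    top = ranking.iloc[0]["circ_id"]
    hits = pd.read_csv(args.outdir / "hits.tsv", sep="\t")
    predicted = set(hits.loc[hits.circ_id == top, "mirna_id"])
    nominated, counts = intersect_candidates(set(up) | set(down), predicted)
    print(f"Venn (DE only, predicted only, both): {counts}")
    print(f"nominated sponge target of {top}: {sorted(nominated)}")


if __name__ == "__main__":
    main()
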