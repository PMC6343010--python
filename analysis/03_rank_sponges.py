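#!/usr/bin/env python
"""Filter target votes and rank circRNAs by sponged disease features.

Applies the five-algorithm vote-sum filter (>= 5), scores each circRNA
by the feature classes of the disease miRNAs it sponges (sum_classes
policy), and writes the ranking plus the tripartite network.
"""

import argparse
from pathlib import Path

import networkx as nx
import pandas as pd

from circsponge.hybrid import DuplexHit, SeedClass
from circsponge.io import read_annotations_tsv, read_fasta, read_votes_tsv, write_votes_tsv
from circsponge.sponge import build_network, filter_votes, rank_circrnas, score_circrna


def load_hits(path):
    df = pd.read_csv(path, sep="\t")
    return [
        DuplexHit(
            str(r.mirna_id), str(r.circ_id), int(r.start),
            SeedClass(r.seed_class), float(r.dG_kcal_mol), str(r.pairing),
            (int(r.start), int(r.end)),
        )
        for r in df.itertuples(index=False)
    ]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--indir", type=Path, default=Path("results/screen/inputs"))
    ap.add_argument("--outdir", type=Path, default=Path("results/screen"))
    args = ap.parse_args()

    hits = load_hits(args.outdir / "hits.tsv")
    votes = read_votes_tsv(args.indir / "votes.tsv")
    annotations = read_annotations_tsv(args.indir / "annotations.tsv")
    known = {a.mirna_id for a in annotations}

    kept_votes = filter_votes(votes, min_sum=5)
    write_votes_tsv(kept_votes, args.outdir / "votes_filtered.tsv")
    print(f"vote filter kept {len(kept_votes)}/{len(votes)} miRNA->mRNA records")

    circ_ids = sorted({c.id for c in read_fasta(args.indir / "circrnas.fasta")})
    by_circ = {}
    for h in hits:
        by_circ.setdefault(h.target_id, []).append(h)
    scores = [
        score_circrna(
            cid,
            [h for h in by_circ.get(cid, []) if h.mirna_id in known],
            annotations,
        )
        for cid in circ_ids
    ]
    ranked = rank_circrnas(scores)
    pd.DataFrame(
        {
            "rank": [s.rank for s in ranked],
            "circ_id": [s.circ_id for s in ranked],
            "score": [s.score for s in ranked],
            "n_sponged": [len(s.sponged) for s in ranked],
        }
    ).to_csv(args.outdir / "ranking.tsv", sep="\t", index=False)
    top = ranked[0]
    print(f"top-ranked sponge candidate: {top.circ_id} "
          f"(score {top.score:g}, {len(top.sponged)} disease miRNAs)")

    top_hits = [h for h in hits if h.target_id == top.circ_id]
    g = build_network(top_hits, kept_votes, [f"gene_{k}" for k in range(5)])
    nx.write_graphml(g, args.outdir / "network.graphml")
    print(f"network: {g.number_of_nodes()} nodes, {g.number_of_edges()} edges")


if __name__ == "__main__":
    main()
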