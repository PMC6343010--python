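"""File I/O: FASTA, BED, TSV tables, YAML sidecars.

All coordinates written to BED are 0-based half-open; human-readable
report columns (``site_1based``) are 1-based.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .hybrid import DuplexHit, RnaSeq


def read_fasta(path) -> list[RnaSeq]:
    """Read RNA sequences (DNA alphabet is normalized T -> U)."""
    return [
        RnaSeq(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(seqs: Sequence[RnaSeq], path) -> None:
    records = [
        SeqRecord(Seq(s.seq), id=s.id, description="") for s in seqs
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_bed(path) -> dict:
    """BED3+ -> {name: [(start, end), ...]} keyed by the first column."""
    out: dict = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            out.setdefault(fields[0], []).append(
                (int(fields[1]), int(fields[2]))
            )
    return out


def write_bed(intervals: Mapping[str, Iterable[tuple]], path, name_prefix="site") -> None:
    with open(path, "w") as fh:
        for chrom, ivs in intervals.items():
            for k, (start, end) in enumerate(ivs):
                fh.write(f"{chrom}\t{start}\t{end}\t{name_prefix}_{k}\n")


def hits_to_frame(hits: Sequence[DuplexHit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "circ_id": [h.target_id for h in hits],
            "mirna_id": [h.mirna_id for h in hits],
            "start": [h.target_span[0] for h in hits],
            "end": [h.target_span[1] for h in hits],
            "site_1based": [h.target_span[0] + 1 for h in hits],
            "seed_class": [h.seed_class.value for h in hits],
            "dG_kcal_mol": [h.dG for h in hits],
            "pairing": [h.pairing_string for h in hits],
            "ago_supported": [h.ago_supported for h in hits],
        }
    )


def write_hits(hits: Sequence[DuplexHit], tsv_path, bed_path: Optional[str] = None) -> None:
    hits_to_frame(hits).to_csv(tsv_path, sep="\t", index=False)
    if bed_path:
        by_circ: dict = {}
        for h in hits:
            by_circ.setdefault(h.target_id, []).append(h.target_span)
        write_bed(by_circ, bed_path, name_prefix="hit")


def read_expression_tsv(matrix_path, groups_path):
    """Matrix TSV (features x samples) + two-column sample sheet."""
    from .expression import ExpressionMatrix

    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    sheet = pd.read_csv(groups_path, sep="\t")
    groups = pd.Series(
        sheet.iloc[:, 1].to_numpy(), index=sheet.iloc[:, 0].astype(str)
    )
    return ExpressionMatrix(values, groups)


def write_expression_tsv(mat, matrix_path, groups_path) -> None:
    mat.values.to_csv(matrix_path, sep="\t")
    pd.DataFrame(
        {"sample": mat.groups.index, "group": mat.groups.to_numpy()}
    ).to_csv(groups_path, sep="\t", index=False)


def read_votes_tsv(path):
    from .sponge import VoteRecord

    df = pd.read_csv(path, sep="\t")
    return [
        VoteRecord(
            str(r.mirna_id),
            str(r.gene_id),
            int(r.targetscan),
            int(r.pictar),
            int(r.rna22),
            int(r.pita),
            int(r.miranda),
        )
        for r in df.itertuples(index=False)
    ]


def write_votes_tsv(records, path) -> None:
    from .sponge import ALGORITHMS

    pd.DataFrame(
        [
            {
                "mirna_id": r.mirna_id,
                "gene_id": r.gene_id,
                **{a: getattr(r, a) for a in ALGORITHMS},
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)


def read_annotations_tsv(path):
    """miRNA -> feature-class annotation (classes comma-separated)."""
    from .sponge import DiseaseMiRna

    df = pd.read_csv(path, sep="\t")
    return [
        DiseaseMiRna(
            str(r.mirna_id),
            frozenset(str(r.feature_classes).split(",")),
            int(getattr(r, "evidence_count", 1)),
        )
        for r in df.itertuples(index=False)
    ]


def write_annotations_tsv(annotations, path) -> None:
    pd.DataFrame(
        [
            {
                "mirna_id": a.mirna_id,
                "feature_classes": ",".join(sorted(a.feature_classes)),
                "evidence_count": a.evidence_count,
            }
            for a in annotations
        ]
    ).to_csv(path, sep="\t", index=False)


def write_yaml(obj, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def read_yaml(path):
    with open(path) as fh:
        return yaml.safe_load(fh)


def sha256_of(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
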