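"""Vote-consensus target filtering and five-feature sponge ranking.

A circRNA is a candidate "miRNA sponge" when it carries binding sites for
miRNAs implicated in disease.  Disease miRNAs are annotated with up to
five functional feature classes of breast cancer biology (self-renewal/
apoptosis, chemoresistance, differentiation/proliferation, migration/
invasion/metastasis, EMT).  miRNA->mRNA target evidence is filtered by a
vote rule: the summed site counts of five prediction algorithms
(TargetScan, PicTar, RNA22, PITA, miRanda) must reach a minimum (5 by
default, the rule being inclusive: a (1,1,1,1,1) record is kept).

Scoring policies:

``sum_classes``
    score = sum over sponged disease miRNAs of the number of feature
    classes each carries — "classes of miRNA harbored" by the circRNA.
    This is the default.
``union_classes``
    score = size of the union of feature classes across sponged miRNAs
    (bounded by 5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import networkx as nx

from .hybrid import DuplexHit

FEATURE_CLASSES = (
    "self_renewal_apoptosis",
    "chemoresistance",
    "differentiation_proliferation",
    "migration_invasion_metastasis",
    "EMT",
)

ALGORITHMS = ("targetscan", "pictar", "rna22", "pita", "miranda")


@dataclass(frozen=True)
class VoteRecord:
    """Per-algorithm predicted site counts for one miRNA->gene pair."""

    mirna_id: str
    gene_id: str
    targetscan: int = 0
    pictar: int = 0
    rna22: int = 0
    pita: int = 0
    miranda: int = 0

    def __post_init__(self) -> None:
        for algo in ALGORITHMS:
            if getattr(self, algo) < 0:
                raise ValueError(
                    f"{self.mirna_id}->{self.gene_id}: negative {algo} count"
                )

    @property
    def vote_sum(self) -> int:
        return sum(getattr(self, a) for a in ALGORITHMS)


@dataclass(frozen=True)
class DiseaseMiRna:
    """A disease-associated miRNA and the feature classes it touches."""

    mirna_id: str
    feature_classes: frozenset
    evidence_count: int = 1

    def __post_init__(self) -> None:
        classes = frozenset(self.feature_classes)
        object.__setattr__(self, "feature_classes", classes)
        if not classes:
            raise ValueError(f"{self.mirna_id}: feature_classes must be non-empty")
        unknown = classes - set(FEATURE_CLASSES)
        if unknown:
            raise ValueError(f"{self.mirna_id}: unknown classes {sorted(unknown)}")


@dataclass
class SpongeScore:
    """Ranking record for one circRNA."""

    circ_id: str
    sponged: tuple  # DiseaseMiRna, distinct, sorted by id
    n_hits: int  # retained hits on sponged miRNAs (tie-break evidence)
    score: float
    policy: str
    rank: Optional[int] = None


def filter_votes(
    records: Sequence[VoteRecord], min_sum: int = 5
) -> list[VoteRecord]:
    """Keep records whose five-algorithm site-count sum reaches ``min_sum``.

    The bound is inclusive (>=), so the default keeps any record with at
    least five sites in total.  Input order is preserved.
    """
    return [r for r in records if r.vote_sum >= min_sum]


def score_circrna(
    circ_id: str,
    hits: Sequence[DuplexHit],
    annotations: Iterable[DiseaseMiRna],
    policy: str = "sum_classes",
    evidence_weighted: bool = False,
) -> SpongeScore:
    """Score one circRNA by the disease miRNAs its retained sites sponge.

    ``hits`` are the retained binding sites for this circRNA;
    ``annotations`` the disease-miRNA feature annotation.  Hits to
    miRNAs without any annotation entry are excluded with a warning.
    With ``evidence_weighted`` each miRNA's class contribution is
    multiplied by its literature evidence count.
    """
    if policy not in ("sum_classes", "union_classes"):
        raise ValueError(f"unknown policy {policy!r}")
    ann = {a.mirna_id: a for a in annotations}
    own = [h for h in hits if h.target_id == circ_id]
    if len(own) != len(hits):
        raise ValueError(f"hits reference targets other than {circ_id}")
    sponged: dict[str, DiseaseMiRna] = {}
    n_hits = 0
    for hit in own:
        if hit.mirna_id not in ann:
            warnings.warn(
                f"{circ_id}: hit for unannotated miRNA {hit.mirna_id!r} "
                "excluded from scoring",
                stacklevel=2,
            )
            continue
        sponged[hit.mirna_id] = ann[hit.mirna_id]
        n_hits += 1
    mirnas = tuple(sponged[k] for k in sorted(sponged))
    if policy == "sum_classes":
        score = float(
            sum(
                len(m.feature_classes)
                * (m.evidence_count if evidence_weighted else 1)
                for m in mirnas
            )
        )
    else:
        union: set = set()
        for m in mirnas:
            union |= m.feature_classes
        score = float(len(union))
    return SpongeScore(
        circ_id=circ_id, sponged=mirnas, n_hits=n_hits, score=score, policy=policy
    )


def rank_circrnas(scores: Sequence[SpongeScore]) -> list[SpongeScore]:
    """Rank circRNAs 1..n by descending score.

    Ties break deterministically by more distinct sponged miRNAs, then
    more retained hits, then lexicographic circRNA id.
    """
    policies = {s.policy for s in scores}
    if len(policies) > 1:
        raise ValueError(f"mixed scoring policies {sorted(policies)}")
    ordered = sorted(
        scores, key=lambda s: (-s.score, -len(s.sponged), -s.n_hits, s.circ_id)
    )
    for i, s in enumerate(ordered, start=1):
        s.rank = i
    return ordered


def build_network(
    hits: Sequence[DuplexHit],
    filtered_votes: Sequence[VoteRecord],
    coexpressed_genes: Iterable[str],
) -> nx.DiGraph:
    """Tripartite circRNA -> miRNA -> mRNA interaction graph.

    circRNA->miRNA edges come from retained binding sites; miRNA->mRNA
    edges from vote-filtered target records restricted to positively
    co-expressed genes and to miRNAs that actually have a circRNA edge,
    so no typed edge dangles.
    """
    genes = set(coexpressed_genes)
    g = nx.DiGraph()
    sponged_mirnas = set()
    for hit in hits:
        g.add_node(hit.target_id, kind="circRNA")
        g.add_node(hit.mirna_id, kind="miRNA")
        if g.has_edge(hit.target_id, hit.mirna_id):
            g[hit.target_id][hit.mirna_id]["n_sites"] += 1
            g[hit.target_id][hit.mirna_id]["best_dG"] = min(
                g[hit.target_id][hit.mirna_id]["best_dG"], hit.dG
            )
        else:
            g.add_edge(hit.target_id, hit.mirna_id, n_sites=1, best_dG=hit.dG)
        sponged_mirnas.add(hit.mirna_id)
    for rec in filtered_votes:
        if rec.mirna_id in sponged_mirnas and rec.gene_id in genes:
            g.add_node(rec.gene_id, kind="mRNA")
            g.add_edge(rec.mirna_id, rec.gene_id, vote_sum=rec.vote_sum)
    return g
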