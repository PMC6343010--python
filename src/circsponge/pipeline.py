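"""End-to-end sponge screen orchestration.

``run_screen`` executes the full candidate screen in dependency order —
simulate-or-read inputs, binding-site scan, vote filtering, five-feature
scoring and ranking, differential expression, co-expression, candidate
intersection, clinical statistics — writing every intermediate artifact
plus a manifest (thresholds, seeds, input hashes, headline results)
under one output directory.  With the same config and seed the run is
bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd

from . import clinical, expression, io, sponge, synthetic
from .energy import default_table
from .hybrid import scan_sites

logger = logging.getLogger(__name__)

_STREAM_ANCHOR = 6  # rng substream for the demo mRNA/anchor profiles


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


@dataclass
class RunConfig:
    """Paths, thresholds and policies for one screen run.

    When the input paths are ``None`` the synthetic generators produce
    them (under ``<outdir>/inputs``) from ``synth``; explicit paths take
    precedence and must exist.
    """

    outdir: str
    seed: int = 0
    dg_threshold: float = -20.0
    vote_min_sum: int = 5
    fc_threshold: float = 1.5
    p_threshold: float = 0.05
    r_threshold: float = 0.1
    policy: str = "sum_classes"
    circ_fasta: Optional[str] = None
    mirna_fasta: Optional[str] = None
    conserved_bed: Optional[str] = None
    votes_tsv: Optional[str] = None
    annotations_tsv: Optional[str] = None
    mirna_matrix_tsv: Optional[str] = None
    mirna_groups_tsv: Optional[str] = None
    mrna_matrix_tsv: Optional[str] = None
    mrna_groups_tsv: Optional[str] = None
    anchor_tsv: Optional[str] = None
    patients_tsv: Optional[str] = None
    synth: Optional[synthetic.SynthConfig] = None

    def validate(self) -> None:
        for name in (
            "circ_fasta",
            "mirna_fasta",
            "conserved_bed",
            "votes_tsv",
            "annotations_tsv",
            "mirna_matrix_tsv",
            "mirna_groups_tsv",
            "mrna_matrix_tsv",
            "mrna_groups_tsv",
            "anchor_tsv",
            "patients_tsv",
        ):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{name}: no such file {path}")
        for thr in (
            self.dg_threshold,
            self.fc_threshold,
            self.p_threshold,
            self.r_threshold,
        ):
            if not np.isfinite(thr):
                raise ValueError("thresholds must be finite")


def demo_config(seed: int = 0, outdir: str = "screen_demo") -> RunConfig:
    """The packaged synthetic demo: one circRNA planted as the top sponge.

    Annotations are drawn first; the circRNA ``circ_0`` is planted with
    sites for every disease-annotated miRNA (most for the most-annotated
    one), other circRNAs with strictly fewer, so the screen must rank
    ``circ_0`` first.  Exactly one disease miRNA targeted by ``circ_0``
    is also planted as differentially expressed, so the intersection
    nominates a singleton.
    """
    base = synthetic.SynthConfig(
        seed=seed,
        n_circ=6,
        circ_len=300,
        n_mirna=8,
        mirna_len=22,
        noise_sd=0.2,
        planted_log2fc=2.0,
        n_samples_per_group=(3, 4),
    )
    annotations = synthetic.gen_annotations(base)
    by_classes = sorted(
        annotations, key=lambda a: (-len(a.feature_classes), a.mirna_id)
    )
    disease_ids = [a.mirna_id for a in by_classes]
    planted = [("circ_0", disease_ids[0], 3)]
    planted += [("circ_0", m, 2) for m in disease_ids[1:2]]
    planted += [("circ_0", m, 1) for m in disease_ids[2:]]
    # runner-up sponges with strictly smaller disease coverage
    if len(disease_ids) > 1:
        planted.append(("circ_1", disease_ids[1], 1))
    if len(disease_ids) > 2:
        planted.append(("circ_2", disease_ids[2], 1))
    cfg = dataclasses.replace(base, planted_sites=tuple(planted))
    return RunConfig(outdir=outdir, seed=seed, synth=cfg)


def _simulate_inputs(run: RunConfig, indir: Path) -> dict:
    """Generate every missing input file from the synthetic config."""
    scfg = run.synth or synthetic.SynthConfig(seed=run.seed)
    circs, mirnas, site_map = synthetic.gen_sequences(scfg)
    annotations = synthetic.gen_annotations(scfg)
    disease_ids = [a.mirna_id for a in annotations]
    mirna_ids = [m.id for m in mirnas]

    # miRNA expression: the most-annotated planted miRNA is DE (up in TN)
    planted_on_top = [
        m for c, m, n in scfg.planted_sites if c == "circ_0" and n > 0
    ]
    by_classes = {a.mirna_id: len(a.feature_classes) for a in annotations}
    nominated = (
        max(planted_on_top, key=lambda m: (by_classes.get(m, 0), m))
        if planted_on_top
        else None
    )
    decoys = [m for m in mirna_ids if m not in disease_ids][:2]
    de = {m: 1 for m in ([nominated] if nominated else []) + decoys}
    mi_mat, mi_truth = synthetic.gen_expression(scfg, de, feature_ids=mirna_ids)

    # mRNA matrix + anchor profile: half the genes track the anchor
    rng = np.random.default_rng([int(scfg.seed), _STREAM_ANCHOR])
    samples = list(mi_mat.values.columns)
    genes = [f"gene_{k}" for k in range(10)]
    anchor = pd.Series(rng.normal(8.0, 1.0, size=len(samples)), index=samples)
    rows = []
    for k, g in enumerate(genes):
        if k < 5:
            rows.append(0.9 * anchor.to_numpy() + rng.normal(0, 0.3, len(samples)))
        else:
            rows.append(-0.9 * anchor.to_numpy() + rng.normal(0, 0.3, len(samples)) + 16)
    mr_mat = expression.ExpressionMatrix(
        pd.DataFrame(rows, index=genes, columns=samples), mi_mat.groups.copy()
    )
    true_targets = {m: {g for g in genes[:3]} for m in disease_ids}
    votes = synthetic.gen_votes(scfg, mirna_ids, genes, true_targets)
    cohort = synthetic.gen_cohort(scfg)

    paths = {
        "circ_fasta": indir / "circrnas.fasta",
        "mirna_fasta": indir / "mirnas.fasta",
        "sites_bed": indir / "planted_sites.bed",
        "votes_tsv": indir / "votes.tsv",
        "annotations_tsv": indir / "annotations.tsv",
        "mirna_matrix_tsv": indir / "mirna_matrix.tsv",
        "mirna_groups_tsv": indir / "mirna_groups.tsv",
        "mrna_matrix_tsv": indir / "mrna_matrix.tsv",
        "mrna_groups_tsv": indir / "mrna_groups.tsv",
        "anchor_tsv": indir / "anchor_profile.tsv",
        "patients_tsv": indir / "patients.tsv",
        "config_yaml": indir / "synth_config.yaml",
    }
    io.write_fasta(circs, paths["circ_fasta"])
    io.write_fasta(mirnas, paths["mirna_fasta"])
    bed = {}
    for (cid, mid), sites in sorted(site_map.items()):
        bed.setdefault(cid, []).extend(
            (off, off + length) for off, length in sites
        )
    io.write_bed(bed, paths["sites_bed"])
    io.write_votes_tsv(votes, paths["votes_tsv"])
    io.write_annotations_tsv(annotations, paths["annotations_tsv"])
    io.write_expression_tsv(
        mi_mat, paths["mirna_matrix_tsv"], paths["mirna_groups_tsv"]
    )
    io.write_expression_tsv(
        mr_mat, paths["mrna_matrix_tsv"], paths["mrna_groups_tsv"]
    )
    anchor.rename("anchor").to_frame().rename_axis("sample").to_csv(
        paths["anchor_tsv"], sep="\t"
    )
    cohort.to_csv(paths["patients_tsv"], sep="\t", index=False)
    io.write_yaml(synthetic.config_to_dict(scfg), paths["config_yaml"])
    return {
        "paths": paths,
        "site_map": site_map,
        "de_truth": mi_truth,
        "nominated_truth": nominated,
    }


def run_screen(run: RunConfig) -> dict:
    """Execute the full screen; returns (and writes) the run manifest."""
    run.validate()
    outdir = Path(run.outdir)
    indir = outdir / "inputs"
    resdir = outdir / "results"
    indir.mkdir(parents=True, exist_ok=True)
    resdir.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "seed": run.seed,
        "thresholds": {
            "dg_kcal_mol": run.dg_threshold,
            "vote_min_sum": run.vote_min_sum,
            "abs_log2fc": run.fc_threshold,
            "p": run.p_threshold,
            "pearson_r": run.r_threshold,
        },
        "policy": run.policy,
        "stages": [],
    }

    def stage(name):
        def deco(fn):
            try:
                out = fn()
            except Exception as exc:  # noqa: BLE001 - re-raised with context
                raise StageError(f"stage '{name}' failed: {exc}") from exc
            manifest["stages"].append(name)
            return out

        return deco

    @stage("simulate")
    def sim():
        if run.circ_fasta is None:
            return _simulate_inputs(run, indir)
        return None

    paths = (
        {k: str(v) for k, v in sim["paths"].items()}
        if sim
        else {
            "circ_fasta": run.circ_fasta,
            "mirna_fasta": run.mirna_fasta,
            "votes_tsv": run.votes_tsv,
            "annotations_tsv": run.annotations_tsv,
            "mirna_matrix_tsv": run.mirna_matrix_tsv,
            "mirna_groups_tsv": run.mirna_groups_tsv,
            "mrna_matrix_tsv": run.mrna_matrix_tsv,
            "mrna_groups_tsv": run.mrna_groups_tsv,
            "anchor_tsv": run.anchor_tsv,
            "patients_tsv": run.patients_tsv,
        }
    )
    manifest["inputs"] = {
        k: {"path": str(p), "sha256": io.sha256_of(p)}
        for k, p in paths.items()
        if p is not None and Path(p).exists()
    }

    @stage("scan")
    def hits():
        circs = io.read_fasta(paths["circ_fasta"])
        mirnas = io.read_fasta(paths["mirna_fasta"])
        conserved = (
            io.read_bed(run.conserved_bed) if run.conserved_bed else {}
        )
        table = default_table()
        allhits = []
        for circ in circs:
            if circ.id in conserved:
                circ = dataclasses.replace(
                    circ, conserved=tuple(conserved[circ.id])
                )
            for m in mirnas:
                allhits.extend(
                    scan_sites(m, circ, table, dg_threshold=run.dg_threshold)
                )
        io.write_hits(allhits, resdir / "hits.tsv", resdir / "hits.bed")
        return allhits

    @stage("votes")
    def filtered_votes():
        records = io.read_votes_tsv(paths["votes_tsv"])
        kept = sponge.filter_votes(records, min_sum=run.vote_min_sum)
        io.write_votes_tsv(kept, resdir / "votes_filtered.tsv")
        return kept

    @stage("score_rank")
    def ranked():
        annotations = io.read_annotations_tsv(paths["annotations_tsv"])
        by_circ: dict = {}
        for h in hits:
            by_circ.setdefault(h.target_id, []).append(h)
        circ_ids = {r.id for r in io.read_fasta(paths["circ_fasta"])}
        known = {a.mirna_id for a in annotations}
        scores = [
            sponge.score_circrna(
                cid,
                [h for h in by_circ.get(cid, []) if h.mirna_id in known],
                annotations,
                policy=run.policy,
            )
            for cid in sorted(circ_ids)
        ]
        out = sponge.rank_circrnas(scores)
        pd.DataFrame(
            {
                "rank": [s.rank for s in out],
                "circ_id": [s.circ_id for s in out],
                "score": [s.score for s in out],
                "n_sponged_mirnas": [len(s.sponged) for s in out],
                "n_hits": [s.n_hits for s in out],
                "policy": [s.policy for s in out],
            }
        ).to_csv(resdir / "ranking.tsv", sep="\t", index=False)
        return out

    @stage("de")
    def de_results():
        mat = io.read_expression_tsv(
            paths["mirna_matrix_tsv"], paths["mirna_groups_tsv"]
        )
        res = expression.differential_expression(
            mat, fc_threshold=run.fc_threshold, p_threshold=run.p_threshold
        )
        expression.de_to_frame(res).to_csv(resdir / "de_mirna.tsv", sep="\t")
        return res

    @stage("coexpr")
    def coexpr_edges():
        mat = io.read_expression_tsv(
            paths["mrna_matrix_tsv"], paths["mrna_groups_tsv"]
        )
        anchor_df = pd.read_csv(paths["anchor_tsv"], sep="\t", index_col=0)
        anchor = anchor_df.iloc[:, 0]
        edges = expression.coexpression_edges(
            anchor, mat, r_threshold=run.r_threshold
        )
        pd.DataFrame(
            {
                "gene_id": [e.gene_id for e in edges],
                "r": [e.r for e in edges],
                "kept": [e.kept for e in edges],
            }
        ).to_csv(resdir / "coexpression.tsv", sep="\t", index=False)
        return edges

    @stage("intersect")
    def venn():
        top = ranked[0]
        predicted = {h.mirna_id for h in hits if h.target_id == top.circ_id}
        de_pass = {r.feature_id for r in de_results if r.passed}
        inter, counts = expression.intersect_candidates(de_pass, predicted)
        io.write_yaml(
            {
                "de_only": counts[0],
                "predicted_only": counts[1],
                "intersection": counts[2],
                "nominated": sorted(inter),
            },
            resdir / "venn.yaml",
        )
        return inter, counts

    @stage("network")
    def graph():
        top = ranked[0]
        top_hits = [h for h in hits if h.target_id == top.circ_id]
        kept_genes = [e.gene_id for e in coexpr_edges if e.kept]
        g = sponge.build_network(top_hits, filtered_votes, kept_genes)
        nx.write_graphml(g, resdir / "network.graphml")
        nodes = pd.DataFrame(
            {"id": list(g.nodes), "kind": [g.nodes[n]["kind"] for n in g.nodes]}
        )
        edges = pd.DataFrame(
            {"source": [u for u, _ in g.edges], "target": [v for _, v in g.edges]}
        )
        nodes.to_csv(resdir / "network_nodes.tsv", sep="\t", index=False)
        edges.to_csv(resdir / "network_edges.tsv", sep="\t", index=False)
        return g

    @stage("clinical")
    def clin():
        df = pd.read_csv(paths["patients_tsv"], sep="\t")
        if df.empty:
            return None
        assoc = clinical.cohort_association_table(df)
        assoc.to_csv(resdir / "clinical_association.tsv", sep="\t")
        records = clinical.records_from_frame(
            df[["patient_id", "time_months", "event", "group"]]
        )
        curves = clinical.kaplan_meier(records)
        for gname, curve in curves.items():
            curve.to_csv(resdir / f"km_{gname}.tsv", sep="\t", index=False)
        stat, p = clinical.logrank(records)
        return {"logrank_chi2": stat, "logrank_p": p}

    inter, counts = venn
    manifest["results"] = {
        "n_hits": len(hits),
        "n_votes_kept": len(filtered_votes),
        "top_circ": ranked[0].circ_id,
        "top_score": ranked[0].score,
        "ranking": [(s.rank, s.circ_id, s.score) for s in ranked],
        "n_de_passed": sum(r.passed for r in de_results),
        "n_coexpressed_kept": sum(e.kept for e in coexpr_edges),
        "venn": {
            "de_only": counts[0],
            "predicted_only": counts[1],
            "intersection": counts[2],
        },
        "nominated_mirnas": sorted(inter),
        "network_nodes": graph.number_of_nodes(),
        "network_edges": graph.number_of_edges(),
        "clinical": clin,
    }
    if sim:
        manifest["ground_truth"] = {
            "planted_sites": {
                f"{c}|{m}": v for (c, m), v in sorted(sim["site_map"].items())
            },
            "nominated_truth": sim["nominated_truth"],
        }
    def _np_safe(obj):
        if isinstance(obj, dict):
            return {k: _np_safe(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_np_safe(v) for v in obj]
        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.floating):
            return float(obj)
        if isinstance(obj, np.bool_):
            return bool(obj)
        return obj

    manifest = _np_safe(manifest)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
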