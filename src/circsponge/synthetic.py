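"""Synthetic study inputs: sequences with planted sites, expression
matrices with planted effects, and a clinical cohort with prescribed
2x2 margins.

Every generator returns machine-readable ground truth next to the data
and is a pure function of :class:`SynthConfig` (one integer seed, with a
fixed substream per generator), so identical configurations reproduce
identical files byte for byte.

What is emulated and what is not: circRNA conserved regions are uniform
random RNA with planted sites that are exact reverse complements of a
miRNA (or of its seed, in ``plant_mode="seed"``); expression matrices
are group means plus i.i.d. Gaussian noise on the log2 scale (no probe
effects, no batch structure); the cohort draws exponential survival
times per marker group with administrative uniform censoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .clinical import REFERENCE_COHORT_TABLES, TwoByTwo
from .expression import ExpressionMatrix
from .hybrid import RnaSeq, revcomp
from .sponge import ALGORITHMS, FEATURE_CLASSES, DiseaseMiRna, VoteRecord

_BASES = np.array(list("ACGU"))

# substream tags so each generator has its own reproducible stream
_STREAM_SEQ, _STREAM_EXPR, _STREAM_COHORT, _STREAM_ANNOT, _STREAM_VOTES = range(5)


class PlacementError(ValueError):
    """Planted sites cannot be placed without overlap."""


@dataclass(frozen=True)
class SynthConfig:
    """Study-condition parameters for the synthetic inputs.

    ``planted_sites`` lists (circ_id, mirna_id, n_sites) with ids of the
    form ``circ_<i>`` / ``mir_<j>``.  ``n_samples_per_group`` mirrors the
    3 TNBC vs 4 luminal/HER2+ cell lines of the expression contrast.
    ``cohort_counts`` maps variable name -> :class:`TwoByTwo` with
    columns (low, high); the default is the published 136-patient
    reference cohort.  Survival: exponential times with low-group hazard
    ``survival_base_hazard`` per month and high-group hazard multiplied
    by ``survival_hazard_ratio``; administrative censoring uniform over
    ``censor_window`` months.
    """

    seed: int = 0
    n_circ: int = 6
    circ_len: int = 300
    n_mirna: int = 8
    mirna_len: int = 22
    planted_sites: tuple = ()
    n_samples_per_group: tuple = (3, 4)
    planted_log2fc: float = 2.0
    noise_sd: float = 0.3
    cohort_counts: Mapping[str, TwoByTwo] = field(
        default_factory=lambda: dict(REFERENCE_COHORT_TABLES)
    )
    survival_hazard_ratio: float = 9.114
    survival_base_hazard: float = 0.01
    censor_window: tuple = (12.0, 72.0)
    plant_mode: str = "full"  # "full" complement or "seed"-only match

    def __post_init__(self) -> None:
        if min(self.n_circ, self.circ_len, self.n_mirna) < 0:
            raise ValueError("counts must be >= 0")
        if self.mirna_len < 8:
            raise ValueError("mirna_len must be >= 8 (a seed must exist)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.survival_hazard_ratio <= 0:
            raise ValueError("survival_hazard_ratio must be > 0")
        if self.plant_mode not in ("full", "seed"):
            raise ValueError("plant_mode must be 'full' or 'seed'")
        sites = tuple((str(c), str(m), int(n)) for c, m, n in self.planted_sites)
        if any(n < 0 for _, _, n in sites):
            raise ValueError("site counts must be >= 0")
        object.__setattr__(self, "planted_sites", sites)
        ns = self.n_samples_per_group
        pair = (int(ns), int(ns)) if np.isscalar(ns) else (int(ns[0]), int(ns[1]))
        object.__setattr__(self, "n_samples_per_group", pair)

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def gen_sequences(cfg: SynthConfig):
    """Generate miRNAs, circRNA conserved sequences, and planted sites.

    Returns (circs, mirnas, site_map) where ``site_map`` maps
    (circ_id, mirna_id) -> list of (offset, length) giving the exact
    position of each planted site (reverse complement of the miRNA, or
    of its 8-nt 5' portion in seed mode).  Background is uniform over
    {A, C, G, U}; sites never overlap.
    """
    rng = cfg.rng(_STREAM_SEQ)
    mirnas = [
        RnaSeq(f"mir_{j}", _random_rna(rng, cfg.mirna_len))
        for j in range(cfg.n_mirna)
    ]
    mirna_by_id = {m.id: m for m in mirnas}
    circ_ids = [f"circ_{i}" for i in range(cfg.n_circ)]
    wanted: dict[str, list] = {cid: [] for cid in circ_ids}
    for cid, mid, n in cfg.planted_sites:
        if cid not in wanted:
            raise ValueError(f"planted site references unknown circRNA {cid!r}")
        if mid not in mirna_by_id:
            raise ValueError(f"planted site references unknown miRNA {mid!r}")
        wanted[cid].extend([mid] * n)

    site_len = cfg.mirna_len if cfg.plant_mode == "full" else 8
    circs = []
    site_map: dict[tuple, list] = {}
    for cid in circ_ids:
        seq = np.array(list(_random_rna(rng, cfg.circ_len)))
        segs = wanted[cid]
        nseg = len(segs)
        if nseg:
            if nseg * site_len > cfg.circ_len:
                raise PlacementError(
                    f"cannot place {nseg} sites of {site_len} nt in {cid} "
                    f"({cfg.circ_len} nt); pairs: "
                    f"{sorted({(cid, m) for m in segs})}"
                )
            # non-overlapping placement via the gap bijection: choose nseg
            # distinct slots, then stretch each by the site length
            slots = np.sort(
                rng.choice(
                    cfg.circ_len - nseg * site_len + nseg, size=nseg, replace=False
                )
            )
            offsets = slots + np.arange(nseg) * (site_len - 1)
            order = rng.permutation(nseg)
            for k, off in zip(order, offsets):
                mid = segs[int(k)]
                m = mirna_by_id[mid]
                insert = (
                    revcomp(m.seq)
                    if cfg.plant_mode == "full"
                    else revcomp(m.seq[:8])
                )
                seq[int(off) : int(off) + site_len] = list(insert)
                site_map.setdefault((cid, mid), []).append(
                    (int(off), site_len)
                )
        circs.append(RnaSeq(cid, "".join(seq)))
    for key in site_map:
        site_map[key].sort()
    return circs, mirnas, site_map


def gen_expression(
    cfg: SynthConfig,
    de_features: Mapping[str, int] | Iterable[str],
    feature_ids: Optional[Sequence[str]] = None,
    group_labels: tuple = ("TN", "luminal_her2"),
) -> tuple[ExpressionMatrix, dict]:
    """Two-group log2 expression matrix with planted fold changes.

    ``de_features`` is a set of feature ids (all shifted up in group A)
    or a mapping id -> sign (+1 up in group A, -1 down).  Non-DE
    features have identical group means; noise is i.i.d. Gaussian with
    sd ``cfg.noise_sd``.  Returns (matrix, ground_truth log2fc by id).
    """
    rng = cfg.rng(_STREAM_EXPR)
    if feature_ids is None:
        feature_ids = [f"mir_{j}" for j in range(cfg.n_mirna)]
    feature_ids = [str(f) for f in feature_ids]
    if isinstance(de_features, Mapping):
        signs = {str(k): int(v) for k, v in de_features.items()}
    else:
        signs = {str(k): 1 for k in de_features}
    unknown = set(signs) - set(feature_ids)
    if unknown:
        raise ValueError(f"de_features not in feature_ids: {sorted(unknown)}")
    n1, n2 = cfg.n_samples_per_group
    if min(n1, n2) < 2:
        raise ValueError("need >= 2 samples per group for downstream testing")

    base = rng.uniform(6.0, 12.0, size=len(feature_ids))
    truth = {
        f: signs.get(f, 0) * cfg.planted_log2fc for f in feature_ids
    }
    mean_a = base + np.array([truth[f] for f in feature_ids])
    mean_b = base
    samples = [f"{group_labels[0]}_{i+1}" for i in range(n1)] + [
        f"{group_labels[1]}_{i+1}" for i in range(n2)
    ]
    means = np.concatenate(
        [np.tile(mean_a[:, None], (1, n1)), np.tile(mean_b[:, None], (1, n2))],
        axis=1,
    )
    values = means + rng.normal(0.0, cfg.noise_sd, size=means.shape)
    df = pd.DataFrame(values, index=feature_ids, columns=samples)
    groups = pd.Series(
        [group_labels[0]] * n1 + [group_labels[1]] * n2, index=samples
    )
    return ExpressionMatrix(df, groups), truth


def gen_cohort(cfg: SynthConfig) -> pd.DataFrame:
    """Patient table reproducing every requested 2x2 table exactly.

    One row per patient with the low/high marker group, one categorical
    column per variable (levels permuted within marker group so
    crosstabs hit the prescribed counts exactly), an exponential
    survival time differing between groups by the configured hazard
    ratio, and an event flag under administrative uniform censoring.
    """
    rng = cfg.rng(_STREAM_COHORT)
    tables = dict(cfg.cohort_counts)
    if not tables:
        return pd.DataFrame(
            columns=["patient_id", "group", "time_months", "event"]
        )
    margins = None
    for name, t in tables.items():
        if not isinstance(t, TwoByTwo):
            t = TwoByTwo(name, ("level1", "level2"), tuple(map(tuple, t)))
            tables[name] = t
        if margins is None:
            margins = t.col_margins
        elif t.col_margins != margins:
            raise ValueError(
                f"variable {name!r}: column margins {t.col_margins} are "
                f"inconsistent with {margins} (one record per patient is "
                "impossible)"
            )
    n_low, n_high = margins
    n = n_low + n_high
    if n == 0:
        return pd.DataFrame(
            columns=["patient_id", "group", "time_months", "event"]
            + list(tables)
        )

    df = pd.DataFrame(
        {
            "patient_id": [f"P{i+1:04d}" for i in range(n)],
            "group": ["low"] * n_low + ["high"] * n_high,
        }
    )
    for name, t in tables.items():
        (a, b), (c, d) = t.counts
        lv1, lv2 = t.row_labels
        low_levels = np.array([lv1] * a + [lv2] * c, dtype=object)
        high_levels = np.array([lv1] * b + [lv2] * d, dtype=object)
        df[name] = np.concatenate(
            [rng.permutation(low_levels), rng.permutation(high_levels)]
        )

    lam = np.where(
        df["group"] == "high",
        cfg.survival_base_hazard * cfg.survival_hazard_ratio,
        cfg.survival_base_hazard,
    )
    t_event = rng.exponential(1.0 / lam)
    t_censor = rng.uniform(*cfg.censor_window, size=n)
    df["time_months"] = np.maximum(np.minimum(t_event, t_censor), 1e-6)
    df["event"] = t_event <= t_censor
    return df


def gen_annotations(
    cfg: SynthConfig,
    disease_fraction: float = 0.5,
    max_classes: int = 3,
) -> list[DiseaseMiRna]:
    """Random disease-miRNA feature annotation (input-table emulation).

    A ``disease_fraction`` of the miRNAs receives 1..``max_classes``
    feature classes drawn from the five canonical ones.
    """
    rng = cfg.rng(_STREAM_ANNOT)
    n_disease = int(round(cfg.n_mirna * disease_fraction))
    chosen = rng.choice(cfg.n_mirna, size=n_disease, replace=False)
    out = []
    for j in sorted(int(x) for x in chosen):
        k = int(rng.integers(1, max_classes + 1))
        classes = rng.choice(len(FEATURE_CLASSES), size=k, replace=False)
        out.append(
            DiseaseMiRna(
                f"mir_{j}",
                frozenset(FEATURE_CLASSES[int(c)] for c in classes),
                evidence_count=int(rng.integers(1, 6)),
            )
        )
    return out


def gen_votes(
    cfg: SynthConfig,
    mirna_ids: Sequence[str],
    gene_ids: Sequence[str],
    true_targets: Mapping[str, Iterable[str]],
) -> list[VoteRecord]:
    """Per-algorithm site-count table (input-table emulation).

    True miRNA->gene targets receive counts summing to at least 5;
    every other pair gets sparse counts summing below 5.
    """
    rng = cfg.rng(_STREAM_VOTES)
    truth = {m: set(gs) for m, gs in true_targets.items()}
    records = []
    for m in mirna_ids:
        for g in gene_ids:
            if g in truth.get(m, ()):
                counts = rng.integers(1, 3, size=5)  # sum in [5, 10]
            else:
                counts = rng.multinomial(int(rng.integers(0, 4)), [0.2] * 5)
            records.append(
                VoteRecord(m, g, **{a: int(c) for a, c in zip(ALGORITHMS, counts)})
            )
    return records


def config_to_dict(cfg: SynthConfig) -> dict:
    """YAML-serializable form of a config (for sidecar files)."""
    d = asdict(cfg)
    d["cohort_counts"] = {
        name: {
            "row_labels": list(t.row_labels),
            "col_labels": list(t.col_labels),
            "counts": [list(r) for r in t.counts],
        }
        for name, t in cfg.cohort_counts.items()
    }
    d["planted_sites"] = [list(p) for p in cfg.planted_sites]
    d["n_samples_per_group"] = list(cfg.n_samples_per_group)
    d["censor_window"] = list(cfg.censor_window)
    return d
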