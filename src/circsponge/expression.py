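"""Two-group differential expression, co-expression edges, and candidate
intersection.

The expression screen mirrors a standard two-group microarray contrast on
the log2 scale: per-feature log2 fold change (difference of group means)
with a two-sided Welch t test, a feature passing when |log2FC| > 1.5 and
raw P < 0.05 (both strict).  Positive co-expression partners of an anchor
transcript are selected by Pearson r > 0.1 (strict).  The final
nomination intersects differentially expressed miRNAs with the predicted
sponge targets of the top circRNA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Log2-scale expression values (features x samples) with group labels."""

    values: pd.DataFrame
    groups: pd.Series  # sample id -> group label

    def __post_init__(self) -> None:
        self.groups = self.groups.reindex(self.values.columns)
        if self.groups.isna().any():
            missing = list(self.groups[self.groups.isna()].index)
            raise ValueError(f"samples without group label: {missing}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")

    @property
    def group_labels(self) -> tuple:
        return tuple(pd.unique(self.groups))

    def samples_of(self, group: str) -> list:
        return list(self.groups.index[self.groups == group])


@dataclass
class DEResult:
    """Differential-expression verdict for one feature."""

    feature_id: str
    log2fc: float
    p: float
    direction: str  # up / down / none
    passed: bool


def differential_expression(
    mat: ExpressionMatrix,
    fc_threshold: float = 1.5,
    p_threshold: float = 0.05,
    group_order: Optional[tuple] = None,
    moderated: bool = False,
) -> list[DEResult]:
    """Welch two-sample contrast per feature with strict cutoff semantics.

    log2FC is ``mean(group A) - mean(group B)`` with (A, B) given by
    ``group_order`` (defaults to order of appearance in the sample sheet).
    A feature passes iff |log2FC| > ``fc_threshold`` AND p < ``p_threshold``
    — both strict, so a fold change of exactly 1.5 fails.  ``moderated``
    pools the per-feature variances toward their grand mean before the t
    statistic (a simple moderated-variance alternative; off by default).
    """
    labels = group_order or mat.group_labels
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    a_cols = mat.samples_of(labels[0])
    b_cols = mat.samples_of(labels[1])
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("each group needs >= 2 samples")
    a = mat.values[a_cols].to_numpy(dtype=float)
    b = mat.values[b_cols].to_numpy(dtype=float)
    log2fc = a.mean(axis=1) - b.mean(axis=1)

    if moderated:
        va = a.var(axis=1, ddof=1)
        vb = b.var(axis=1, ddof=1)
        v0a, v0b = va.mean(), vb.mean()
        va = 0.5 * (va + v0a)
        vb = 0.5 * (vb + v0b)
        se = np.sqrt(va / a.shape[1] + vb / b.shape[1])
        with np.errstate(divide="ignore", invalid="ignore"):
            t = log2fc / se
        df = a.shape[1] + b.shape[1] - 2
        p = 2.0 * stats.t.sf(np.abs(t), df)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)

    results = []
    for feat, fc, pi in zip(mat.values.index, log2fc, p):
        if not np.isfinite(pi):
            # both groups degenerate (zero variance); equal means -> no
            # evidence either way, p = 1 by convention
            logger.warning("%s: degenerate variance, p set to 1", feat)
            pi = 1.0
        passed = abs(fc) > fc_threshold and pi < p_threshold
        direction = "up" if fc > 0 else ("down" if fc < 0 else "none")
        results.append(DEResult(str(feat), float(fc), float(pi), direction, passed))
    return results


def de_to_frame(results: Sequence[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in results],
            "log2fc": [r.log2fc for r in results],
            "p": [r.p for r in results],
            "direction": [r.direction for r in results],
            "passed": [r.passed for r in results],
        }
    ).set_index("feature_id")


@dataclass
class CoexprEdge:
    """Correlation of one gene with the anchor transcript's profile."""

    gene_id: str
    r: float
    kept: bool
    reason: str = ""


def coexpression_edges(
    anchor_profile: pd.Series,
    mat: ExpressionMatrix,
    r_threshold: float = 0.1,
) -> list[CoexprEdge]:
    """Pearson correlation of every gene with an anchor profile.

    Computed over samples shared between the anchor profile and the
    matrix (>= 3 required).  An edge is kept iff r > ``r_threshold``
    (strict).  Constant vectors have undefined r and are never kept.
    """
    shared = [s for s in mat.values.columns if s in anchor_profile.index]
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared samples, got {len(shared)}")
    if len(shared) == 3:
        logger.warning(
            "co-expression computed on only 3 shared samples; Pearson r is "
            "statistically fragile at this n"
        )
    x = anchor_profile[shared].to_numpy(dtype=float)
    xm = x - x.mean()
    xs = np.sqrt((xm**2).sum())
    edges = []
    for gene in mat.values.index:
        y = mat.values.loc[gene, shared].to_numpy(dtype=float)
        ym = y - y.mean()
        ys = np.sqrt((ym**2).sum())
        if xs == 0.0 or ys == 0.0:
            logger.warning("%s: constant vector, correlation undefined", gene)
            edges.append(CoexprEdge(str(gene), float("nan"), False, "constant"))
            continue
        r = float((xm * ym).sum() / (xs * ys))
        edges.append(CoexprEdge(str(gene), r, r > r_threshold))
    return edges


def intersect_candidates(
    de_mirnas: Iterable[str], predicted_targets: Iterable[str]
) -> tuple[set, tuple]:
    """Venn intersection of DE miRNAs with predicted sponge targets.

    Returns (intersection, (|A only|, |B only|, |A and B|)).
    """
    a, b = set(de_mirnas), set(predicted_targets)
    inter = a & b
    return inter, (len(a - b), len(b - a), len(inter))
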