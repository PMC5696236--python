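"""CD8+ infiltration association with CT-gene expression.

Per-sample CD8+ infiltration scores (precomputed estimates of cytotoxic
T-cell abundance) are compared across expression tiers of individual CT
genes, and against an aggregate signal over the good-prognosis CT set. The
score scale is unknown a priori, so all tests are rank-based: a two-sided
Wilcoxon rank-sum for two tiers, Kruskal-Wallis plus a rank-based trend
(Spearman correlation of score against ordered tier index) for three.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, InfiltrationTable, ValidationError, logger
from .survival import assign_groups, GROUP_LABELS

__all__ = ["InfiltrationAssociation", "per_gene_association", "aggregate_association"]


@dataclass(frozen=True)
class InfiltrationAssociation:
    label: str                 # gene id or aggregate label
    tumor_type: str
    n_tiers: int
    tier_sizes: dict
    tier_medians: dict
    statistic: float
    p_value: float
    trend_rho: float
    trend_p: float
    direction: str             # "higher" | "lower" CD8 in expressers, "" if untestable
    testable: bool
    method: str

    def to_row(self) -> dict:
        d = {
            "label": self.label,
            "tumor_type": self.tumor_type,
            "n_tiers": self.n_tiers,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "trend_rho": self.trend_rho,
            "trend_p": self.trend_p,
            "direction": self.direction,
            "testable": self.testable,
            "method": self.method,
        }
        for k, v in self.tier_medians.items():
            d[f"median_{k}"] = v
        for k, v in self.tier_sizes.items():
            d[f"n_{k}"] = v
        return d


def _ranksum(x: np.ndarray, y: np.ndarray):
    """Two-sided rank-sum; exact null enumeration when both groups are small
    and tie-free, scipy's normal approximation otherwise."""
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if tie_free and max(x.size, y.size) <= 25 else "asymptotic"
    return stats.mannwhitneyu(x, y, alternative="two-sided", method=method)


def _intersect(expression: ExpressionMatrix, cd8: InfiltrationTable) -> list[str]:
    common = [s for s in expression.sample_ids if s in set(cd8.sample_ids)]
    dropped = len(expression.sample_ids) - len(common)
    if dropped:
        logger.info(
            "infiltration: %d expression samples lack a CD8 score and were dropped",
            dropped,
        )
    return common


def _untestable(label, tumor, n_tiers, sizes, medians, method) -> InfiltrationAssociation:
    return InfiltrationAssociation(
        label, tumor, n_tiers, sizes, medians,
        np.nan, np.nan, np.nan, np.nan, "", False, method,
    )


def per_gene_association(
    expression: ExpressionMatrix,
    cd8: InfiltrationTable,
    gene_id: str,
    n_tiers: int = 2,
    expr_cutoff: float = 1.0,
) -> InfiltrationAssociation:
    """Compare CD8 scores across the expression tiers of one gene.

    Two tiers: Wilcoxon rank-sum (exact null when both groups are small and
    tie-free); three tiers (none / low / high): Kruskal-Wallis plus the
    Spearman trend over the ordered tier index. Direction is "higher" when
    expressers' median CD8 exceeds non-expressers' (trend sign for 3 tiers).
    Fewer than two non-empty tiers, or a constant CD8 score, is untestable
    (flagged; a constant score yields p = 1 by convention).
    """
    if gene_id not in expression.values.index:
        raise KeyError(f"gene {gene_id!r} not in expression matrix")
    if n_tiers not in (2, 3):
        raise ValidationError("n_tiers must be 2 or 3")
    samples = _intersect(expression, cd8)
    if not samples:
        raise ValidationError("no overlapping samples between expression and CD8 table")
    v = expression.values.loc[gene_id, samples].to_numpy(dtype=float)
    scores = cd8.scores.loc[samples].to_numpy(dtype=float)
    informative = np.isfinite(v)
    v, scores = v[informative], scores[informative]
    groups = assign_groups(v, expr_cutoff, n_tiers)
    labels = GROUP_LABELS if n_tiers == 3 else ("not_expressed", "expressed")
    tier_scores = {l: scores[groups == l] for l in labels}
    sizes = {l: int(s.size) for l, s in tier_scores.items()}
    medians = {
        l: (float(np.median(s)) if s.size else np.nan) for l, s in tier_scores.items()
    }
    nonempty = [l for l in labels if sizes[l] > 0]
    tumor = expression.context
    method = "ranksum" if n_tiers == 2 else "kruskal+trend"
    if len(nonempty) < 2:
        return _untestable(gene_id, tumor, n_tiers, sizes, medians, method)
    if np.all(scores == scores[0]):  # no variation in CD8 at all
        return InfiltrationAssociation(
            gene_id, tumor, n_tiers, sizes, medians,
            0.0, 1.0, 0.0, 1.0, "", True, method,
        )
    if n_tiers == 2:
        stat, p = _ranksum(tier_scores["expressed"], tier_scores["not_expressed"])
        rho, trend_p = np.nan, np.nan
        direction = (
            "higher" if medians["expressed"] > medians["not_expressed"] else "lower"
        )
    else:
        present = [tier_scores[l] for l in nonempty]
        stat, p = stats.kruskal(*present)
        order = {l: i for i, l in enumerate(labels)}
        tier_idx = np.array([order[g] for g in groups], dtype=float)
        rho, trend_p = stats.spearmanr(tier_idx, scores)
        direction = "higher" if rho > 0 else "lower"
    return InfiltrationAssociation(
        gene_id, tumor, n_tiers, sizes, medians,
        float(stat), float(p), float(rho), float(trend_p), direction, True, method,
    )


def aggregate_association(
    expression: ExpressionMatrix,
    cd8: InfiltrationTable,
    good_prognosis_genes: Iterable[str],
    expr_cutoff: float = 1.0,
) -> InfiltrationAssociation:
    """Aggregate test over the good-prognosis CT set of one tumor.

    Per sample, the aggregate CT signal is the count of good-prognosis genes
    expressed (strictly > cutoff); samples are split at the median count
    (ties at the median go low) and CD8 scores compared by rank-sum. Genes
    are treated as a set (order and duplicates are irrelevant). A constant
    aggregate is untestable.
    """
    genes = sorted(set(good_prognosis_genes))
    if not genes:
        raise ValidationError("aggregate_association: empty good-prognosis gene set")
    present = [g for g in genes if g in expression.values.index]
    if not present:
        raise ValidationError(
            "aggregate_association: none of the good-prognosis genes are in the matrix"
        )
    samples = _intersect(expression, cd8)
    if not samples:
        raise ValidationError("no overlapping samples between expression and CD8 table")
    sub = expression.values.loc[present, samples]
    counts = (sub > expr_cutoff).sum(axis=0).to_numpy(dtype=float)
    scores = cd8.scores.loc[samples].to_numpy(dtype=float)
    label = f"aggregate[{len(present)} genes]"
    tumor = expression.context
    med = float(np.median(counts))
    high = counts > med
    sizes = {"low": int((~high).sum()), "high": int(high.sum())}
    medians = {
        "low": float(np.median(scores[~high])) if (~high).any() else np.nan,
        "high": float(np.median(scores[high])) if high.any() else np.nan,
    }
    if high.all() or (~high).all():
        return _untestable(label, tumor, 2, sizes, medians, "ranksum")
    if np.all(scores == scores[0]):
        return InfiltrationAssociation(
            label, tumor, 2, sizes, medians, 0.0, 1.0, 0.0, 1.0, "", True, "ranksum",
        )
    stat, p = _ranksum(scores[high], scores[~high])
    direction = "higher" if medians["high"] > medians["low"] else "lower"
    return InfiltrationAssociation(
        label, tumor, 2, sizes, medians,
        float(stat), float(p), np.nan, np.nan, direction, True, "ranksum",
    )
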