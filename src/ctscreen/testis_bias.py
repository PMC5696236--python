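"""Testis-bias screen: proportional score, stringency tiers, consensus set.

The proportional score of a gene is its testis expression divided by the sum
of its expression over all surveyed normal tissues, so a score of 1.0 means
testis-exclusive expression and 0.9 means at least 90% of all measured
expression comes from testis. Genes are screened per source atlas at one or
more inclusive tiers (default 0.9, with 0.99 as the stringent alternative),
and the working set is the non-redundant union of per-source passing sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import chain, combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, TissueProfile, ValidationError, logger

__all__ = [
    "aggregate_replicates",
    "proportional_scores",
    "proportional_score",
    "screen_source",
    "ConsensusSet",
    "consensus",
    "passing_set",
]


def aggregate_replicates(
    matrix: ExpressionMatrix, tissue_labels: Mapping[str, str], source: str = ""
) -> TissueProfile:
    """Collapse replicate samples to one value per tissue by arithmetic mean.

    Every sample must be mapped to a tissue; every tissue in the map must
    have at least one sample present in the matrix.
    """
    unmapped = [s for s in matrix.sample_ids if s not in tissue_labels]
    if unmapped:
        raise ValidationError(f"samples missing from the tissue map: {unmapped}")
    groups = pd.Series({s: tissue_labels[s] for s in matrix.sample_ids})
    empty = set(tissue_labels.values()) - set(groups.values)
    if empty:
        raise ValidationError(f"tissues with zero samples: {sorted(empty)}")
    prof = matrix.values.T.groupby(groups).mean().T
    prof = prof[sorted(prof.columns)]
    return TissueProfile(prof, source=source or matrix.context)


def proportional_scores(profile: TissueProfile) -> pd.Series:
    """Per-gene testis proportion: testis value / row sum over all tissues.

    NaN where the row sum is zero (the score is undefined, not 0/0).
    Missing tissue values are treated as zero contribution.
    """
    vals = profile.values.fillna(0.0)
    total = vals.sum(axis=1)
    testis = vals[profile.testis_column]
    with np.errstate(invalid="ignore", divide="ignore"):
        score = testis / total
    score[total == 0] = np.nan
    score.name = "proportional_score"
    return score


def proportional_score(profile: TissueProfile, gene_id: str) -> float:
    if gene_id not in profile.values.index:
        raise KeyError(f"gene {gene_id!r} not present in source {profile.source!r}")
    return float(proportional_scores(profile).loc[gene_id])


def screen_source(
    profile: TissueProfile, tiers: Sequence[float] = (0.9, 0.99)
) -> pd.DataFrame:
    """Score every gene of one source and flag tier passage (inclusive).

    Returns a DataFrame indexed by gene with columns ``source``,
    ``proportional_score`` and one boolean ``pass_<tier>`` per tier.
    Zero-row genes carry an undefined (NA) score and fail all tiers.
    """
    if len(tiers) == 0:
        raise ValidationError("screen_source needs at least one tier")
    for t in tiers:
        if not 0.0 < t <= 1.0:
            raise ValidationError(f"tier must lie in (0, 1], got {t}")
    score = proportional_scores(profile)
    out = pd.DataFrame({"source": profile.source, "proportional_score": score})
    for t in sorted(tiers):
        out[tier_column(t)] = (score >= t).fillna(False)
    return out


def tier_column(tier: float) -> str:
    return f"pass_{tier:g}"


def passing_set(screen: pd.DataFrame, tier: float) -> set[str]:
    col = tier_column(tier)
    if col not in screen.columns:
        raise KeyError(f"screen has no tier column {col!r}")
    return set(screen.index[screen[col]])


@dataclass(frozen=True)
class ConsensusSet:
    """Cross-source consensus of testis-biased genes.

    ``membership`` is a genes x sources boolean DataFrame covering the union
    of all per-source passing sets; ``mode`` records whether the consensus is
    the union (default, the non-redundant total across sources) or the
    intersection of per-source sets.
    """

    membership: pd.DataFrame
    mode: str = "union"

    @property
    def genes(self) -> set[str]:
        m = self.membership
        if self.mode == "intersection":
            return set(m.index[m.all(axis=1)])
        return set(m.index[m.any(axis=1)])

    @property
    def sources(self) -> list[str]:
        return self.membership.columns.tolist()

    def per_source(self) -> dict[str, set[str]]:
        return {s: set(self.membership.index[self.membership[s]]) for s in self.sources}

    def venn_counts(self) -> dict[frozenset, int]:
        """Count genes in every non-empty Venn region (exact membership)."""
        counts: dict[frozenset, int] = {}
        srcs = self.sources
        for r in range(1, len(srcs) + 1):
            for combo in combinations(srcs, r):
                region = frozenset(combo)
                mask = np.ones(len(self.membership), dtype=bool)
                for s in srcs:
                    col = self.membership[s].to_numpy()
                    mask &= col if s in region else ~col
                counts[region] = int(mask.sum())
        return counts

    def to_frame(self) -> pd.DataFrame:
        df = self.membership.copy()
        df["n_sources"] = df.sum(axis=1).astype(int)
        df["region"] = [
            "+".join(s for s in self.sources if row[s])
            for _, row in self.membership.iterrows()
        ]
        df["in_consensus"] = [g in self.genes for g in df.index]
        return df.sort_index()


def consensus(per_source_sets: Mapping[str, Iterable[str]], mode: str = "union") -> ConsensusSet:
    """Build the consensus from per-source passing gene sets.

    The union mode mirrors the non-redundant cross-source total; Venn-region
    counts are derivable from the membership table.
    """
    if len(per_source_sets) == 0:
        raise ValidationError("consensus needs at least one source set")
    if mode not in ("union", "intersection"):
        raise ValidationError(f"mode must be union|intersection, got {mode!r}")
    sets = {s: set(g) for s, g in per_source_sets.items()}
    universe = sorted(set(chain.from_iterable(sets.values())))
    membership = pd.DataFrame(
        {s: [g in sets[s] for g in universe] for s in sets}, index=universe
    )
    cs = ConsensusSet(membership, mode=mode)
    logger.info(
        "consensus (%s) over %d sources: %d genes", mode, len(sets), len(cs.genes)
    )
    return cs
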