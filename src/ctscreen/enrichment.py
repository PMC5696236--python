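"""Cancer-gene classification and Monte Carlo set enrichment.

Genes are classified per tumor type from their S-score: oncogene-like when
the score is >= +3, tumor-suppressor-like when <= -3 (inclusive cutoffs),
otherwise neither. Whether a query gene set (the testis-biased set or the CT
catalog) is enriched or depleted for cancer genes is tested by Monte Carlo
resampling: random gene sets of the query's size are drawn uniformly without
replacement from the universe of genes with an S-score in that tumor, and
the category count of each random set forms the null distribution. Because
draws are without replacement, the exact null is hypergeometric — used as
the closed-form oracle in the test suite, never as the implementation.

Empirical p-values carry the add-one (Davison-Hinkley) correction,
p = (1 + #{null at least as extreme}) / (n_sims + 1), so they are never zero.
The three category tests (oncogene, suppressor, cancer_gene = both) reuse the
same simulated draws within a tumor for coherence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import SScoreTable, ValidationError, logger

__all__ = [
    "CATEGORIES",
    "classify",
    "EnrichmentResult",
    "monte_carlo_enrichment",
    "enrich_tumor",
    "enrich_all",
]

CATEGORIES = ("oncogene", "suppressor", "cancer_gene")


def classify(
    s_table: SScoreTable,
    onco_cutoff: float = 3.0,
    supp_cutoff: float = -3.0,
    inclusive: bool = True,
) -> pd.DataFrame:
    """Three-way partition of every gene x tumor S-score.

    Returns a long DataFrame with columns ``gene_id``, ``tumor_type``,
    ``s_score``, ``gene_class`` and ``missing``; NA scores are classed
    "neither" and flagged missing. ``inclusive`` selects >= / <= cutoffs
    (default) versus strict > / <.
    """
    if not supp_cutoff < onco_cutoff:
        raise ValidationError(
            f"supp_cutoff ({supp_cutoff}) must be < onco_cutoff ({onco_cutoff})"
        )
    long = s_table.values.stack(future_stack=True).rename("s_score").reset_index()
    long.columns = ["gene_id", "tumor_type", "s_score"]
    s = long["s_score"]
    if inclusive:
        onco, supp = s >= onco_cutoff, s <= supp_cutoff
    else:
        onco, supp = s > onco_cutoff, s < supp_cutoff
    long["gene_class"] = np.select([onco, supp], ["oncogene", "suppressor"], "neither")
    long["missing"] = s.isna()
    long.loc[long["missing"], "gene_class"] = "neither"
    return long


@dataclass(frozen=True)
class EnrichmentResult:
    """Outcome of one Monte Carlo enrichment test for one category."""

    tumor_type: str
    category: str
    universe_size: int
    category_size: int
    query_size: int
    observed_count: int
    null_counts: np.ndarray = field(repr=False)
    p_enrich: float = 1.0
    p_deplete: float = 1.0
    p_two_sided: float = 1.0
    call: str = "neither"

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_counts))

    @property
    def null_ci(self) -> tuple[float, float]:
        return tuple(np.percentile(self.null_counts, [2.5, 97.5]))

    def to_row(self) -> dict:
        lo, hi = self.null_ci
        return {
            "tumor_type": self.tumor_type,
            "category": self.category,
            "universe_size": self.universe_size,
            "category_size": self.category_size,
            "query_size": self.query_size,
            "observed_count": self.observed_count,
            "null_mean": self.null_mean,
            "null_p2.5": lo,
            "null_p97.5": hi,
            "p_enrich": self.p_enrich,
            "p_deplete": self.p_deplete,
            "p_two_sided": self.p_two_sided,
            "call": self.call,
        }


def _pvalues_and_call(
    null_counts: np.ndarray, observed: int, alpha: float
) -> tuple[float, float, float, str]:
    n_sims = len(null_counts)
    p_enrich = (1 + int(np.sum(null_counts >= observed))) / (n_sims + 1)
    p_deplete = (1 + int(np.sum(null_counts <= observed))) / (n_sims + 1)
    p_two = min(1.0, 2.0 * min(p_enrich, p_deplete))
    call = "neither"
    if p_two <= alpha:
        call = "enriched" if p_enrich < p_deplete else "depleted"
    return p_enrich, p_deplete, p_two, call


def _draw_category_counts(
    masks: np.ndarray, query_size: int, n_sims: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n_sims`` random subsets of ``query_size`` indices and count, per
    row of ``masks`` (categories x universe), how many members each draw hits."""
    n_cat, n_universe = masks.shape
    counts = np.empty((n_cat, n_sims), dtype=np.int64)
    for i in range(n_sims):
        idx = rng.choice(n_universe, size=query_size, replace=False)
        counts[:, i] = masks[:, idx].sum(axis=1)
    return counts


def monte_carlo_enrichment(
    universe: Sequence[bool] | np.ndarray,
    query_size: int,
    observed_count: int,
    n_sims: int = 10000,
    seed: int | np.random.Generator = 0,
    alpha: float = 0.05,
    tumor_type: str = "",
    category: str = "cancer_gene",
) -> EnrichmentResult:
    """Monte Carlo test of one category for one tumor.

    ``universe`` is the per-gene category-membership indicator over all genes
    with an S-score in the tumor. Each simulation draws ``query_size`` genes
    uniformly without replacement and counts members.
    """
    mask = np.asarray(universe, dtype=bool)
    if mask.size == 0:
        raise ValidationError("monte_carlo_enrichment: empty universe")
    if query_size > mask.size:
        raise ValidationError(
            f"query_size ({query_size}) exceeds universe size ({mask.size})"
        )
    if observed_count > query_size:
        raise ValidationError(
            f"observed_count ({observed_count}) exceeds query_size ({query_size})"
        )
    if n_sims < 1:
        raise ValidationError("n_sims must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    null_counts = _draw_category_counts(mask[None, :], query_size, n_sims, rng)[0]
    p_e, p_d, p_2, call = _pvalues_and_call(null_counts, observed_count, alpha)
    return EnrichmentResult(
        tumor_type=tumor_type,
        category=category,
        universe_size=int(mask.size),
        category_size=int(mask.sum()),
        query_size=int(query_size),
        observed_count=int(observed_count),
        null_counts=null_counts,
        p_enrich=p_e,
        p_deplete=p_d,
        p_two_sided=p_2,
        call=call,
    )


def enrich_tumor(
    classification: pd.DataFrame,
    tumor_type: str,
    query_genes: Iterable[str],
    n_sims: int = 10000,
    seed: int | np.random.Generator = 0,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Run the three category tests (oncogene, suppressor, cancer_gene) for
    one tumor on shared simulated draws.

    The universe is every gene with a non-missing S-score in the tumor; the
    effective query is the query set intersected with that universe.
    """
    sub = classification[
        (classification["tumor_type"] == tumor_type) & ~classification["missing"]
    ]
    if sub.empty:
        raise ValidationError(f"no genes with S-scores for tumor {tumor_type!r}")
    genes = sub["gene_id"].to_numpy()
    classes = sub["gene_class"].to_numpy()
    query = set(query_genes) & set(genes)
    if not query:
        raise ValidationError(
            f"query set shares no genes with the S-score universe of {tumor_type!r}"
        )
    in_query = np.array([g in query for g in genes])
    masks = np.vstack(
        [
            classes == "oncogene",
            classes == "suppressor",
            (classes == "oncogene") | (classes == "suppressor"),
        ]
    )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = _draw_category_counts(masks, int(in_query.sum()), n_sims, rng)
    results = []
    for row, cat in zip(counts, CATEGORIES):
        observed = int((masks[CATEGORIES.index(cat)] & in_query).sum())
        p_e, p_d, p_2, call = _pvalues_and_call(row, observed, alpha)
        results.append(
            EnrichmentResult(
                tumor_type=tumor_type,
                category=cat,
                universe_size=len(genes),
                category_size=int(masks[CATEGORIES.index(cat)].sum()),
                query_size=int(in_query.sum()),
                observed_count=observed,
                null_counts=row,
                p_enrich=p_e,
                p_deplete=p_d,
                p_two_sided=p_2,
                call=call,
            )
        )
    return results


def enrich_all(
    s_table: SScoreTable,
    query_genes: Iterable[str],
    n_sims: int = 10000,
    seed: int = 0,
    alpha: float = 0.05,
    onco_cutoff: float = 3.0,
    supp_cutoff: float = -3.0,
) -> pd.DataFrame:
    """Enrichment over every tumor type; one independent substream per tumor.

    Returns a tidy table (one row per tumor x category) ready for a
    box-plot-style summary of the null distributions.
    """
    classification = classify(s_table, onco_cutoff, supp_cutoff)
    query = set(query_genes)
    rows = []
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(s_table.tumor_types))
    for child, tumor in zip(children, s_table.tumor_types):
        rng = np.random.default_rng(child)
        for res in enrich_tumor(classification, tumor, query, n_sims, rng, alpha):
            rows.append(res.to_row())
        logger.info("enrichment done for tumor %s", tumor)
    out = pd.DataFrame(rows)
    out.index = pd.RangeIndex(len(out), name="row")
    return out
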