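"""Tumor-side CT calling: prevalence filter, sharing matrix, catalog.

A testis-biased gene is called a putative cancer/testis (CT) gene in a tumor
type when it is expressed (strictly above the expression cutoff, default 1 in
the matrix's native unit) in at least 10% — or 15% under the stringent tier —
of that tumor's informative samples. Informative means the sample has a
non-missing value for the gene, so missingness can never inflate prevalence.
Prevalence is compared against the threshold as an exact rational; no
floating-point rounding enters the boundary decision.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, ValidationError, logger
from .testis_bias import ConsensusSet

__all__ = [
    "CTCalls",
    "prevalence_filter",
    "SharingMatrix",
    "sharing_matrix",
    "combine_screens",
    "ct_column",
]


def ct_column(threshold: float) -> str:
    return f"ct_{threshold:g}"


def _exact_threshold(threshold: float) -> Fraction:
    # via Decimal(str(...)) so 0.1 means the decimal 1/10, not its binary float
    return Fraction(Decimal(str(threshold)))


@dataclass(frozen=True)
class CTCalls:
    """Per-gene CT calls for one tumor type.

    ``table`` is indexed by gene with columns ``n_informative``,
    ``n_expressing``, ``prevalence`` and one boolean ``ct_<threshold>`` per
    prevalence tier. ``missing_genes`` lists candidates absent from the tumor
    matrix (reported, never silently dropped).
    """

    tumor_type: str
    table: pd.DataFrame
    expr_cutoff: float
    unit: str
    missing_genes: tuple[str, ...] = ()

    def called(self, threshold: float) -> set[str]:
        col = ct_column(threshold)
        if col not in self.table.columns:
            raise KeyError(f"no calls at prevalence threshold {threshold}")
        return set(self.table.index[self.table[col]])


def prevalence_filter(
    tumor_matrix: ExpressionMatrix,
    candidate_genes: Iterable[str],
    expr_cutoff: float = 1.0,
    prevalence_thresholds: Sequence[float] = (0.10, 0.15),
) -> CTCalls:
    """Call CT genes in one tumor by the expression-prevalence rule.

    A sample counts as expressing iff its value is strictly greater than
    ``expr_cutoff``; a gene is CT at a tier iff
    n_expressing / n_informative >= tier (inclusive, exact rational).
    """
    candidates = list(dict.fromkeys(candidate_genes))
    if not candidates:
        raise ValidationError("prevalence_filter: empty candidate gene set")
    if tumor_matrix.values.shape[1] == 0:
        raise ValidationError(
            f"prevalence_filter: tumor matrix {tumor_matrix.context!r} has no samples"
        )
    present = [g for g in candidates if g in tumor_matrix.values.index]
    missing = tuple(g for g in candidates if g not in tumor_matrix.values.index)
    if missing:
        logger.warning(
            "tumor %s: %d candidate genes absent from the matrix: %s",
            tumor_matrix.context, len(missing), list(missing)[:10],
        )
    sub = tumor_matrix.values.loc[present]
    informative = sub.notna()
    n_inf = informative.sum(axis=1).astype(int)
    n_expr = ((sub > expr_cutoff) & informative).sum(axis=1).astype(int)
    if (n_inf == 0).any():
        bad = n_inf.index[n_inf == 0].tolist()
        raise ValidationError(
            f"prevalence_filter: genes with zero informative samples in "
            f"{tumor_matrix.context!r}: {bad}"
        )
    table = pd.DataFrame(
        {
            "n_informative": n_inf,
            "n_expressing": n_expr,
            "prevalence": n_expr / n_inf,
        }
    )
    for thr in sorted(prevalence_thresholds):
        frac = _exact_threshold(thr)
        # n_expr / n_inf >= p/q  <=>  n_expr * q >= p * n_inf  (integers)
        table[ct_column(thr)] = (
            n_expr * frac.denominator >= frac.numerator * n_inf
        )
    return CTCalls(
        tumor_type=tumor_matrix.context,
        table=table,
        expr_cutoff=expr_cutoff,
        unit=tumor_matrix.unit,
        missing_genes=missing,
    )


@dataclass(frozen=True)
class SharingMatrix:
    """Pairwise CT-gene sharing across tumor types at one prevalence tier.

    ``shared`` is symmetric with the per-tumor CT count on the diagonal;
    ``exclusive`` counts genes called in that tumor and no other;
    ``fraction_exclusive`` is the fraction of all called genes found in
    exactly one tumor type.
    """

    threshold: float
    shared: pd.DataFrame
    exclusive: pd.Series
    fraction_exclusive: float


def sharing_matrix(
    calls: Mapping[str, CTCalls] | Mapping[str, Iterable[str]],
    threshold: float = 0.10,
) -> SharingMatrix:
    if len(calls) < 2:
        raise ValidationError("sharing_matrix needs at least two tumor types")
    sets: dict[str, set[str]] = {}
    for t, c in calls.items():
        sets[t] = c.called(threshold) if isinstance(c, CTCalls) else set(c)
    tumors = list(sets)
    shared = pd.DataFrame(
        [[len(sets[a] & sets[b]) for b in tumors] for a in tumors],
        index=tumors, columns=tumors, dtype=int,
    )
    all_genes = set().union(*sets.values())
    n_holding = {g: sum(g in sets[t] for t in tumors) for g in all_genes}
    exclusive = pd.Series(
        {t: sum(1 for g in sets[t] if n_holding[g] == 1) for t in tumors},
        name="exclusive", dtype=int,
    )
    frac = (
        sum(1 for g in all_genes if n_holding[g] == 1) / len(all_genes)
        if all_genes else 0.0
    )
    return SharingMatrix(threshold, shared, exclusive, frac)


def combine_screens(
    consensus: ConsensusSet,
    calls: Mapping[str, CTCalls],
    threshold: float = 0.10,
) -> pd.DataFrame:
    """Catalog of putative CT genes: testis-biased AND CT-called in >=1 tumor.

    Returns a DataFrame indexed by gene with the list of tumor types in which
    the gene is called, the tumor count, and an ``exclusive`` flag for genes
    called in exactly one tumor type. Calls must have been computed over the
    consensus genes only (pipeline ordering is enforced).
    """
    consensus_genes = consensus.genes
    per_tumor: dict[str, set[str]] = {}
    for tumor, c in calls.items():
        outside = set(c.table.index) - consensus_genes
        if outside:
            raise ValidationError(
                f"calls for tumor {tumor!r} cover genes outside the consensus "
                f"set (pipeline ordering violation): {sorted(outside)[:10]}"
            )
        per_tumor[tumor] = c.called(threshold)
    rows = {}
    for gene in sorted(set().union(*per_tumor.values()) if per_tumor else set()):
        tumors = sorted(t for t, s in per_tumor.items() if gene in s)
        rows[gene] = {
            "tumor_types": ",".join(tumors),
            "n_tumors": len(tumors),
            "exclusive": len(tumors) == 1,
        }
    catalog = pd.DataFrame.from_dict(rows, orient="index")
    if catalog.empty:
        catalog = pd.DataFrame(columns=["tumor_types", "n_tumors", "exclusive"])
    catalog.index.name = "gene_id"
    logger.info(
        "catalog at prevalence %g: %d putative CT genes (%d tumor-exclusive)",
        threshold, len(catalog),
        int(catalog["exclusive"].sum()) if len(catalog) else 0,
    )
    return catalog
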