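"""Typed tabular containers and TSV readers/writers for the CT-gene screen.

All files are UTF-8, tab-separated, with a header row; the first column holds
gene (or sample) identifiers, which are treated as opaque strings. Missing
values are encoded as ``NA``. Gene-identifier harmonization across sources is
assumed to have been done upstream and is a documented precondition, not a
service this package provides.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "EXPRESSION_UNITS",
    "ExpressionMatrix",
    "TissueProfile",
    "ClinicalTable",
    "SScoreTable",
    "InfiltrationTable",
    "ValidationError",
    "read_expression_matrix",
    "read_tissue_profile",
    "read_clinical_table",
    "read_sscore_table",
    "read_infiltration_table",
    "read_gene_list",
    "write_table",
    "write_gene_list",
]

EXPRESSION_UNITS = ("TPM", "FPKM", "RSEM")

NA_REP = "NA"

logger = logging.getLogger("ctscreen")
if not logger.handlers:  # default: per-stage lines to stderr
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[%(name)s] %(levelname)s %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


class ValidationError(ValueError):
    """An input table violates a declared invariant; the message carries
    the offending identifiers or cell coordinates."""


def _check_unique(labels: pd.Index, what: str) -> None:
    if labels.has_duplicates:
        dupes = labels[labels.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dupes}")


def _check_numeric_body(df: pd.DataFrame, path: str) -> pd.DataFrame:
    """Coerce the body to floats; a non-numeric cell raises with its
    (row label, column label) coordinates."""
    out = {}
    for col in df.columns:
        vals = np.empty(len(df), dtype=float)
        for i, raw in enumerate(df[col]):
            if raw is None or (isinstance(raw, float) and np.isnan(raw)):
                vals[i] = np.nan
                continue
            try:
                vals[i] = float(raw)  # exact round-trip, unlike pd.to_numeric
            except (TypeError, ValueError):
                raise ValidationError(
                    f"{path}: non-numeric value {raw!r} at row "
                    f"{df.index[i]!r}, column {col!r}"
                ) from None
        out[col] = vals
    return pd.DataFrame(out, index=df.index)


def _check_non_negative(values: pd.DataFrame, what: str) -> None:
    arr = values.to_numpy(dtype=float)
    bad = (arr < 0) | np.isinf(arr)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            f"{what}: negative or non-finite value {arr[i, j]} at "
            f"row {values.index[i]!r}, column {values.columns[j]!r}"
        )


@dataclass(frozen=True)
class ExpressionMatrix:
    """Non-negative gene x sample expression values with a declared unit.

    ``values`` is a genes-by-samples DataFrame; NaN marks a missing
    (non-informative) measurement, negative or infinite entries are rejected.
    ``unit`` is one of TPM / FPKM / RSEM and is recorded so that every
    threshold comparison downstream can state which unit it used.
    ``context`` is a free-text label (source atlas or tumor-type code).
    """

    values: pd.DataFrame
    unit: str
    context: str = ""

    def __post_init__(self) -> None:
        if self.unit not in EXPRESSION_UNITS:
            raise ValidationError(
                f"unit must be one of {EXPRESSION_UNITS}, got {self.unit!r}"
            )
        _check_unique(self.values.index, "gene IDs")
        _check_unique(self.values.columns, "sample IDs")
        _check_non_negative(self.values, f"ExpressionMatrix({self.context})")

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class TissueProfile:
    """One aggregated expression value per gene per normal tissue for a
    single source atlas; exactly one column must be named "testis"
    (case-insensitive)."""

    values: pd.DataFrame
    source: str = ""

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene IDs")
        _check_unique(self.values.columns, "tissue IDs")
        testis = [c for c in self.values.columns if str(c).lower() == "testis"]
        if len(testis) != 1:
            raise ValidationError(
                f"TissueProfile({self.source}): expected exactly one 'testis' "
                f"column, found {testis or 'none'}"
            )
        _check_non_negative(self.values, f"TissueProfile({self.source})")

    @property
    def testis_column(self) -> str:
        return next(c for c in self.values.columns if str(c).lower() == "testis")

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def tissue_ids(self) -> list[str]:
        return self.values.columns.tolist()


@dataclass(frozen=True)
class ClinicalTable:
    """Overall-survival records: per sample, follow-up time in days and a
    binary event indicator (1 = death observed, 0 = censored). The time unit
    is fixed to days; no auto-detection is attempted."""

    data: pd.DataFrame  # index: sample_id; columns: time_days, event

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample IDs")
        missing = {"time_days", "event"} - set(self.data.columns)
        if missing:
            raise ValidationError(f"ClinicalTable missing columns: {sorted(missing)}")
        t = self.data["time_days"].to_numpy(dtype=float)
        e = self.data["event"].to_numpy(dtype=float)
        if np.any(~np.isfinite(t)) or np.any(t < 0):
            i = int(np.argwhere(~np.isfinite(t) | (t < 0))[0][0])
            raise ValidationError(
                f"ClinicalTable: invalid time {t[i]} for sample {self.data.index[i]!r}"
            )
        if not np.isin(e, (0.0, 1.0)).all():
            i = int(np.argwhere(~np.isin(e, (0.0, 1.0)))[0][0])
            raise ValidationError(
                f"ClinicalTable: event must be 0/1, got {e[i]} for sample "
                f"{self.data.index[i]!r}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def time(self) -> np.ndarray:
        return self.data["time_days"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy(dtype=int)


@dataclass(frozen=True)
class SScoreTable:
    """Per-gene, per-tumor-type S-scores (an integrative cancer-gene score
    combining mutation, methylation, CNV and expression evidence). The score
    is consumed as an input, never computed here. Missing entries (NA) are
    allowed; present entries must be finite."""

    values: pd.DataFrame  # genes x tumor types

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene IDs")
        _check_unique(self.values.columns, "tumor types")
        arr = self.values.to_numpy(dtype=float)
        bad = np.isinf(arr)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"SScoreTable: non-finite value at row {self.values.index[i]!r}, "
                f"column {self.values.columns[j]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def tumor_types(self) -> list[str]:
        return self.values.columns.tolist()


@dataclass(frozen=True)
class InfiltrationTable:
    """Per-sample CD8+ infiltration score (a bulk-expression-derived estimate
    of cytotoxic T-cell abundance, precomputed upstream)."""

    scores: pd.Series  # index: sample_id

    def __post_init__(self) -> None:
        _check_unique(self.scores.index, "sample IDs")
        arr = self.scores.to_numpy(dtype=float)
        if np.any(~np.isfinite(arr)):
            i = int(np.argwhere(~np.isfinite(arr))[0][0])
            raise ValidationError(
                f"InfiltrationTable: non-finite score for sample "
                f"{self.scores.index[i]!r}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return self.scores.index.tolist()


# ---------------------------------------------------------------------------
# readers / writers


def _read_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", index_col=0, dtype=object,
        na_values=[NA_REP], keep_default_na=False,
    )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = None
    return df


def read_expression_matrix(path, unit: str, context: str = "") -> ExpressionMatrix:
    """Read a genes-x-samples TSV (first column gene IDs, header sample IDs)."""
    raw = _read_tsv(path)
    return ExpressionMatrix(_check_numeric_body(raw, str(path)), unit=unit,
                            context=context or str(path))


def read_tissue_profile(path, source: str = "") -> TissueProfile:
    raw = _read_tsv(path)
    return TissueProfile(_check_numeric_body(raw, str(path)),
                         source=source or str(path))


def read_clinical_table(path) -> ClinicalTable:
    raw = _read_tsv(path)
    return ClinicalTable(_check_numeric_body(raw, str(path)))


def read_sscore_table(path) -> SScoreTable:
    raw = _read_tsv(path)
    return SScoreTable(_check_numeric_body(raw, str(path)))


def read_infiltration_table(path) -> InfiltrationTable:
    raw = _read_tsv(path)
    num = _check_numeric_body(raw, str(path))
    if "cd8_score" not in num.columns:
        raise ValidationError(f"{path}: expected a 'cd8_score' column")
    return InfiltrationTable(num["cd8_score"])


def read_gene_list(path) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes: Iterable[str], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def write_table(result, path) -> None:
    """Write any container or DataFrame as TSV.

    Floats are written with the shortest round-tripping representation, so
    ``read(write(X)) == X`` holds at full precision; missing values become
    ``NA``.
    """
    if isinstance(result, (ExpressionMatrix, TissueProfile, SScoreTable)):
        df = result.values
        index_label = "gene_id"
    elif isinstance(result, ClinicalTable):
        df = result.data
        index_label = "sample_id"
    elif isinstance(result, InfiltrationTable):
        df = result.scores.to_frame("cd8_score")
        index_label = "sample_id"
    elif isinstance(result, pd.Series):
        df = result.to_frame()
        index_label = result.index.name or "id"
    elif isinstance(result, pd.DataFrame):
        df = result
        index_label = result.index.name or "id"
    else:
        raise TypeError(f"cannot write object of type {type(result).__name__}")
    df.to_csv(path, sep="\t", na_rep=NA_REP, index_label=index_label)
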