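"""Survival screen: Kaplan-Meier, log-rank, Storey q-values, tier patterns.

Per gene and tumor type, patients are split into expressers (expression
strictly > 1 in the tumor's native unit) and non-expressers, and the survival
difference is tested with the standard unweighted log-rank test. Genes
expressed in fewer than 30 samples are skipped. Within each tumor the
log-rank p-values are converted to Storey q-values and genes with q <= 0.05
are classified as associated with good prognosis (expressers show fewer
deaths than expected, signed O-E < 0) or poor prognosis (more).

The published screen then inspected three-tier Kaplan-Meier plots
(no expression / below-median / above-median expression, the median taken
over expressing samples only) by eye for a dose-response pattern. Here that
manual step is replaced by an explicit surrogate: the restricted mean
survival time (RMST, the area under the KM curve up to the largest event
time common to all three tiers) must be strictly ordered consistently with
the two-group direction. The two-group result is always reported
independently of the pattern flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ClinicalTable, ExpressionMatrix, ValidationError, logger

__all__ = [
    "KMCurve",
    "km_estimator",
    "LogrankResult",
    "logrank_test",
    "q_values",
    "assign_groups",
    "rmst",
    "three_tier_pattern",
    "screen_prognosis",
    "plot_km_groups",
]


@dataclass(frozen=True)
class KMCurve:
    """Kaplan-Meier product-limit estimate as a right-continuous,
    non-increasing step function starting at S(0-) = 1."""

    times: np.ndarray      # unique event times, ascending
    survival: np.ndarray   # S(t) at and after each event time
    n_at_risk: np.ndarray
    n_events: np.ndarray
    max_followup: float

    def __call__(self, t) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right")
        s = np.concatenate([[1.0], self.survival])
        out = s[idx]
        return float(out) if out.ndim == 0 else out

    def rmst(self, tau: float) -> float:
        """Area under the curve on [0, tau]."""
        if tau < 0:
            raise ValidationError("rmst truncation time must be >= 0")
        grid = np.concatenate([[0.0], self.times[self.times < tau], [tau]])
        heights = self(grid[:-1])  # right-continuous: value on [t_i, t_{i+1})
        return float(np.sum(np.diff(grid) * heights))


def _as_surv_arrays(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=float)
    if t.size == 0:
        raise ValidationError("empty survival input")
    if t.shape != e.shape:
        raise ValidationError("times and events must have equal length")
    if np.any(t < 0) or np.any(~np.isfinite(t)):
        raise ValidationError("survival times must be finite and >= 0")
    if not np.isin(e, (0.0, 1.0)).all():
        raise ValidationError("events must be 0/1")
    return t, e.astype(int)


def km_estimator(times, events) -> KMCurve:
    """Product-limit estimate of the survival function."""
    t, e = _as_surv_arrays(times, events)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    event_times = np.unique(t[e == 1])
    n = t.size
    surv = []
    risk = []
    deaths = []
    s = 1.0
    for et in event_times:
        at_risk = int(np.sum(t >= et))
        d = int(np.sum((t == et) & (e == 1)))
        s *= 1.0 - d / at_risk
        surv.append(s)
        risk.append(at_risk)
        deaths.append(d)
    return KMCurve(
        times=event_times,
        survival=np.asarray(surv, dtype=float),
        n_at_risk=np.asarray(risk, dtype=int),
        n_events=np.asarray(deaths, dtype=int),
        max_followup=float(t.max()),
    )


@dataclass(frozen=True)
class LogrankResult:
    chi2: float
    p_value: float
    o_minus_e: float   # observed minus expected events in the group of interest
    variance: float
    n_events: int
    defined: bool = True


def logrank_test(group_of_interest, times, events) -> LogrankResult:
    """Unweighted two-group log-rank test.

    ``group_of_interest`` is a boolean vector (True = expresser); the signed
    O-E is reported for that group so the caller can set the prognosis
    direction. Both groups must be non-empty; with zero events the statistic
    is undefined and flagged (``defined=False``).
    """
    g = np.asarray(group_of_interest, dtype=bool)
    t, e = _as_surv_arrays(times, events)
    if g.shape != t.shape:
        raise ValidationError("group vector length mismatch")
    if g.all() or (~g).all():
        raise ValidationError("log-rank requires two non-empty groups")
    n_events = int(e.sum())
    if n_events == 0:
        return LogrankResult(np.nan, np.nan, np.nan, np.nan, 0, defined=False)
    o_minus_e = 0.0
    var = 0.0
    for et in np.unique(t[e == 1]):
        at_risk = t >= et
        n = int(at_risk.sum())
        n1 = int((at_risk & g).sum())
        d = int(((t == et) & (e == 1)).sum())
        d1 = int(((t == et) & (e == 1) & g).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        # both groups fully overlap at every event time; no information
        return LogrankResult(0.0, 1.0, o_minus_e, 0.0, n_events, defined=False)
    chi2 = o_minus_e**2 / var
    p = float(stats.chi2.sf(chi2, df=1))
    return LogrankResult(float(chi2), p, float(o_minus_e), float(var), n_events)


def q_values(p_values: Sequence[float], min_storey: int = 100) -> np.ndarray:
    """Storey q-values with smoother-based pi0 estimation.

    pi0 is estimated on the lambda grid 0.05, 0.10, ..., 0.95 as
    #{p > lambda} / (m (1 - lambda)), a cubic smoother is fit to the grid and
    evaluated at the largest lambda. When the estimate leaves (0, 1] or fewer
    than ``min_storey`` p-values are supplied, the method falls back to
    pi0 = 1, i.e. Benjamini-Hochberg.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    pi0 = 1.0
    if p.size >= min_storey:
        lam = np.arange(0.05, 0.96, 0.05)
        pi0_lam = np.array([np.mean(p > l) / (1 - l) for l in lam])
        # cubic smoother over the grid, evaluated at max(lambda)
        coeffs = np.polyfit(lam, pi0_lam, deg=3)
        pi0_hat = float(np.polyval(coeffs, lam[-1]))
        if 0.0 < pi0_hat <= 1.0:
            pi0 = pi0_hat
    bh = multipletests(p, method="fdr_bh")[1]
    return np.minimum(pi0 * bh, 1.0)


GROUP_LABELS = ("not_expressed", "below_median", "above_median")


def assign_groups(
    values: pd.Series | np.ndarray, expr_cutoff: float = 1.0, n_tiers: int = 2
) -> np.ndarray:
    """Expression-based patient grouping.

    Two-tier mode: "not_expressed" (value <= cutoff) vs "expressed"
    (strictly > cutoff). Three-tier mode further splits expressers at their
    median: values <= median go to "below_median" (ties at the median fall
    below), the rest to "above_median".
    """
    v = np.asarray(values, dtype=float)
    expressed = v > expr_cutoff
    if n_tiers == 2:
        return np.where(expressed, "expressed", "not_expressed")
    if n_tiers != 3:
        raise ValidationError("n_tiers must be 2 or 3")
    out = np.full(v.shape, "not_expressed", dtype=object)
    if expressed.any():
        med = float(np.median(v[expressed]))
        out[expressed & (v <= med)] = "below_median"
        out[expressed & (v > med)] = "above_median"
    return out.astype(str)


def rmst(times, events, tau: float) -> float:
    """Restricted mean survival time: area under the KM curve on [0, tau]."""
    return km_estimator(times, events).rmst(tau)


def three_tier_pattern(
    values,
    times,
    events,
    direction: str,
    expr_cutoff: float = 1.0,
    min_tier_size: int = 10,
) -> bool | None:
    """Dose-response surrogate for the manual three-tier KM inspection.

    Truncation time is the largest event time common to all three tiers
    (the minimum over tiers of each tier's largest event time); the pattern
    holds iff the tier RMSTs are strictly ordered consistently with the
    two-group direction — "good": none < below < above, "poor": reversed.
    Returns None (pattern undefined) when a tier is smaller than
    ``min_tier_size`` or has no events.
    """
    if direction not in ("good", "poor"):
        raise ValidationError(f"direction must be good|poor, got {direction!r}")
    v = np.asarray(values, dtype=float)
    t, e = _as_surv_arrays(times, events)
    groups = assign_groups(v, expr_cutoff, n_tiers=3)
    rmsts = {}
    taus = []
    for label in GROUP_LABELS:
        mask = groups == label
        if mask.sum() < max(min_tier_size, 1):
            return None
        if e[mask].sum() == 0:
            return None
        taus.append(t[mask & (e == 1)].max())
    tau = float(min(taus))
    for label in GROUP_LABELS:
        mask = groups == label
        rmsts[label] = km_estimator(t[mask], e[mask]).rmst(tau)
    none_, below, above = (rmsts[l] for l in GROUP_LABELS)
    if direction == "good":
        return bool(none_ < below < above)
    return bool(none_ > below > above)


def screen_prognosis(
    catalog: pd.DataFrame | Iterable[str],
    tumor_matrices: Mapping[str, ExpressionMatrix],
    clinical_tables: Mapping[str, ClinicalTable],
    expr_cutoff: float = 1.0,
    q_cutoff: float = 0.05,
    min_expressed: int = 30,
    min_tier_size: int = 10,
    pool_qvalues: bool = False,
    check_pattern: bool = True,
) -> pd.DataFrame:
    """Gene x tumor survival screen over the CT catalog.

    Every catalog gene is tested in every tumor type where it is expressed in
    at least ``min_expressed`` samples having clinical data. q-values are
    computed within tumor type by default (``pool_qvalues`` pools all tests).
    Direction is "good" when expressers show fewer deaths than expected.
    For significant genes the three-tier RMST dose-response flag is computed.
    """
    genes = list(catalog.index) if isinstance(catalog, pd.DataFrame) else list(catalog)
    if not genes:
        raise ValidationError("screen_prognosis: empty catalog")
    records: list[dict] = []
    for tumor, matrix in tumor_matrices.items():
        if tumor not in clinical_tables:
            raise ValidationError(f"no clinical table for tumor {tumor!r}")
        clin = clinical_tables[tumor]
        samples = [s for s in matrix.sample_ids if s in set(clin.sample_ids)]
        if not samples:
            raise ValidationError(
                f"no overlapping samples between expression and clinical data "
                f"for tumor {tumor!r}"
            )
        clin_sub = clin.data.loc[samples]
        t = clin_sub["time_days"].to_numpy(dtype=float)
        e = clin_sub["event"].to_numpy(dtype=int)
        for gene in genes:
            if gene not in matrix.values.index:
                continue
            v = matrix.values.loc[gene, samples].to_numpy(dtype=float)
            informative = np.isfinite(v)
            vi, ti, ei = v[informative], t[informative], e[informative]
            expressed = vi > expr_cutoff
            rec = {
                "gene_id": gene,
                "tumor_type": tumor,
                "n_samples": int(informative.sum()),
                "n_expressed": int(expressed.sum()),
                "logrank_chi2": np.nan,
                "p_value": np.nan,
                "q_value": np.nan,
                "o_minus_e": np.nan,
                "direction": "",
                "monotone_pattern": pd.NA,
                "tested": False,
                "skip_reason": "",
            }
            if expressed.sum() < min_expressed:
                rec["skip_reason"] = "min_expressed"
            elif expressed.all():
                rec["skip_reason"] = "no_nonexpressers"
            else:
                lr = logrank_test(expressed, ti, ei)
                if not lr.defined:
                    rec["skip_reason"] = "no_events"
                else:
                    rec.update(
                        logrank_chi2=lr.chi2, p_value=lr.p_value,
                        o_minus_e=lr.o_minus_e, tested=True,
                    )
            records.append(rec)
    out = pd.DataFrame.from_records(records)
    if out.empty:
        raise ValidationError("screen_prognosis: no catalog gene found in any tumor")
    # q-values within tumor type (default) or pooled
    out["q_value"] = np.nan
    if pool_qvalues:
        mask = out["tested"].to_numpy()
        out.loc[mask, "q_value"] = q_values(out.loc[mask, "p_value"].to_numpy())
    else:
        for tumor, idx in out.groupby("tumor_type").groups.items():
            mask = out.loc[idx, "tested"]
            tested_idx = idx[mask]
            if len(tested_idx):
                out.loc[tested_idx, "q_value"] = q_values(
                    out.loc[tested_idx, "p_value"].to_numpy()
                )
    significant = out["tested"] & (out["q_value"] <= q_cutoff)
    out.loc[significant, "direction"] = np.where(
        out.loc[significant, "o_minus_e"] < 0, "good", "poor"
    )
    if check_pattern:
        for i in out.index[significant]:
            gene, tumor = out.loc[i, "gene_id"], out.loc[i, "tumor_type"]
            matrix, clin = tumor_matrices[tumor], clinical_tables[tumor]
            samples = [s for s in matrix.sample_ids if s in set(clin.sample_ids)]
            v = matrix.values.loc[gene, samples].to_numpy(dtype=float)
            informative = np.isfinite(v)
            clin_sub = clin.data.loc[samples]
            pat = three_tier_pattern(
                v[informative],
                clin_sub["time_days"].to_numpy(dtype=float)[informative],
                clin_sub["event"].to_numpy(dtype=int)[informative],
                out.loc[i, "direction"],
                expr_cutoff,
                min_tier_size,
            )
            out.loc[i, "monotone_pattern"] = pat
    n_sig = int(significant.sum())
    logger.info(
        "survival screen: %d tested pairs, %d significant at q<=%g",
        int(out["tested"].sum()), n_sig, q_cutoff,
    )
    out.index = pd.RangeIndex(len(out), name="row")
    return out


def plot_km_groups(values, times, events, expr_cutoff=1.0, n_tiers=3,
                   title: str = "", path=None):
    """Write a Kaplan-Meier plot of the expression tiers (optional output)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = assign_groups(values, expr_cutoff, n_tiers)
    labels = GROUP_LABELS if n_tiers == 3 else ("not_expressed", "expressed")
    t, e = _as_surv_arrays(times, events)
    fig, ax = plt.subplots(figsize=(5, 4))
    for label in labels:
        mask = groups == label
        if not mask.any():
            continue
        km = km_estimator(t[mask], e[mask])
        xs = np.concatenate([[0.0], np.repeat(km.times, 2), [km.max_followup]])
        ys = np.concatenate([[1.0, 1.0], np.repeat(km.survival, 2)])[: xs.size]
        ax.plot(xs, ys, label=f"{label} (n={int(mask.sum())})")
    ax.set_xlabel("time (days)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
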