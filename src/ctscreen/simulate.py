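"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the statistical structure the screen assumes, at desk
scale: multi-source normal-tissue profiles with planted testis-restricted
genes laid out on a known Venn design; tumor cohorts with CT genes planted
at exact prevalences (exact-count planting, so threshold-boundary behavior
is deterministic); S-scores as a standard-normal background plus planted
extreme oncogene/suppressor components; exponential survival whose hazard
multiplies up over the planted prognostic genes a patient expresses; and CD8
scores that are a linear function of how many designated genes a sample
expresses, plus Gaussian noise.

A single global seed is expanded into fixed per-component substreams, so any
one component can be regenerated independently and identically. Every
generated bundle ships its ground truth alongside the data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    ClinicalTable,
    ExpressionMatrix,
    InfiltrationTable,
    SScoreTable,
    TissueProfile,
    ValidationError,
    logger,
    write_table,
)

__all__ = [
    "GroundTruth",
    "gen_normal_atlases",
    "gen_tumor_cohort",
    "gen_sscores",
    "gen_survival",
    "gen_cd8",
    "BundleParams",
    "gen_bundle",
]

# fixed substream ids so components can be regenerated independently
_STREAMS = {"atlas": 1, "tumor": 2, "sscore": 3, "survival": 4, "cd8": 5}


def _rng(seed: int, component: str, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAMS[component], index))
    )


@dataclass
class GroundTruth:
    """Planted truth serialized alongside every generated dataset."""

    seed: int = 0
    testis_regions: dict = field(default_factory=dict)   # gene -> sorted source list
    planted_testis: dict = field(default_factory=dict)   # source -> sorted gene list
    planted_ct: dict = field(default_factory=dict)       # tumor -> {gene: prevalence}
    planted_oncogenes: dict = field(default_factory=dict)    # tumor -> gene list
    planted_suppressors: dict = field(default_factory=dict)  # tumor -> gene list
    planted_prognostic: dict = field(default_factory=dict)
    # tumor -> {gene: {"direction": str, "hazard_ratio": float}}
    planted_cd8: dict = field(default_factory=dict)
    # tumor -> {"genes": [...], "shift": float}

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _default_overlap_design(sources: Sequence[str], n_planted: int) -> dict[frozenset, int]:
    """Spread planted genes over all Venn regions: ~40% in the all-source
    region, the rest split evenly over pairs and singles."""
    regions: list[frozenset] = [frozenset(sources)]
    if len(sources) > 1:
        from itertools import combinations

        for r in range(len(sources) - 1, 0, -1):
            regions.extend(frozenset(c) for c in combinations(sources, r))
    design = {r: 0 for r in regions}
    design[frozenset(sources)] = int(round(0.4 * n_planted)) if len(regions) > 1 else n_planted
    rest = n_planted - design[frozenset(sources)]
    others = regions[1:]
    for i in range(rest):
        design[others[i % len(others)]] += 1
    return design


def _background_row(rng: np.random.Generator, n_tissues: int, testis_idx: int) -> np.ndarray:
    """Log-normal background; testis proportion forced <= 0.5 (swap with the
    row minimum in the rare draw where a single tissue dominates)."""
    row = rng.lognormal(mean=0.0, sigma=1.0, size=n_tissues)
    if row[testis_idx] / row.sum() > 0.5:
        j = int(np.argmin(row))
        row[testis_idx], row[j] = row[j], row[testis_idx]
    return row


def _planted_row(rng: np.random.Generator, n_tissues: int, testis_idx: int) -> np.ndarray:
    """Testis-restricted profile: >= 95% of total expression in testis."""
    total = rng.lognormal(mean=3.0, sigma=1.0)
    prop = rng.uniform(0.95, 0.999)
    rest = rng.dirichlet(np.ones(n_tissues - 1)) * (1 - prop) * total
    row = np.empty(n_tissues)
    row[testis_idx] = prop * total
    row[np.arange(n_tissues) != testis_idx] = rest
    return row


def gen_normal_atlases(
    n_genes: int = 1000,
    n_tissues: int = 16,
    n_sources: int = 3,
    testis_fraction: float = 0.05,
    overlap_design: Mapping[Iterable[str], int] | None = None,
    seed: int = 0,
    sources: Sequence[str] | None = None,
) -> tuple[dict[str, TissueProfile], GroundTruth]:
    """Per-source tissue profiles with a known testis-restricted Venn design.

    Background genes draw i.i.d. log-normal expression over all tissues, so
    their testis proportion centers at 1/n_tissues and is capped at 0.5 by
    construction; planted genes concentrate at least 95% of expression in
    testis in every source of their Venn region, and behave as background in
    the others.
    """
    if not 0.0 <= testis_fraction < 1.0:
        raise ValidationError("testis_fraction must lie in [0, 1)")
    if n_tissues < 2:
        raise ValidationError("need at least 2 tissues")
    sources = list(sources) if sources else [f"atlas{i + 1}" for i in range(n_sources)]
    genes = _gene_ids(n_genes)
    n_planted = int(round(testis_fraction * n_genes))
    if overlap_design is None:
        design = _default_overlap_design(sources, n_planted) if n_planted else {}
    else:
        design = {frozenset(k): int(v) for k, v in overlap_design.items()}
        for region in design:
            if not region or not region <= set(sources):
                raise ValidationError(f"overlap design region {set(region)} not a subset of sources")
        if sum(design.values()) > n_planted:
            raise ValidationError(
                f"overlap design places {sum(design.values())} genes but only "
                f"{n_planted} are planted"
            )
    planted_genes = genes[:n_planted]
    regions: dict[str, list[str]] = {}
    i = 0
    for region, count in design.items():
        for g in planted_genes[i : i + count]:
            regions[g] = sorted(region)
        i += count
    for g in planted_genes[i:]:  # any remainder joins the all-source region
        regions[g] = sorted(sources)
    tissues = ["testis"] + [f"tissue{i:02d}" for i in range(1, n_tissues)]
    testis_idx = 0
    profiles: dict[str, TissueProfile] = {}
    truth = GroundTruth(seed=seed, testis_regions=regions,
                        planted_testis={s: [] for s in sources})
    for si, source in enumerate(sources):
        rng = _rng(seed, "atlas", si)
        mat = np.empty((n_genes, n_tissues))
        for gi, g in enumerate(genes):
            if g in regions and source in regions[g]:
                mat[gi] = _planted_row(rng, n_tissues, testis_idx)
                truth.planted_testis[source].append(g)
            else:
                mat[gi] = _background_row(rng, n_tissues, testis_idx)
        profiles[source] = TissueProfile(
            pd.DataFrame(mat, index=genes, columns=tissues), source=source
        )
    logger.info(
        "generated %d-source atlas set: %d genes, %d planted testis-restricted",
        len(sources), n_genes, n_planted,
    )
    return profiles, truth


def gen_tumor_cohort(
    gene_ids: Sequence[str],
    n_samples: int,
    ct_design: Mapping[str, float],
    seed: int = 0,
    noise_rate: float = 0.01,
    expr_cutoff: float = 1.0,
    tumor_type: str = "TUM",
    unit: str = "RSEM",
    tumor_index: int = 0,
) -> ExpressionMatrix:
    """Tumor expression matrix with CT genes planted at exact prevalences.

    For each planted gene exactly round(prevalence * n_samples) samples get a
    value strictly above the cutoff (cutoff + log-normal); all other values
    sit at or below the cutoff. Background genes express only via
    Bernoulli(noise_rate) sporadic activation.
    """
    genes = list(gene_ids)
    unknown = set(ct_design) - set(genes)
    if unknown:
        raise ValidationError(f"ct_design references unknown genes: {sorted(unknown)}")
    for g, p in ct_design.items():
        if not 0.0 <= p <= 1.0:
            raise ValidationError(f"prevalence for {g} must lie in [0, 1], got {p}")
    rng = _rng(seed, "tumor", tumor_index)
    samples = [f"{tumor_type}_S{i:04d}" for i in range(1, n_samples + 1)]

    def below(size):
        return np.minimum(rng.lognormal(-2.0, 1.0, size=size), expr_cutoff)

    def above(size):
        return expr_cutoff + rng.lognormal(0.5, 0.75, size=size)

    mat = below((len(genes), n_samples))
    if noise_rate > 0:
        noise = rng.random((len(genes), n_samples)) < noise_rate
        mat[noise] = above(int(noise.sum()))
    for gi, g in enumerate(genes):
        if g in ct_design:
            k = int(round(ct_design[g] * n_samples))
            row = below(n_samples)
            idx = rng.choice(n_samples, size=k, replace=False)
            row[idx] = above(k)
            mat[gi] = row
    return ExpressionMatrix(
        pd.DataFrame(mat, index=genes, columns=samples), unit=unit, context=tumor_type
    )


def gen_sscores(
    gene_ids: Sequence[str],
    tumor_types: Sequence[str],
    onco_fraction: float = 0.02,
    supp_fraction: float = 0.02,
    effect: float = 4.5,
    seed: int = 0,
    exclude_genes: Iterable[str] = (),
) -> tuple[SScoreTable, dict, dict]:
    """S-score table: N(0,1) background with planted extreme components.

    Planted oncogenes draw N(+effect, 0.5) and suppressors N(-effect, 0.5),
    per tumor. ``exclude_genes`` (e.g. the planted testis set) are never
    planted as cancer genes — this builds in the depletion structure the
    enrichment test is meant to detect. Returns the table plus the per-tumor
    planted oncogene and suppressor lists.
    """
    if onco_fraction + supp_fraction >= 1:
        raise ValidationError("onco_fraction + supp_fraction must be < 1")
    genes = list(gene_ids)
    excluded = set(exclude_genes)
    eligible = [g for g in genes if g not in excluded]
    rng = _rng(seed, "sscore")
    values = rng.normal(0.0, 1.0, size=(len(genes), len(tumor_types)))
    onco: dict[str, list[str]] = {}
    supp: dict[str, list[str]] = {}
    n_onco = int(round(onco_fraction * len(genes)))
    n_supp = int(round(supp_fraction * len(genes)))
    gene_pos = {g: i for i, g in enumerate(genes)}
    for tj, tumor in enumerate(tumor_types):
        if n_onco + n_supp > len(eligible):
            raise ValidationError("not enough eligible genes to plant cancer genes")
        picked = rng.choice(len(eligible), size=n_onco + n_supp, replace=False)
        onco_genes = sorted(eligible[i] for i in picked[:n_onco])
        supp_genes = sorted(eligible[i] for i in picked[n_onco:])
        for g in onco_genes:
            values[gene_pos[g], tj] = rng.normal(effect, 0.5)
        for g in supp_genes:
            values[gene_pos[g], tj] = rng.normal(-effect, 0.5)
        onco[tumor], supp[tumor] = onco_genes, supp_genes
    table = SScoreTable(pd.DataFrame(values, index=genes, columns=list(tumor_types)))
    return table, onco, supp


def gen_survival(
    expression: ExpressionMatrix,
    prognostic_design: Mapping[str, tuple[str, float]],
    baseline_hazard: float = 1.0 / 1000.0,
    censor_rate: float = 1.0 / 2000.0,
    seed: int = 0,
    expr_cutoff: float = 1.0,
    tumor_index: int = 0,
) -> ClinicalTable:
    """Exponential survival driven by the planted prognostic genes.

    Each sample's hazard is ``baseline_hazard`` times the product of the
    hazard ratios of every planted gene it expresses (value > cutoff).
    Censoring is independent exponential at ``censor_rate`` (0 = none, every
    event observed). Directions must be consistent with the hazard ratio:
    "poor" needs HR > 1, "good" HR < 1.
    """
    for g, (direction, hr) in prognostic_design.items():
        if g not in expression.values.index:
            raise ValidationError(f"prognostic design references unknown gene {g!r}")
        if hr <= 0:
            raise ValidationError(f"hazard ratio for {g} must be > 0, got {hr}")
        if direction not in ("good", "poor"):
            raise ValidationError(f"direction for {g} must be good|poor")
        if (direction == "poor") != (hr > 1):
            raise ValidationError(
                f"direction {direction!r} inconsistent with hazard ratio {hr} for {g}"
            )
    rng = _rng(seed, "survival", tumor_index)
    samples = expression.sample_ids
    hazard = np.full(len(samples), baseline_hazard)
    for g, (_, hr) in prognostic_design.items():
        expressed = (expression.values.loc[g] > expr_cutoff).to_numpy()
        hazard *= np.where(expressed, hr, 1.0)
    event_t = rng.exponential(1.0 / hazard)
    if censor_rate > 0:
        censor_t = rng.exponential(1.0 / censor_rate, size=len(samples))
    else:
        censor_t = np.full(len(samples), np.inf)
    time = np.minimum(event_t, censor_t)
    event = (event_t <= censor_t).astype(int)
    return ClinicalTable(
        pd.DataFrame({"time_days": time, "event": event}, index=pd.Index(samples))
    )


def gen_cd8(
    expression: ExpressionMatrix,
    associated_genes: Iterable[str],
    shift: float = 1.5,
    noise_sd: float = 1.0,
    seed: int = 0,
    expr_cutoff: float = 1.0,
    tumor_index: int = 0,
) -> InfiltrationTable:
    """CD8 score = shift x (count of associated genes expressed) + noise."""
    if noise_sd <= 0:
        raise ValidationError("noise_sd must be > 0")
    genes = sorted(set(associated_genes))
    missing = [g for g in genes if g not in expression.values.index]
    if missing:
        raise ValidationError(f"cd8-associated genes missing from matrix: {missing}")
    rng = _rng(seed, "cd8", tumor_index)
    if genes:
        counts = (expression.values.loc[genes] > expr_cutoff).sum(axis=0).to_numpy(float)
    else:
        counts = np.zeros(len(expression.sample_ids))
    scores = shift * counts + rng.normal(0.0, noise_sd, size=counts.size)
    return InfiltrationTable(pd.Series(scores, index=expression.values.columns,
                                       name="cd8_score"))


# ---------------------------------------------------------------------------
# full input bundle


@dataclass
class BundleParams:
    """Study conditions of the default synthetic bundle (desk scale)."""

    n_genes: int = 1000
    n_tissues: int = 16
    n_sources: int = 3
    testis_fraction: float = 0.05
    tumor_types: tuple[str, ...] = ("TUMA", "TUMB", "TUMC")
    n_samples: int = 120
    noise_rate: float = 0.01
    expr_cutoff: float = 1.0
    onco_fraction: float = 0.05
    supp_fraction: float = 0.05
    sscore_effect: float = 4.5
    poor_hazard_ratio: float = 3.0
    good_hazard_ratio: float = 1.0 / 3.0
    baseline_hazard: float = 1.0 / 1000.0
    censor_rate: float = 1.0 / 2000.0
    cd8_shift: float = 1.5
    cd8_noise_sd: float = 1.0


def _ct_design_for_tumor(
    planted_union: list[str], tumor_idx: int, n_tumors: int
) -> dict[str, float]:
    """Deterministic per-tumor CT design with known sharing structure:
    a block shared by all tumors at high prevalence, a per-tumor exclusive
    block, and a ladder of mid prevalences."""
    design: dict[str, float] = {}
    shared = planted_union[:6]
    for g, p in zip(shared, (0.5, 0.5, 0.4, 0.4, 0.3, 0.3)):
        design[g] = p
    excl_start = 6 + tumor_idx * 4
    for g in planted_union[excl_start : excl_start + 4]:
        design[g] = 0.35
    ladder_start = 6 + n_tumors * 4
    ladder = planted_union[ladder_start : ladder_start + 6]
    for i, g in enumerate(ladder):
        if i % n_tumors != tumor_idx:  # rotate membership across tumors
            design[g] = 0.2 + 0.05 * (i % 3)
    return design


def gen_bundle(
    outdir, params: BundleParams | None = None, seed: int = 0
) -> tuple[Path, GroundTruth]:
    """Generate and write the full input bundle plus its ground truth.

    Files written to ``outdir``: one ``atlas_<source>.tsv`` tissue profile
    per source, per-tumor ``tumor_<T>.tsv`` / ``clinical_<T>.tsv`` /
    ``cd8_<T>.tsv``, ``sscores.tsv`` and ``ground_truth.json``.
    """
    params = params or BundleParams()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    profiles, truth = gen_normal_atlases(
        n_genes=params.n_genes,
        n_tissues=params.n_tissues,
        n_sources=params.n_sources,
        testis_fraction=params.testis_fraction,
        seed=seed,
    )
    genes = next(iter(profiles.values())).gene_ids
    planted_union = sorted(truth.testis_regions)
    for source, prof in profiles.items():
        write_table(prof, outdir / f"atlas_{source}.tsv")

    n_tumors = len(params.tumor_types)
    for ti, tumor in enumerate(params.tumor_types):
        design = _ct_design_for_tumor(planted_union, ti, n_tumors)
        truth.planted_ct[tumor] = dict(sorted(design.items()))
        matrix = gen_tumor_cohort(
            genes, params.n_samples, design, seed=seed,
            noise_rate=params.noise_rate, expr_cutoff=params.expr_cutoff,
            tumor_type=tumor, tumor_index=ti,
        )
        write_table(matrix, outdir / f"tumor_{tumor}.tsv")

        # prognostic genes: pick the two highest-prevalence planted CTs
        ranked = sorted(design, key=lambda g: (-design[g], g))
        poor_gene, good_gene = ranked[0], ranked[1]
        prog = {
            poor_gene: ("poor", params.poor_hazard_ratio),
            good_gene: ("good", params.good_hazard_ratio),
        }
        truth.planted_prognostic[tumor] = {
            g: {"direction": d, "hazard_ratio": hr} for g, (d, hr) in prog.items()
        }
        clinical = gen_survival(
            matrix, prog, baseline_hazard=params.baseline_hazard,
            censor_rate=params.censor_rate, seed=seed,
            expr_cutoff=params.expr_cutoff, tumor_index=ti,
        )
        write_table(clinical, outdir / f"clinical_{tumor}.tsv")

        cd8_genes = sorted({good_gene, *ranked[2:4]})
        truth.planted_cd8[tumor] = {"genes": cd8_genes, "shift": params.cd8_shift}
        cd8 = gen_cd8(
            matrix, cd8_genes, shift=params.cd8_shift,
            noise_sd=params.cd8_noise_sd, seed=seed,
            expr_cutoff=params.expr_cutoff, tumor_index=ti,
        )
        write_table(cd8, outdir / f"cd8_{tumor}.tsv")

    sscores, onco, supp = gen_sscores(
        genes, params.tumor_types,
        onco_fraction=params.onco_fraction, supp_fraction=params.supp_fraction,
        effect=params.sscore_effect, seed=seed, exclude_genes=planted_union,
    )
    truth.planted_oncogenes = onco
    truth.planted_suppressors = supp
    write_table(sscores, outdir / "sscores.tsv")
    truth.seed = seed
    truth.to_json(outdir / "ground_truth.json")
    logger.info("synthetic bundle written to %s", outdir)
    return outdir, truth
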