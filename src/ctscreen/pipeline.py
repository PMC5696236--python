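"""End-to-end orchestration of the CT screen over a file bundle.

Stages run in order — testis_bias, ct_detection, enrichment, survival,
infiltration — communicating only through TSV files in the output directory,
so each stage is restartable and individually testable. A JSON run manifest
records the config snapshot, SHA-256 digests of every input, per-stage
outputs and timings, the seed and the package version, making every output
traceable to exact inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .config import ConfigError, RunConfig, _from_mapping
from .ct_detection import combine_screens, prevalence_filter, sharing_matrix
from .enrichment import enrich_all
from .infiltration import aggregate_association, per_gene_association
from .io import (
    ValidationError,
    logger,
    read_clinical_table,
    read_expression_matrix,
    read_infiltration_table,
    read_sscore_table,
    read_tissue_profile,
    write_gene_list,
    write_table,
)
from .survival import screen_prognosis
from .testis_bias import consensus, passing_set, screen_source, tier_column

__all__ = ["PipelineConfig", "load_pipeline_config", "run_pipeline", "StageError",
           "RunManifest"]

STAGES = ("testis_bias", "ct_detection", "enrichment", "survival", "infiltration")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    run: RunConfig
    atlases: dict[str, str]      # source -> tissue-profile TSV
    tumors: dict[str, str]       # tumor type -> expression TSV
    clinical: dict[str, str]     # tumor type -> clinical TSV
    sscores: str                 # S-score TSV
    cd8: dict[str, str]          # tumor type -> CD8 TSV
    outdir: str = "results"
    tumor_unit: str = "RSEM"

    def __post_init__(self) -> None:
        for name in ("atlases", "tumors", "clinical"):
            if not getattr(self, name):
                raise ConfigError(f"pipeline config missing mandatory field {name!r}")
        if not self.sscores:
            raise ConfigError("pipeline config missing mandatory field 'sscores'")


def load_pipeline_config(path) -> PipelineConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{path}: top level must be a mapping")
    raw = dict(raw)
    run = _from_mapping(raw.pop("run", {}) or {})
    known = {f.name for f in dataclasses.fields(PipelineConfig)} - {"run"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown pipeline config keys: {sorted(unknown)}")
    missing = {"atlases", "tumors", "clinical", "sscores"} - set(raw)
    if missing:
        raise ConfigError(f"pipeline config missing mandatory field(s): {sorted(missing)}")
    return PipelineConfig(run=run, **raw)


def config_for_bundle(bundle_dir, outdir=None, run: RunConfig | None = None) -> PipelineConfig:
    """Build a pipeline config pointing at a generated input bundle."""
    bundle = Path(bundle_dir)
    atlases = {p.stem.removeprefix("atlas_"): str(p) for p in sorted(bundle.glob("atlas_*.tsv"))}
    tumors = {p.stem.removeprefix("tumor_"): str(p) for p in sorted(bundle.glob("tumor_*.tsv"))}
    clinical = {p.stem.removeprefix("clinical_"): str(p) for p in sorted(bundle.glob("clinical_*.tsv"))}
    cd8 = {p.stem.removeprefix("cd8_"): str(p) for p in sorted(bundle.glob("cd8_*.tsv"))}
    return PipelineConfig(
        run=run or RunConfig(),
        atlases=atlases, tumors=tumors, clinical=clinical,
        sscores=str(bundle / "sscores.tsv"), cd8=cd8,
        outdir=str(outdir or bundle / "results"),
    )


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str = __version__
    input_digests: dict = field(default_factory=dict)
    stages: list = field(default_factory=list)
    started: str = ""
    finished: str = ""
    complete: bool = False

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all stages in order; abort naming the failing stage."""
    cfg = config.run
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config={"run": cfg.to_dict(),
                **{k: getattr(config, k) for k in
                   ("atlases", "tumors", "clinical", "sscores", "cd8", "outdir")}},
        seed=cfg.seed,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    for group in (config.atlases, config.tumors, config.clinical, config.cd8):
        for name, p in group.items():
            manifest.input_digests[str(p)] = _sha256(p)
    manifest.input_digests[str(config.sscores)] = _sha256(config.sscores)

    def stage(name):
        t0 = time.perf_counter()

        def done(outputs):
            dt = time.perf_counter() - t0
            logger.info("stage %s finished in %.2fs", name, dt)
            manifest.stages.append(
                {"stage": name, "seconds": round(dt, 3),
                 "outputs": [str(o) for o in outputs]}
            )

        return done

    state: dict[str, Any] = {}
    try:
        done = stage("testis_bias")
        per_source_sets = {}
        stringent_sets = {}
        screens = []
        for source, path in config.atlases.items():
            prof = read_tissue_profile(path, source=source)
            scr = screen_source(prof, cfg.proportional_tiers)
            screens.append(scr)
            write_table(scr, outdir / f"testis_screen_{source}.tsv")
            per_source_sets[source] = passing_set(scr, cfg.active_tier)
            stringent_sets[source] = passing_set(scr, max(cfg.proportional_tiers))
        cs = consensus(per_source_sets, mode=cfg.consensus_mode)
        state["consensus"] = cs
        state["consensus_stringent"] = consensus(stringent_sets, mode=cfg.consensus_mode)
        write_table(cs.to_frame(), outdir / "consensus.tsv")
        write_gene_list(sorted(cs.genes), outdir / "consensus_genes.txt")
        done([outdir / "consensus.tsv"])
    except Exception as exc:  # noqa: BLE001 - abort naming the stage
        raise StageError("testis_bias", exc) from exc

    try:
        done = stage("ct_detection")
        matrices = {
            t: read_expression_matrix(p, unit=config.tumor_unit, context=t)
            for t, p in config.tumors.items()
        }
        state["matrices"] = matrices
        catalogs: dict[tuple[float, float], pd.DataFrame] = {}
        for tier_label, cset in (("", state["consensus"]),
                                 ("stringent", state["consensus_stringent"])):
            tier = cfg.active_tier if not tier_label else max(cfg.proportional_tiers)
            genes = sorted(cset.genes)
            calls = {
                t: prevalence_filter(m, genes, cfg.expr_cutoff,
                                     cfg.prevalence_thresholds)
                for t, m in matrices.items()
            }
            for prev in cfg.prevalence_thresholds:
                catalogs[(tier, prev)] = combine_screens(cset, calls, prev)
            if not tier_label:
                state["calls"] = calls
                share = sharing_matrix(calls, cfg.active_prevalence)
                write_table(share.shared, outdir / "sharing_matrix.tsv")
                write_table(share.exclusive.to_frame(), outdir / "exclusive_counts.tsv")
        for (tier, prev), cat in catalogs.items():
            write_table(cat, outdir / f"catalog_tier{tier:g}_prev{prev:g}.tsv")
        state["catalogs"] = catalogs
        state["catalog"] = catalogs[(cfg.active_tier, cfg.active_prevalence)]
        if state["catalog"].empty:
            raise ValidationError("active catalog is empty")
        done([outdir / "sharing_matrix.tsv"])
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("ct_detection", exc) from exc

    try:
        done = stage("enrichment")
        s_table = read_sscore_table(config.sscores)
        rows = []
        for label, genes in (
            ("testis_biased", sorted(state["consensus"].genes)),
            ("ct_catalog", state["catalog"].index.tolist()),
        ):
            res = enrich_all(
                s_table, genes, n_sims=cfg.n_sims, seed=cfg.seed,
                alpha=cfg.enrichment_alpha,
                onco_cutoff=cfg.onco_cutoff, supp_cutoff=cfg.supp_cutoff,
            )
            res.insert(0, "query", label)
            rows.append(res)
        enrichment = pd.concat(rows, ignore_index=True)
        enrichment.index.name = "row"
        write_table(enrichment, outdir / "enrichment.tsv")
        state["enrichment"] = enrichment
        done([outdir / "enrichment.tsv"])
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("enrichment", exc) from exc

    try:
        done = stage("survival")
        clinical = {t: read_clinical_table(p) for t, p in config.clinical.items()}
        prognosis = screen_prognosis(
            state["catalog"], state["matrices"], clinical,
            expr_cutoff=cfg.expr_cutoff, q_cutoff=cfg.q_cutoff,
            min_expressed=cfg.min_expressed, min_tier_size=cfg.min_tier_size,
            pool_qvalues=cfg.pool_qvalues_across_tumors,
        )
        write_table(prognosis, outdir / "prognosis.tsv")
        state["prognosis"] = prognosis
        done([outdir / "prognosis.tsv"])
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("survival", exc) from exc

    try:
        done = stage("infiltration")
        prognosis = state["prognosis"]
        rows = []
        for tumor, path in config.cd8.items():
            if tumor not in state["matrices"]:
                continue
            cd8 = read_infiltration_table(path)
            matrix = state["matrices"][tumor]
            sig = prognosis[
                (prognosis["tumor_type"] == tumor) & (prognosis["direction"] == "good")
            ]
            good_genes = sig["gene_id"].tolist()
            if good_genes:
                rows.append(
                    aggregate_association(matrix, cd8, good_genes, cfg.expr_cutoff).to_row()
                )
                for g in good_genes:
                    rows.append(
                        per_gene_association(matrix, cd8, g, 3, cfg.expr_cutoff).to_row()
                    )
            else:
                logger.info("tumor %s: no good-prognosis genes; infiltration skipped", tumor)
        assoc = pd.DataFrame(rows)
        assoc.index.name = "row"
        write_table(assoc, outdir / "infiltration.tsv")
        done([outdir / "infiltration.tsv"])
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("infiltration", exc) from exc

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.complete = True
    manifest.to_json(outdir / "manifest.json")
    return manifest
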