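"""End-to-end orchestration: preprocess -> network -> modules -> traits ->
preservation -> genesets -> classify, with a manifest of every artifact.

All randomness flows from one top-level seed; rerunning with the same
configuration and seed reproduces identical artifact digests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, classify, data_io, genesets, modules, network, preservation

logger = logging.getLogger("cwgcna")

STAGES = (
    "preprocess",
    "network",
    "modules",
    "traits",
    "preservation",
    "genesets",
    "classify",
)

__all__ = ["PipelineConfig", "PipelineResult", "StageError", "run_pipeline", "STAGES"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and an error code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}/{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class PipelineConfig:
    """Paths and parameters for a full consensus-network run."""

    expression_paths: list[str]
    trait_paths: list[str]
    out_dir: str
    gene_set_paths: list[str] = field(default_factory=list)
    expression_format: str = "tsv"
    # preprocessing
    max_gene_missing: float = 0.5
    max_sample_missing: float = 0.5
    min_variance: float = 1e-10
    # network
    mode: str = "signed"
    power: int | str = "auto"
    target_r2: float = 0.8
    calibration_quantile: float = 0.95
    # tree cut
    min_module_size: int = 30
    cut_height_fraction: float = 0.99
    kme_rescue_threshold: float = 0.3
    merge_cor: float = 0.75
    # candidate thresholds
    cor_threshold: float = 0.5
    p_threshold: float = 0.05
    # hubs
    hub_quantile: float = 0.95
    # preservation
    n_permutations: int = 100
    # classifier
    alpha: float = 0.35
    cv_folds: int = 5
    classifier_permutations: int = 100
    seed: int = 42
    stop_after: str | None = None

    def validate(self) -> None:
        if len(self.expression_paths) < 2:
            raise StageError("preprocess", "config", "need at least two cohorts")
        for p in [*self.expression_paths, *self.trait_paths, *self.gene_set_paths]:
            if not Path(p).exists():
                raise StageError("preprocess", "missing-input", f"no such file: {p}")
        if self.stop_after is not None and self.stop_after not in STAGES:
            raise StageError("preprocess", "config", f"unknown stage {self.stop_after!r}")


@dataclass
class PipelineResult:
    """Artifacts of a pipeline run plus the manifest written alongside."""

    out_dir: Path
    manifest: dict
    cohorts: list = None
    assignment: modules.ModuleAssignment | None = None
    eigengenes: modules.ModuleEigengenes | None = None
    candidates: association.CandidateModuleReport | None = None
    hub_table: pd.DataFrame | None = None
    preservation_result: preservation.PreservationResult | None = None
    enrichment: list | None = None
    classifier_report: classify.ClassifierReport | None = None


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute the configured stages in order, writing TSV artifacts and a
    manifest (inputs, parameters, seed, content digests) to ``out_dir``."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    result = PipelineResult(out_dir=out, manifest={})

    def save(name: str, writer) -> None:
        path = out / name
        writer(path)
        artifacts[name] = _sha256(path)

    def done(stage: str) -> bool:
        if cfg.stop_after == stage:
            _write_manifest(cfg, out, artifacts, result)
            return True
        return False

    # ---- preprocess -------------------------------------------------
    try:
        logger.info("stage preprocess")
        report = data_io.PreprocessReport()
        cohorts = [
            data_io.load_expression_matrix(
                p, format=cfg.expression_format, cohort_name=Path(p).stem
            )
            for p in cfg.expression_paths
        ]
        cohorts = [
            data_io.filter_missing(
                c,
                cfg.max_gene_missing,
                cfg.max_sample_missing,
                cfg.min_variance,
                report=report,
            )
            for c in cohorts
        ]
        cohorts = data_io.align_cohorts(cohorts)
        traits = {}
        for c, tp in zip(cohorts, cfg.trait_paths):
            tt = data_io.read_trait_table(tp, cohort_name=c.cohort_name)
            tt.cohort_name = c.cohort_name
            traits[c.cohort_name] = tt
        result.cohorts = cohorts
        for c in cohorts:
            save(f"expression_{c.cohort_name}.tsv".replace("/", "_"), c.to_tsv)
        save("preprocess_report.txt", lambda p: Path(p).write_text(str(report) + "\n"))
    except StageError:
        raise
    except Exception as e:
        raise StageError("preprocess", type(e).__name__, str(e)) from e
    if done("preprocess"):
        return result

    # ---- network ----------------------------------------------------
    try:
        logger.info("stage network")
        if cfg.power == "auto":
            reports = [
                network.pick_soft_threshold(c, target_r2=cfg.target_r2, mode=cfg.mode)
                for c in cohorts
            ]
            power = max(r.chosen_power for r in reports)
            save(
                "soft_threshold.tsv",
                lambda p: pd.concat(
                    [r.to_frame().assign(cohort=c.cohort_name) for r, c in zip(reports, cohorts)]
                ).to_csv(p, sep="\t", index=False),
            )
        else:
            power = int(cfg.power)
        toms = [
            network.tom_similarity(network.adjacency_matrix(c, cfg.mode, power))
            for c in cohorts
        ]
        ct = network.build_consensus(toms, q=cfg.calibration_quantile)
        np.save(out / "consensus_tom.npy", ct.consensus.values)
        save(
            "consensus_tom_genes.tsv",
            lambda p: pd.Series(ct.gene_ids, name="gene_id").to_csv(p, sep="\t", index=False),
        )
        result.manifest["power"] = int(power)
    except Exception as e:
        raise StageError("network", type(e).__name__, str(e)) from e
    if done("network"):
        return result

    # ---- modules ----------------------------------------------------
    try:
        logger.info("stage modules")
        dendro, assign = modules.detect_modules(
            ct,
            cohorts,
            min_module_size=cfg.min_module_size,
            cut_height_fraction=cfg.cut_height_fraction,
            kme_rescue_threshold=cfg.kme_rescue_threshold,
        )
        assign = modules.merge_modules(assign, cohorts, merge_cor=cfg.merge_cor)
        eig = modules.compute_eigengenes(assign, cohorts)
        result.assignment, result.eigengenes = assign, eig
        save("modules.tsv", assign.to_tsv)
        save("dendrogram.txt", lambda p: Path(p).write_text(dendro.to_newick_like() + "\n"))
        for name, df in eig.eigengenes.items():
            save(f"eigengenes_{name}.tsv", lambda p, df=df: df.to_csv(p, sep="\t"))
    except Exception as e:
        raise StageError("modules", type(e).__name__, str(e)) from e
    if done("modules"):
        return result

    # ---- traits -----------------------------------------------------
    try:
        logger.info("stage traits")
        for c in cohorts:
            if c.cohort_name not in traits:
                raise ValueError(f"no trait table for cohort {c.cohort_name!r}")
            traits[c.cohort_name].validate_against(c)
        candidates = association.select_candidate_modules(
            eig, traits, cfg.cor_threshold, cfg.p_threshold
        )
        gs = association.gene_significance(cohorts, traits)
        mem = association.module_membership(assign, eig, cohorts)
        hubs = association.hub_score(mem, gs)
        hubs = association.select_hubs(
            hubs, q=cfg.hub_quantile, modules=candidates.selected or None
        )
        result.candidates, result.hub_table = candidates, hubs
        save("candidate_modules.tsv", lambda p: candidates.table.to_csv(p, sep="\t", index=False))
        save("hub_table.tsv", lambda p: hubs.to_csv(p, sep="\t", index_label="gene_id"))
    except StageError:
        raise
    except Exception as e:
        raise StageError("traits", type(e).__name__, str(e)) from e
    if done("traits"):
        return result

    # ---- preservation -----------------------------------------------
    try:
        logger.info("stage preservation")
        focus = candidates.selected or list(assign.modules())
        pres = preservation.module_preservation(
            cohorts[0],
            assign,
            cohorts[1],
            n_permutations=cfg.n_permutations,
            seed=cfg.seed,
            mode=cfg.mode,
            power=result.manifest.get("power", 6),
            modules=focus,
        )
        result.preservation_result = pres
        save("preservation.tsv", lambda p: pres.table.to_csv(p, sep="\t"))
        save("preservation_summary.txt", lambda p: Path(p).write_text(pres.summary() + "\n"))
    except Exception as e:
        raise StageError("preservation", type(e).__name__, str(e)) from e
    if done("preservation"):
        return result

    # ---- genesets ---------------------------------------------------
    try:
        logger.info("stage genesets")
        hub_genes = result.hub_table.index[result.hub_table["is_hub"]].tolist()
        if cfg.gene_set_paths and hub_genes:
            curated = []
            for p in cfg.gene_set_paths:
                curated.extend(genesets.read_gmt(p))
            universe = genesets.GeneSet("universe", frozenset(cohorts[0].gene_ids))
            query = genesets.GeneSet("hubs", frozenset(hub_genes), category="hubs")
            enr = genesets.hypergeometric_enrichment(query, curated, universe)
            result.enrichment = enr
            save(
                "hub_enrichment.tsv",
                lambda p: genesets.enrichment_table(enr).to_csv(p, sep="\t", index=False),
            )
            known = [s for s in curated if s.category == "known_disease"]
            if known:
                novel = genesets.intersect_gene_sets(query, known[0], "difference")
                save(
                    "novel_candidates.txt",
                    lambda p: Path(p).write_text("\n".join(sorted(novel.genes)) + "\n"),
                )
    except Exception as e:
        raise StageError("genesets", type(e).__name__, str(e)) from e
    if done("genesets"):
        return result

    # ---- classify ---------------------------------------------------
    try:
        logger.info("stage classify")
        hub_genes = result.hub_table.index[result.hub_table["is_hub"]].tolist()
        if not hub_genes:
            raise ValueError("no hub genes available as predictors")
        train, test = cohorts[0], cohorts[1]
        y_train = traits[train.cohort_name].phenotype.reindex(train.sample_ids).to_numpy()
        y_test = traits[test.cohort_name].phenotype.reindex(test.sample_ids).to_numpy()
        X_train = train.values.loc[hub_genes].T
        X_test = test.values.loc[hub_genes].T
        rep = classify.permutation_significance(
            X_train,
            y_train,
            alpha=cfg.alpha,
            cv_folds=cfg.cv_folds,
            n_permutations=cfg.classifier_permutations,
            seed=cfg.seed,
            X_eval=X_test,
            y_eval=y_test,
        )
        result.classifier_report = rep
        save(
            "classifier_report.txt",
            lambda p: Path(p).write_text(
                f"alpha\t{cfg.alpha}\nprauc\t{rep.prauc:.6f}\n"
                f"permutation_p\t{rep.permutation_p:.6f}\n"
                f"n_permutations\t{rep.n_permutations}\n"
                f"selected_predictors\t{';'.join(rep.selected_predictors)}\n"
            ),
        )
    except StageError:
        raise
    except Exception as e:
        raise StageError("classify", type(e).__name__, str(e)) from e

    _write_manifest(cfg, out, artifacts, result)
    return result


def _write_manifest(cfg, out: Path, artifacts: dict, result: PipelineResult) -> None:
    manifest = {
        "inputs": {
            "expression": list(cfg.expression_paths),
            "traits": list(cfg.trait_paths),
            "gene_sets": list(cfg.gene_set_paths),
        },
        "parameters": {
            k: v for k, v in asdict(cfg).items()
            if k not in ("expression_paths", "trait_paths", "gene_set_paths", "out_dir")
        },
        "seed": cfg.seed,
        "artifacts": dict(sorted(artifacts.items())),
    }
    manifest.update(result.manifest)
    result.manifest = manifest
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
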