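"""End-to-end orchestration: simulate/load -> validate -> diversity ->
correlation -> Ward clustering -> PCA composite scoring, with all result
tables written to an output directory plus a JSON run manifest for
reproducibility."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .correlation import CorrelationResult, count_significant_pairs, pearson_matrix
from .diversity_stats import DiversityTable, diversity_table
from .exceptions import ConfigError
from .pca_scoring import PCAResult, ScoreTable, pca_scores
from .schema_io import (
    PhenotypeMatrix,
    TraitSchema,
    ValidationReport,
    load_phenotype_matrix,
    load_trait_schema,
    validate_matrix,
    write_phenotype_matrix,
    write_table,
)
from .synthetic_cohort import CohortConfig, default_config, generate_cohort
from .ward_cluster import MergeTree, cluster_matrix, export_newick

log = logging.getLogger("germdiv")


@dataclass
class RunConfig:
    """One pipeline run; exactly one of ``input_path`` / ``simulate`` is set."""

    out_dir: str | Path
    input_path: str | Path | None = None
    simulate: CohortConfig | None = None
    schema_path: str | Path | None = None
    k: int = 4
    standardize_cluster: bool = True
    retain_rule: str = "kaiser"
    retain_k: int | None = None
    score_mode: str = "raw"
    select_rule: str = "median"
    alpha: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if (self.input_path is None) == (self.simulate is None):
            raise ConfigError("set exactly one of input_path / simulate")
        if self.k < 1:
            raise ConfigError("k must be >= 1")

    def to_manifest_dict(self) -> dict:
        return {
            "input_path": str(self.input_path) if self.input_path else None,
            "simulate": None
            if self.simulate is None
            else {
                "n_individuals": self.simulate.n_individuals,
                "seed": self.simulate.seed,
                "clip": self.simulate.clip,
                "correlation": "identity"
                if self.simulate.correlation is None
                else np.asarray(self.simulate.correlation).tolist(),
            },
            "schema_path": str(self.schema_path) if self.schema_path else None,
            "k": self.k,
            "standardize_cluster": self.standardize_cluster,
            "retain_rule": self.retain_rule,
            "retain_k": self.retain_k,
            "score_mode": self.score_mode,
            "select_rule": self.select_rule,
            "alpha": self.alpha,
            "seed": self.seed,
        }


@dataclass
class ResultBundle:
    matrix: PhenotypeMatrix
    validation: ValidationReport
    diversity: DiversityTable
    correlation: CorrelationResult
    tree: MergeTree
    assignments: np.ndarray
    profiles: list
    pca: PCAResult
    scores: ScoreTable
    manifest: dict = field(default_factory=dict)


def _stage(name: str):
    log.info("stage: %s", name)
    return time.perf_counter()


def run_pipeline(config: RunConfig) -> ResultBundle:
    """Execute every stage on one validated matrix and write all outputs."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    schema = load_trait_schema(config.schema_path)

    t0 = _stage("input")
    if config.simulate is not None:
        sim = config.simulate
        if sim.seed != config.seed:
            sim.seed = config.seed
        matrix = generate_cohort(sim, schema=schema)
        write_phenotype_matrix(matrix, out / "cohort.csv")
    else:
        matrix = load_phenotype_matrix(config.input_path, schema)
    timings["input"] = time.perf_counter() - t0

    t0 = _stage("validate")
    report = validate_matrix(matrix, schema)
    if not report.is_valid:
        first = report.errors[0]
        raise ConfigError(
            f"stage 'validate' failed: {len(report.errors)} error(s); first: "
            f"row {first.row}, column {first.column}: {first.message}"
        )
    for w in report.warnings:
        log.warning("validate: %s: %s", w.column, w.message)
    timings["validate"] = time.perf_counter() - t0

    t0 = _stage("diversity")
    diversity = diversity_table(matrix, schema)
    write_table(diversity.qualitative_frame(), out / "diversity_qualitative.csv", decimals=2)
    write_table(diversity.quantitative_frame(), out / "diversity_quantitative.csv", decimals=2)
    timings["diversity"] = time.perf_counter() - t0

    t0 = _stage("correlation")
    corr = pearson_matrix(matrix)
    total, pos, neg = count_significant_pairs(corr, alpha=config.alpha)
    log.info(
        "correlation: %d significant pairs at alpha=%g (%d positive, %d negative)",
        total, config.alpha, pos, neg,
    )
    write_table(corr.r, out / "correlation_r.csv", decimals=3)
    write_table(corr.p, out / "correlation_p.csv", decimals=4)
    corr.pair_list().to_csv(out / "correlation_pairs.csv", index=False, float_format="%.4f")
    timings["correlation"] = time.perf_counter() - t0

    t0 = _stage("cluster")
    log.info("cluster: standardize=%s, k=%d", config.standardize_cluster, config.k)
    tree, assignments, profiles, block = cluster_matrix(
        matrix, k=config.k, standardize_traits=config.standardize_cluster
    )
    (out / "dendrogram.nwk").write_text(export_newick(tree, list(block.index)) + "\n")
    pd.DataFrame({"id": block.index, "group": assignments}).to_csv(
        out / "cluster_assignments.csv", index=False
    )
    profile_rows = []
    for p in profiles:
        for trait in block.columns:
            profile_rows.append(
                {
                    "group": p.group,
                    "count": p.count,
                    "trait": trait,
                    "mean": p.means[trait],
                    "deviation": p.deviations[trait],
                    "salient": dict(p.salient).get(trait, ""),
                }
            )
    pd.DataFrame(profile_rows).to_csv(
        out / "cluster_profiles.csv", index=False, float_format="%.3f"
    )
    timings["cluster"] = time.perf_counter() - t0

    t0 = _stage("pca")
    log.info("pca: retain=%s, score_mode=%s", config.retain_rule, config.score_mode)
    pca, scores = pca_scores(
        matrix,
        retain_rule=config.retain_rule,
        k=config.retain_k,
        score_mode=config.score_mode,
        select_rule=config.select_rule,
    )
    write_table(pca.to_frame(), out / "pca_table.csv", decimals=3)
    write_table(scores.table, out / "scores.csv", decimals=2)
    timings["pca"] = time.perf_counter() - t0

    manifest = {
        "package": "germdiv",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_manifest_dict(),
        "n_individuals": matrix.n_individuals,
        "n_traits": len(matrix.schema),
        "significant_pairs": {"total": total, "positive": pos, "negative": neg},
        "retained_components": pca.retained,
        "n_selected": int(scores.table["selected"].sum()),
        "timings_s": {k: round(v, 4) for k, v in timings.items()},
    }
    manifest["config_sha256"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()
    ).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")

    return ResultBundle(
        matrix=matrix,
        validation=report,
        diversity=diversity,
        correlation=corr,
        tree=tree,
        assignments=assignments,
        profiles=profiles,
        pca=pca,
        scores=scores,
        manifest=manifest,
    )


def default_run(out_dir: str | Path, n: int = 151, seed: int = 42, **kwargs) -> ResultBundle:
    """Convenience: full pipeline on a default synthetic cohort."""
    return run_pipeline(
        RunConfig(
            out_dir=out_dir,
            simulate=default_config(n_individuals=n, seed=seed),
            seed=seed,
            **kwargs,
        )
    )
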