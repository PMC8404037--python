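"""End-to-end orchestration: preprocess → rule inference → clustering →
scoring → network fusion, with every intermediate persisted and a manifest of
content hashes for resumption/reproducibility checks."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import anfis, clustering, fusion, scoring
from .preprocess import AbundanceTable, augment, prefilter_features, read_abundance

__all__ = ["PipelineConfig", "StageError", "PipelineResult", "run_pipeline"]


class StageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    # inputs
    abundance: str | None = None
    orientation: str = "samples"
    label_column: str | None = None
    label_file: str | None = None
    taxonomy: str | None = None
    enrichment: str | None = None
    disease: str | None = None
    outdir: str = "taxafuse_out"
    # preprocessing
    n_top: int = 100
    n_trees: int = 500
    # rule inference
    num_labels: int = 7
    max_iter: int = 10
    step_size: float = 0.01
    # clustering
    minpts: int = 2
    grid_start: float = 1.0
    grid_stop: float | None = None        # None → max integer entry of the rule matrix
    grid_step: float = 0.5
    alias_tol: float = 1e-7
    # scoring
    k_folds: int = 10
    # randomness
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    config: PipelineConfig
    table: AbundanceTable
    inferred: anfis.InferredMatrix
    eps: float
    assignment: clustering.ClusterAssignment
    clustered: clustering.ClusteredMatrix
    scores: scoring.ScoreTable
    network: fusion.FusedNetwork | None
    max_corr_diff: float
    artifacts: dict[str, Path] = field(default_factory=dict)
    log: dict = field(default_factory=dict)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 - stage boundary
                raise StageError(name, exc) from exc

        return wrapped

    return deco


@_stage("preprocess")
def _run_preprocess(config: PipelineConfig, table: AbundanceTable | None) -> AbundanceTable:
    if table is None:
        if config.abundance is None:
            raise ValueError("no abundance input: give a file path or an in-memory table")
        table = read_abundance(
            config.abundance,
            orientation=config.orientation,
            label_column=config.label_column,
            label_file=config.label_file,
        )
    if table.n_features > config.n_top:
        table = prefilter_features(table, n_top=config.n_top, n_trees=config.n_trees, seed=config.seed)
    return table


@_stage("anfis")
def _run_anfis(config: PipelineConfig, table: AbundanceTable):
    aug = augment(table)
    model, inferred = anfis.infer_rule_matrix(
        aug, num_labels=config.num_labels, max_iter=config.max_iter, step_size=config.step_size
    )
    max_diff, _ = anfis.correlation_preservation(aug.features, inferred.values[:, :-1].astype(float))
    return model, inferred, max_diff


@_stage("clustering")
def _run_clustering(config: PipelineConfig, inferred: anfis.InferredMatrix):
    stop = config.grid_stop if config.grid_stop is not None else float(inferred.values.max())
    grid = list(np.arange(config.grid_start, stop + 1e-9, config.grid_step))
    if not grid:
        grid = [config.grid_start]
    return clustering.select_epsilon(
        inferred, grid=grid, minpts=config.minpts, tol=config.alias_tol
    )


@_stage("scoring")
def _run_scoring(config: PipelineConfig, inferred: anfis.InferredMatrix, clustered):
    y = inferred.scaled_values[:, -1]
    return scoring.score_pipeline(clustered, y, k_folds=min(config.k_folds, inferred.n_rules), seed=config.seed)


@_stage("fusion")
def _run_fusion(config: PipelineConfig, clustered, scores):
    taxonomy = fusion.read_taxonomy(config.taxonomy) if config.taxonomy else {}
    features = list(scores.feature_scores)
    name_map = fusion.build_name_map(features, taxonomy)
    table = fusion.read_enrichment(config.enrichment)
    net = fusion.build_network(table, disease=config.disease)
    multi = {k: v for k, v in clustered.provenance.items() if len(v) > 1}
    fusion.infuse_clusters(net, multi, name_map)
    fusion.node_scores(net, scores.feature_scores, name_map)
    return net


def run_pipeline(config: PipelineConfig, table: AbundanceTable | None = None) -> PipelineResult:
    """Run all stages in order, persisting every intermediate under
    ``config.outdir``. A missing enrichment file skips the fusion stage with a
    warning; any stage failure raises :class:`StageError` naming the stage,
    leaving earlier artifacts in place."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    table = _run_preprocess(config, table)
    filtered_path = outdir / "filtered.tsv"
    df = table.to_frame()
    df.insert(0, "label", table.labels)
    df.to_csv(filtered_path, sep="\t")
    artifacts["filtered"] = filtered_path

    model, inferred, max_corr_diff = _run_anfis(config, table)
    inferred_path = outdir / "inferred.tsv"
    pd.DataFrame(
        inferred.values, columns=inferred.feature_names + ["effective_label"]
    ).to_csv(inferred_path, sep="\t", index=False)
    artifacts["inferred"] = inferred_path
    model_path = outdir / "model.json"
    model_path.write_text(json.dumps(_model_to_json(model), indent=1))
    artifacts["model"] = model_path

    eps, assignment, clustered = _run_clustering(config, inferred)
    clusters_path = outdir / "clusters.json"
    clusters_path.write_text(
        json.dumps(
            {
                "eps": eps,
                "minpts": assignment.minpts,
                "assignment": {
                    name: int(lab)
                    for name, lab in zip(inferred.feature_names, assignment.labels)
                },
                "loadings": clustered.loadings,
                "provenance": clustered.provenance,
            },
            indent=1,
        )
    )
    artifacts["clusters"] = clusters_path

    scores = _run_scoring(config, inferred, clustered)
    scores_path = outdir / "scores.tsv"
    _scores_frame(scores, clustered).to_csv(scores_path, sep="\t", index=False)
    artifacts["scores"] = scores_path

    network = None
    if config.enrichment:
        network = _run_fusion(config, clustered, scores)
        net_path = outdir / "network.graphml"
        fusion.export_graph(network, net_path)
        artifacts["network"] = net_path
    else:
        warnings.warn("no enrichment table given: fusion stage skipped", stacklevel=2)

    log = {
        "parameters": config.to_dict(),
        "n_samples": table.n_samples,
        "n_features": table.n_features,
        "effective_samples": inferred.n_rules,
        "max_corr_diff": max_corr_diff,
        "eps": eps,
        "n_clusters": assignment.n_clusters,
        "lambda": scores.lam,
        "score_summary": scores.summary,
    }
    if network is not None:
        log["n_nodes"] = network.graph.number_of_nodes()
        log["n_edges"] = network.graph.number_of_edges()
    log_path = outdir / "run_log.json"
    log_path.write_text(json.dumps(log, indent=1))
    artifacts["log"] = log_path

    manifest = {name: _sha256(p) for name, p in artifacts.items()}
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    artifacts["manifest"] = manifest_path

    return PipelineResult(
        config=config,
        table=table,
        inferred=inferred,
        eps=eps,
        assignment=assignment,
        clustered=clustered,
        scores=scores,
        network=network,
        max_corr_diff=max_corr_diff,
        artifacts=artifacts,
        log=log,
    )


def _model_to_json(model: anfis.TSModel) -> dict:
    return {
        "num_labels": model.num_labels,
        "iterations_run": model.iterations_run,
        "rmse_trajectory": model.rmse_trajectory,
        "variables": [
            {
                "name": v.name,
                "means": [float(m) for m in v.means],
                "sigmas": [float(s) for s in v.sigmas],
                "domain": [float(v.domain[0]), float(v.domain[1])],
            }
            for v in model.input_variables + [model.output_variable]
        ],
        "rules": [
            {
                "antecedent": list(r.antecedent),
                "output_term": r.output_term,
                "consequent": [float(c) for c in r.consequent],
                "degree": r.degree,
            }
            for r in model.rules
        ],
    }


def _scores_frame(scores: scoring.ScoreTable, clustered) -> pd.DataFrame:
    rows = []
    for column, cscore in scores.cluster_scores.items():
        for feat in clustered.provenance[column]:
            rows.append(
                {
                    "feature": feat,
                    "cluster_id": column,
                    "cluster_score": cscore,
                    "loading": clustered.loadings[column][feat],
                    "feature_score": scores.feature_scores[feat],
                }
            )
    return pd.DataFrame(rows)
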