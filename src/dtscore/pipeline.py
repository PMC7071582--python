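"""End-to-end orchestration: inputs -> feature matrix -> ensemble -> report.

Stages run in order (features, network, ontology, targets, ensemble,
evaluate); any failure raises a stage-tagged :class:`PipelineError` and no
partial score files are written.  A JSON manifest records the config, input
hashes, per-stage timings and library versions.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .ensemble import DruggabilityResult, EnsembleConfig, fit_predict_ensemble
from .errors import PipelineError
from .evaluate import feature_tests, roc_auc
from .features import (
    FeatureMatrix,
    assemble_features,
    average_entropy,
    log_transform,
    min_max_scale,
    read_expression,
    read_feature_table,
    tissue_entropy,
)
from .network import (
    CENTRALITY_COLUMNS,
    build_network,
    compute_centralities,
    filter_top_fraction,
    read_edge_table,
)
from .ontology import rank_ontologies, read_gmt, score_all
from .targets import StudySets, build_study_sets, read_catalog

__all__ = ["RunConfig", "run_pipeline", "build_feature_matrix"]

log = logging.getLogger("dtscore")

DEFAULT_INDICATION = "oncolog|cancer|leukemia|lymphoma|melanoma|carcinoma|sarcoma|tumor|tumour|myeloma"


@dataclass
class RunConfig:
    features: str
    edges: str
    catalog: str
    outdir: str
    features_meta: str | None = None
    expression: list[str] = field(default_factory=list)
    gmt: list[str] = field(default_factory=list)
    edge_fraction: float = 0.1
    indication: str = DEFAULT_INDICATION
    n_models: int = 10_000
    n_trees: int = 1000
    mtry: int | str = "auto"
    seed: int = 0
    tune: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise PipelineError(f"[config] unknown keys in {path}: {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class _StageTimer:
    def __init__(self) -> None:
        self.timings: dict[str, float] = {}

    def run(self, stage: str, fn, *args, **kwargs):
        start = time.perf_counter()
        log.info("stage %s: start", stage)
        try:
            result = fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as exc:  # tag every stage failure
            raise PipelineError(f"[{stage}] {exc}") from exc
        elapsed = time.perf_counter() - start
        self.timings[stage] = round(elapsed, 3)
        log.info("stage %s: done in %.2fs", stage, elapsed)
        return result


def build_feature_matrix(
    cfg: RunConfig, sets: StudySets | None = None
) -> FeatureMatrix:
    """Assemble, transform and scale the unified feature matrix.

    Sources: the precomputed feature TSV, averaged tissue entropy over the
    expression files, the five network centralities (flagged heavy-tailed),
    and one ontology rank-score column per GMT category (computed against
    the training positives only, never the holdout).  Median imputation
    excludes the positive set when ``sets`` is given.
    """
    seq_df, kinds, heavy = read_feature_table(cfg.features, cfg.features_meta)
    universe = list(seq_df.index.astype(str))
    seq_df.index = seq_df.index.astype(str)
    sources: list[pd.DataFrame] = [seq_df]
    all_kinds = dict(kinds)
    heavy_cols = set(heavy)

    if cfg.expression:
        entropies = [
            tissue_entropy(read_expression(p)) for p in cfg.expression
        ]
        sources.append(average_entropy(entropies).to_frame())

    edges = read_edge_table(cfg.edges)
    kept = filter_top_fraction(edges, cfg.edge_fraction)
    graph = build_network(kept)
    centralities = compute_centralities(graph, universe)
    sources.append(centralities)
    heavy_cols |= set(CENTRALITY_COLUMNS)

    if cfg.gmt and sets is not None:
        uni = frozenset(universe)
        positives = frozenset(sets.positives)
        for path in cfg.gmt:
            cat = read_gmt(path)
            ranked = rank_ontologies(cat, positives, uni)
            sources.append(score_all(ranked, universe).to_frame())

    exclude = set(sets.positives) if sets is not None else set()
    fm = assemble_features(
        sources, kinds=all_kinds, heavy_tailed=heavy_cols, impute_exclude=exclude
    )
    return min_max_scale(log_transform(fm))


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full workflow and write outputs into ``cfg.outdir``.

    Returns a summary dict with the evaluation report and output paths.
    """
    timer = _StageTimer()
    outdir = Path(cfg.outdir)

    seq_df, _, _ = timer.run("inputs", read_feature_table, cfg.features, cfg.features_meta)
    universe = frozenset(str(p) for p in seq_df.index)

    catalog = timer.run("targets", read_catalog, cfg.catalog)
    sets = timer.run("study_sets", build_study_sets, catalog, universe, cfg.indication)

    fm = timer.run("features", build_feature_matrix, cfg, sets)

    ens_cfg = EnsembleConfig(
        n_models=cfg.n_models,
        n_trees=cfg.n_trees,
        mtry=cfg.mtry,
        seed=cfg.seed,
        tune=cfg.tune,
    )
    result: DruggabilityResult = timer.run(
        "ensemble", fit_predict_ensemble, fm, sets, ens_cfg
    )

    def _evaluate():
        report: dict = {}
        if sets.clinical_holdout:
            auc, curve = roc_auc(
                result.scores.to_dict(), sets.clinical_holdout, sets.negative_pool
            )
            report["holdout_auc"] = auc
            report["roc_points"] = curve
        tests = feature_tests(fm, sets.positives, sets.negative_pool)
        report["feature_tests"] = tests
        return report

    report = timer.run("evaluate", _evaluate)

    outdir.mkdir(parents=True, exist_ok=True)
    paths = result.write(outdir)
    if "roc_points" in report:
        roc_path = outdir / "roc_points.tsv"
        report["roc_points"].to_csv(roc_path, sep="\t", index=False)
        paths["roc_points"] = roc_path
    tests_path = outdir / "feature_tests.tsv"
    report["feature_tests"].to_csv(tests_path, sep="\t")
    paths["feature_tests"] = tests_path

    eval_json = {
        "holdout_auc": report.get("holdout_auc"),
        "n_positives": len(sets.positives),
        "n_clinical_holdout": len(sets.clinical_holdout),
        "n_negative_pool": len(sets.negative_pool),
    }
    report_path = outdir / "report.json"
    with open(report_path, "w") as fh:
        json.dump(eval_json, fh, indent=2)
    paths["report"] = report_path

    input_files = [cfg.features, cfg.edges, cfg.catalog]
    input_files += list(cfg.expression) + list(cfg.gmt)
    if cfg.features_meta:
        input_files.append(cfg.features_meta)
    manifest = {
        "dtscore_version": __version__,
        "config": asdict(cfg),
        "input_sha256": {str(p): _sha256(p) for p in input_files},
        "stage_timings_s": timer.timings,
        "n_features": fm.data.shape[1],
    }
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    paths["manifest"] = manifest_path

    return {
        "holdout_auc": report.get("holdout_auc"),
        "paths": {k: str(v) for k, v in paths.items()},
        "sets": sets,
        "scores": result.scores,
        "importances": result.importances,
    }
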