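"""Positive-unlabeled bagging with balanced random forests.

For each of ``n_models`` replicates a pseudo-negative set of the same size
as the positive set is sampled without replacement from the negative pool,
a random forest is fitted on the balanced two-class data, and class-1
probabilities are predicted for every protein.  The final druggability
score is the mean probability over replicates; feature importance is the
mean decrease in Gini impurity averaged over replicates.

Replicate seeds are spawned deterministically from the master seed, so
results are bit-identical across runs and independent of execution order.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import AbstractSet, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .errors import InputError
from .features import FeatureMatrix
from .targets import StudySets

__all__ = [
    "EnsembleConfig",
    "DruggabilityResult",
    "sample_negatives",
    "fit_replicate",
    "fit_predict_ensemble",
    "tune_mtry",
]


@dataclass(frozen=True)
class EnsembleConfig:
    """Hyperparameters of the bagged ensemble.

    ``mtry`` is the number of split candidates per node; ``"auto"`` means
    floor(sqrt(n_features)).  ``step_factor``/``improve`` drive the optional
    out-of-bag mtry search (multiplicative step; a candidate is accepted
    only if the relative OOB-error improvement is at least ``improve``).
    """

    n_models: int = 10_000
    n_trees: int = 1000
    mtry: int | str = "auto"
    seed: int = 0
    step_factor: float = 1.5
    improve: float = 0.01
    tune: bool = False

    def __post_init__(self) -> None:
        if self.n_models < 1:
            raise InputError("n_models must be >= 1")
        if self.n_trees < 1:
            raise InputError("n_trees must be >= 1")
        if isinstance(self.mtry, str):
            if self.mtry != "auto":
                raise InputError(f"mtry must be an integer or 'auto', got {self.mtry!r}")
        elif self.mtry < 1:
            raise InputError("mtry must be >= 1")

    def resolve_mtry(self, n_features: int) -> int:
        if self.mtry == "auto":
            return max(1, int(math.floor(math.sqrt(n_features))))
        if self.mtry > n_features:
            raise InputError(f"mtry={self.mtry} exceeds feature count {n_features}")
        return int(self.mtry)


@dataclass
class DruggabilityResult:
    """Averaged per-protein scores and per-feature importances."""

    scores: pd.Series
    importances: pd.Series
    config: dict
    replicate_seeds: list[int]

    def write(self, outdir: str | Path, prefix: str = "") -> dict[str, Path]:
        """Write scores TSV, importances TSV and a JSON run manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "scores": outdir / f"{prefix}scores.tsv",
            "importances": outdir / f"{prefix}importances.tsv",
            "manifest": outdir / f"{prefix}ensemble_manifest.json",
        }
        self.scores.rename("score").to_csv(
            paths["scores"], sep="\t", index_label="protein_id"
        )
        self.importances.rename("mean_gini_decrease").to_csv(
            paths["importances"], sep="\t", index_label="feature"
        )
        with open(paths["manifest"], "w") as fh:
            json.dump(
                {"config": self.config, "replicate_seeds": self.replicate_seeds},
                fh,
                indent=2,
            )
        return paths


def sample_negatives(
    pool: AbstractSet[str] | Sequence[str], k: int, rng: np.random.Generator
) -> frozenset[str]:
    """Uniform sample of k proteins without replacement, deterministic in rng.

    The pool is sorted before sampling so the draw does not depend on set
    iteration order.
    """
    ordered = sorted(pool)
    if k > len(ordered):
        raise InputError(f"cannot sample {k} from a pool of {len(ordered)}")
    picked = rng.choice(len(ordered), size=k, replace=False)
    return frozenset(ordered[i] for i in picked)


def fit_replicate(
    fm: FeatureMatrix,
    positives: AbstractSet[str],
    negatives: AbstractSet[str],
    cfg: EnsembleConfig,
    random_state: int,
) -> tuple[RandomForestClassifier, np.ndarray]:
    """Fit one balanced random forest; return it with per-feature Gini decrease."""
    if positives & negatives:
        raise InputError("positive and negative sets overlap")
    if not positives or not negatives:
        raise InputError("both classes must be non-empty")
    train_ids = sorted(positives) + sorted(negatives)
    missing = [p for p in train_ids if p not in fm.data.index]
    if missing:
        raise InputError(f"training proteins absent from feature matrix: {missing[:5]}")
    X = fm.data.loc[train_ids].to_numpy(dtype=float)
    y = np.array([1] * len(positives) + [0] * len(negatives))
    clf = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        max_features=cfg.resolve_mtry(fm.data.shape[1]),
        criterion="gini",
        random_state=random_state,
        n_jobs=1,
    )
    clf.fit(X, y)
    return clf, clf.feature_importances_


def fit_predict_ensemble(
    fm: FeatureMatrix, sets: StudySets, cfg: EnsembleConfig
) -> DruggabilityResult:
    """Run the full PU bagging loop and average predictions and importances.

    Every protein in the feature matrix is scored by every replicate,
    including proteins that happened to serve as sampled negatives in some
    replicates (a deliberate, slightly optimistic-for-negatives choice) and
    the training positives themselves (resubstitution scores).
    """
    if len(sets.positives) < 2:
        raise InputError("need at least 2 positive proteins")
    k = len(sets.positives)
    if k > len(sets.negative_pool):
        raise InputError("negative pool smaller than the positive set")

    X_all = fm.data.to_numpy(dtype=float)
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.n_models)
    prob_sum = np.zeros(len(fm.data.index))
    imp_sum = np.zeros(fm.data.shape[1])
    seeds_used: list[int] = []
    for child in children:
        rng = np.random.default_rng(child)
        model_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        seeds_used.append(model_seed)
        negatives = sample_negatives(sets.negative_pool, k, rng)
        clf, importances = fit_replicate(fm, sets.positives, negatives, cfg, model_seed)
        prob_sum += clf.predict_proba(X_all)[:, list(clf.classes_).index(1)]
        imp_sum += importances

    scores = pd.Series(prob_sum / cfg.n_models, index=fm.data.index, name="score")
    importances = pd.Series(
        imp_sum / cfg.n_models, index=fm.data.columns, name="mean_gini_decrease"
    )
    snapshot = asdict(cfg)
    snapshot["resolved_mtry"] = cfg.resolve_mtry(fm.data.shape[1])
    return DruggabilityResult(
        scores=scores,
        importances=importances,
        config=snapshot,
        replicate_seeds=seeds_used,
    )


def _oob_error(
    fm: FeatureMatrix,
    positives: AbstractSet[str],
    negatives: AbstractSet[str],
    cfg: EnsembleConfig,
    mtry: int,
) -> float:
    train_ids = sorted(positives) + sorted(negatives)
    X = fm.data.loc[train_ids].to_numpy(dtype=float)
    y = np.array([1] * len(positives) + [0] * len(negatives))
    clf = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        max_features=mtry,
        oob_score=True,
        random_state=cfg.seed,
        n_jobs=1,
    )
    clf.fit(X, y)
    return 1.0 - clf.oob_score_


def tune_mtry(
    fm: FeatureMatrix,
    positives: AbstractSet[str],
    negatives: AbstractSet[str],
    cfg: EnsembleConfig,
) -> int:
    """Out-of-bag search for mtry around floor(sqrt(p)).

    Starting from the square-root default, candidates are scaled up and
    down multiplicatively by ``cfg.step_factor``; a step is taken only while
    the relative OOB-error improvement is at least ``cfg.improve``.  Falls
    back to the starting value when nothing improves.
    """
    p = fm.data.shape[1]
    start = max(1, int(math.floor(math.sqrt(p))))
    if p == 1 or cfg.step_factor <= 1:
        return start
    best_mtry = start
    best_err = _oob_error(fm, positives, negatives, cfg, start)
    for direction in ("up", "down"):
        mtry, err = start, best_err
        while True:
            nxt = (
                min(p, int(math.ceil(mtry * cfg.step_factor)))
                if direction == "up"
                else max(1, int(math.floor(mtry / cfg.step_factor)))
            )
            if nxt == mtry:
                break
            nxt_err = _oob_error(fm, positives, negatives, cfg, nxt)
            gain = (err - nxt_err) / err if err > 0 else 0.0
            if gain < cfg.improve:
                break
            mtry, err = nxt, nxt_err
            if err < best_err:
                best_mtry, best_err = mtry, err
    return best_mtry
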