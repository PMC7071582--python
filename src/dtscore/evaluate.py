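"""Evaluation: ROC/AUC, univariate feature tests, repeated LOOCV, rank correlation."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import AbstractSet, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from .features import CATEGORICAL, FeatureMatrix
from .targets import StudySets  # noqa: F401  (re-exported for callers)

__all__ = ["EvaluationReport", "roc_auc", "feature_tests", "loocv", "rank_correlation"]


@dataclass
class EvaluationReport:
    auc: float
    roc_points: pd.DataFrame  # columns fpr, tpr
    sensitivity: float | None = None
    specificity: float | None = None
    accuracy: float | None = None
    feature_results: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        out = {"auc": self.auc}
        for key in ("sensitivity", "specificity", "accuracy"):
            value = getattr(self, key)
            if value is not None:
                out[key] = value
        return out


def roc_auc(
    scores: Mapping[str, float] | pd.Series,
    positives: AbstractSet[str],
    negatives: AbstractSet[str],
) -> tuple[float, pd.DataFrame]:
    """AUC via the rank (Mann-Whitney) formulation plus a threshold-sweep curve.

    Ties count one half.  Returns (auc, DataFrame of (fpr, tpr) points from
    (0,0) to (1,1)).
    """
    if not positives or not negatives:
        raise InputError("both classes must be non-empty")
    if positives & negatives:
        raise InputError("positive and negative sets overlap")
    scores = dict(scores)
    missing = (positives | negatives) - set(scores)
    if missing:
        raise InputError(f"unscored proteins: {sorted(missing)[:5]}")

    pos = sorted(positives)
    neg = sorted(negatives)
    values = np.array([scores[p] for p in pos] + [scores[n] for n in neg], dtype=float)
    n_pos, n_neg = len(pos), len(neg)
    ranks = stats.rankdata(values)  # average ranks handle ties as 1/2
    u = ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2.0
    auc = u / (n_pos * n_neg)

    # threshold sweep, descending unique scores
    labels = np.array([1] * n_pos + [0] * n_neg)
    order = np.argsort(-values, kind="mergesort")
    sorted_labels = labels[order]
    sorted_values = values[order]
    tps = np.cumsum(sorted_labels)
    fps = np.cumsum(1 - sorted_labels)
    # keep the last point of each tied-score block
    distinct = np.r_[np.diff(sorted_values) != 0, True]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr})
    return float(auc), curve


def feature_tests(
    fm: FeatureMatrix,
    positives: AbstractSet[str],
    negatives: AbstractSet[str],
) -> pd.DataFrame:
    """Univariate class-difference tests per feature.

    Continuous features use the two-sided Wilcoxon rank-sum test (exact for
    small samples); categorical (indicator) features use the chi-squared
    test on the level x class contingency table without continuity
    correction.  Constant features are skipped with a warning; zero-count
    categorical levels are dropped with a warning.

    Returns a DataFrame indexed by feature with columns test_name,
    statistic, p_value.
    """
    pos = sorted(p for p in positives if p in fm.data.index)
    neg = sorted(n for n in negatives if n in fm.data.index)
    if not pos or not neg:
        raise InputError("both classes must be represented in the feature matrix")

    rows = []
    for col in fm.data.columns:
        x = fm.data.loc[pos, col].dropna().to_numpy(dtype=float)
        y = fm.data.loc[neg, col].dropna().to_numpy(dtype=float)
        combined = np.concatenate([x, y])
        if len(np.unique(combined)) < 2:
            warnings.warn(f"constant feature {col!r} skipped in tests", stacklevel=2)
            continue
        if fm.kinds.get(col) == CATEGORICAL:
            levels = np.unique(combined)
            table = np.array(
                [[(x == lv).sum() for lv in levels], [(y == lv).sum() for lv in levels]]
            )
            keep = table.sum(axis=0) > 0
            if not keep.all():
                warnings.warn(
                    f"zero-count levels dropped for feature {col!r}", stacklevel=2
                )
                table = table[:, keep]
            stat, p, _, _ = stats.chi2_contingency(table, correction=False)
            rows.append((col, "chi2", float(stat), float(p)))
        else:
            stat, p = stats.mannwhitneyu(x, y, alternative="two-sided")
            rows.append((col, "wilcoxon_rank_sum", float(stat), float(p)))
    return pd.DataFrame(
        rows, columns=["feature", "test_name", "statistic", "p_value"]
    ).set_index("feature")


def loocv(
    fm: FeatureMatrix,
    positives: AbstractSet[str],
    negative_pool: AbstractSet[str],
    cfg,
    n_repeats: int = 100,
) -> dict[str, float]:
    """Leave-one-out cross-validation averaged over repeated negative draws.

    Each repeat samples a balanced pseudo-negative set, then scores every
    example by a forest trained on the remaining 2k-1 examples.  Examples
    are classified at threshold 0.5.  Returns the mean sensitivity,
    specificity, accuracy and AUC over repeats.
    """
    from .ensemble import fit_replicate, sample_negatives

    pos = sorted(positives)
    if len(pos) < 3:
        raise InputError("need at least 3 positives for LOOCV")
    if n_repeats < 1:
        raise InputError("n_repeats must be >= 1")
    k = len(pos)

    sens, spec, acc, aucs = [], [], [], []
    children = np.random.SeedSequence(cfg.seed).spawn(n_repeats)
    for child in children:
        rng = np.random.default_rng(child)
        negatives = sample_negatives(negative_pool, k, rng)
        neg = sorted(negatives)
        loo_scores: dict[str, float] = {}
        for held in pos + neg:
            train_pos = frozenset(p for p in pos if p != held)
            train_neg = frozenset(n for n in neg if n != held)
            model_seed = int(rng.integers(0, 2**31 - 1))
            clf, _ = fit_replicate(fm, train_pos, train_neg, cfg, model_seed)
            x = fm.data.loc[[held]].to_numpy(dtype=float)
            loo_scores[held] = float(
                clf.predict_proba(x)[0, list(clf.classes_).index(1)]
            )
        tp = sum(loo_scores[p] > 0.5 for p in pos)
        tn = sum(loo_scores[n] <= 0.5 for n in neg)
        sens.append(tp / k)
        spec.append(tn / k)
        acc.append((tp + tn) / (2 * k))
        auc, _ = roc_auc(loo_scores, frozenset(pos), frozenset(neg))
        aucs.append(auc)
    return {
        "sensitivity": float(np.mean(sens)),
        "specificity": float(np.mean(spec)),
        "accuracy": float(np.mean(acc)),
        "auc": float(np.mean(aucs)),
        "n_repeats": n_repeats,
    }


def rank_correlation(
    scores_a: Mapping[str, float], scores_b: Mapping[str, float]
) -> tuple[float, float]:
    """Spearman rank correlation over the shared keys of two score maps."""
    shared = sorted(set(scores_a) & set(scores_b))
    if len(shared) < 3:
        raise InputError("need at least 3 shared keys")
    rho, p = stats.spearmanr(
        [scores_a[k] for k in shared], [scores_b[k] for k in shared]
    )
    return float(rho), float(p)
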