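"""Protein feature table construction, transformation and normalization.

The feature matrix unifies per-protein columns from several sources:
precomputed sequence/annotation features read from TSV, a tissue-specificity
entropy column derived from expression matrices, network centralities and
ontology rank scores computed by sibling modules.  Heavy-tailed columns are
log-transformed and every column is min-max scaled to [0, 1] before modeling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import InputError

__all__ = [
    "FeatureMatrix",
    "tissue_entropy",
    "average_entropy",
    "log_transform",
    "min_max_scale",
    "assemble_features",
    "read_expression",
    "read_feature_table",
    "write_feature_table",
]

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"


@dataclass
class FeatureMatrix:
    """Proteins x features numeric table plus per-feature annotations.

    ``data`` is indexed by protein id; categorical features are stored as
    0/1 indicator columns.  ``kinds`` maps every column to ``continuous`` or
    ``categorical``; ``heavy_tailed`` lists columns that get a log(1+x)
    transform before scaling.  ``metadata`` records provenance decisions
    (imputation counts, dropped columns, applied transforms).
    """

    data: pd.DataFrame
    kinds: dict[str, str] = field(default_factory=dict)
    heavy_tailed: frozenset[str] = frozenset()
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise InputError(f"duplicate protein ids: {dupes[:5]}")
        for col in self.data.columns:
            self.kinds.setdefault(col, CONTINUOUS)
        unknown = set(self.heavy_tailed) - set(self.data.columns)
        if unknown:
            raise InputError(f"heavy_tailed flags for unknown columns: {sorted(unknown)}")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    def copy(self) -> "FeatureMatrix":
        return replace(
            self,
            data=self.data.copy(),
            kinds=dict(self.kinds),
            metadata=dict(self.metadata),
        )


def tissue_entropy(expr: pd.DataFrame) -> pd.Series:
    """Shannon entropy of each gene's expression profile across tissues.

    For a gene g with expression ``e_i`` in tissue i and total ``S = sum(e_i)``
    the entropy is ``-(1/S) * sum_i e_i * log2(e_i / S)``, with the convention
    that zero-expression terms contribute 0.  Ranges from 0 (single-tissue
    expression) to log2(N) (uniform profile).  Genes with zero total
    expression get NaN.

    Parameters
    ----------
    expr
        Genes x tissues non-negative matrix, indexed by gene id.
    """
    if expr.shape[1] < 2:
        raise InputError("expression matrix needs at least 2 tissues")
    if expr.index.has_duplicates:
        raise InputError("duplicate gene ids in expression matrix")
    values = expr.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise InputError("expression values must be finite")
    if (values < 0).any():
        raise InputError("expression values must be non-negative")
    totals = values.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = values / totals[:, None]
        terms = np.where(p > 0, p * np.log2(p), 0.0)
    entropy = -terms.sum(axis=1)
    entropy[totals == 0] = np.nan
    # clip tiny negative rounding residue from the p*log2(p) sum; +0.0 fixes -0.0
    entropy = np.where(entropy < 0, 0.0, entropy) + 0.0
    return pd.Series(entropy, index=expr.index, name="tissue_entropy")


def average_entropy(entropies_per_source: Sequence[pd.Series]) -> pd.Series:
    """Per-gene mean entropy over sources, ignoring missing values.

    A gene present in only some sources is averaged over those; a gene
    missing (NaN) everywhere stays NaN.
    """
    if len(entropies_per_source) == 0:
        raise InputError("need at least one entropy table")
    combined = pd.concat(entropies_per_source, axis=1)
    return combined.mean(axis=1, skipna=True).rename("tissue_entropy")


def log_transform(fm: FeatureMatrix) -> FeatureMatrix:
    """Apply log(1+x) to heavy-tailed columns; other columns pass through.

    log(1+x) rather than log(x) keeps zero-valued entries (e.g. centralities
    of isolated proteins) representable.  Negative values in a flagged
    column are an input error.
    """
    out = fm.copy()
    for col in sorted(fm.heavy_tailed):
        values = out.data[col]
        if (values.dropna() < 0).any():
            raise InputError(f"negative values in heavy-tailed column {col!r}")
        out.data[col] = np.log1p(values)
    out.metadata.setdefault("transforms", []).append(
        {"log1p": sorted(fm.heavy_tailed)}
    )
    return out


def min_max_scale(fm: FeatureMatrix) -> FeatureMatrix:
    """Scale each column affinely so min -> 0 and max -> 1.

    Constant columns map to all zeros (the scaling formula is degenerate and
    they carry no information).  All-missing columns are dropped with a
    warning.  Missing entries stay missing.
    """
    out = fm.copy()
    dropped: list[str] = []
    for col in list(out.data.columns):
        values = out.data[col].astype(float)
        lo, hi = values.min(skipna=True), values.max(skipna=True)
        if pd.isna(lo):
            warnings.warn(f"dropping all-missing column {col!r}", stacklevel=2)
            out.data = out.data.drop(columns=[col])
            out.kinds.pop(col, None)
            dropped.append(col)
        elif lo == hi:
            out.data[col] = values.where(values.isna(), 0.0)
        else:
            out.data[col] = (values - lo) / (hi - lo)
    out.heavy_tailed = frozenset(out.heavy_tailed - set(dropped))
    if dropped:
        out.metadata.setdefault("dropped_all_missing", []).extend(dropped)
    out.metadata.setdefault("transforms", []).append({"min_max_scale": True})
    return out


def assemble_features(
    sources: Sequence[pd.DataFrame],
    kinds: Mapping[str, str] | None = None,
    heavy_tailed: Iterable[str] = (),
    impute_exclude: Iterable[str] = (),
) -> FeatureMatrix:
    """Outer-join per-protein feature tables into one FeatureMatrix.

    Categorical columns (declared in ``kinds`` or of object dtype) are
    expanded to 0/1 indicator columns named ``<feature>=<level>``.  Missing
    numeric entries after the join are imputed with the column median
    computed over proteins NOT in ``impute_exclude`` (pass the positive
    training set here to avoid leaking its statistics).

    Raises
    ------
    InputError
        If a feature name occurs in more than one source.
    """
    if len(sources) == 0:
        raise InputError("need at least one feature source")
    kinds = dict(kinds or {})
    seen: set[str] = set()
    for src in sources:
        overlap = seen & set(src.columns)
        if overlap:
            raise InputError(f"duplicate feature names across sources: {sorted(overlap)}")
        seen |= set(src.columns)

    joined = pd.concat(sources, axis=1, join="outer")
    joined.index.name = "protein_id"

    out_kinds: dict[str, str] = {}
    pieces: list[pd.DataFrame] = []
    for col in joined.columns:
        col_kind = kinds.get(col)
        series = joined[col]
        is_cat = col_kind == CATEGORICAL or (
            col_kind is None and series.dtype == object
        )
        needs_expansion = is_cat and (
            series.dtype == object or series.dropna().nunique() > 2
        )
        if needs_expansion:
            dummies = pd.get_dummies(series, prefix=col, prefix_sep="=", dtype=float)
            # proteins missing in this source get all-zero indicators
            dummies.loc[series.isna(), :] = 0.0
            for dcol in dummies.columns:
                out_kinds[dcol] = CATEGORICAL
            pieces.append(dummies)
        else:
            out_kinds[col] = CATEGORICAL if is_cat else CONTINUOUS
            pieces.append(series.astype(float).to_frame())
    data = pd.concat(pieces, axis=1)

    exclude = set(impute_exclude)
    background = data.loc[[p for p in data.index if p not in exclude]]
    imputed: dict[str, int] = {}
    for col in data.columns:
        n_missing = int(data[col].isna().sum())
        if n_missing == 0:
            continue
        median = background[col].median(skipna=True)
        if pd.isna(median):  # fall back to global median for tiny universes
            median = data[col].median(skipna=True)
        data[col] = data[col].fillna(median)
        imputed[col] = n_missing

    heavy = frozenset(h for h in heavy_tailed if h in data.columns)
    meta = {
        "n_sources": len(sources),
        "imputed_counts": imputed,
        "imputation": "median over proteins outside the excluded set",
    }
    return FeatureMatrix(data=data, kinds=out_kinds, heavy_tailed=heavy, metadata=meta)


# ---------------------------------------------------------------------------
# I/O


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a gene x tissue expression TSV (first column gene_id, header row)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 2:
        raise InputError(f"{path}: expression matrix needs at least 2 tissue columns")
    return df


def read_feature_table(
    path: str | Path, meta_path: str | Path | None = None
) -> tuple[pd.DataFrame, dict[str, str], frozenset[str]]:
    """Read a protein feature TSV plus its optional YAML sidecar.

    The sidecar declares ``feature_kinds`` (name -> continuous/categorical)
    and ``heavy_tailed`` (list of column names).  Without a sidecar, object
    dtype columns are treated as categorical and nothing is heavy-tailed.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    kinds: dict[str, str] = {}
    heavy: frozenset[str] = frozenset()
    if meta_path is not None:
        with open(meta_path) as fh:
            meta = yaml.safe_load(fh) or {}
        kinds = dict(meta.get("feature_kinds", {}))
        heavy = frozenset(meta.get("heavy_tailed", []))
        bad = {k for k, v in kinds.items() if v not in (CONTINUOUS, CATEGORICAL)}
        if bad:
            raise InputError(f"{meta_path}: invalid feature kind for {sorted(bad)}")
    return df, kinds, heavy


def write_feature_table(
    df: pd.DataFrame,
    path: str | Path,
    meta_path: str | Path | None = None,
    kinds: Mapping[str, str] | None = None,
    heavy_tailed: Iterable[str] = (),
) -> None:
    df.to_csv(path, sep="\t", index_label="protein_id")
    if meta_path is not None:
        meta = {
            "feature_kinds": dict(kinds or {}),
            "heavy_tailed": sorted(heavy_tailed),
        }
        with open(meta_path, "w") as fh:
            yaml.safe_dump(meta, fh, sort_keys=True)
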