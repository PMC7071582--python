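"""Drug-target catalog parsing and study-set construction.

The catalog is a TSV of (target_id, drug_id, status, indication) records.
From it we build three pairwise-disjoint protein sets:

- positives: targets with at least one approved drug whose indication
  matches the filter (the training class);
- clinical holdout: targets with a matching clinical-trial drug and no
  approved drug at all (the validation class);
- negative pool: everything else in the universe except approved-drug
  targets of ANY indication — the sampling pool for pseudo-negatives.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import AbstractSet, Callable

import pandas as pd

from .errors import InputError

__all__ = ["StudySets", "read_catalog", "build_study_sets", "indication_matcher", "STATUSES"]

STATUSES = frozenset({"approved", "clinical", "research", "withdrawn"})


@dataclass(frozen=True)
class StudySets:
    positives: frozenset[str]
    clinical_holdout: frozenset[str]
    negative_pool: frozenset[str]

    def __post_init__(self) -> None:
        if self.positives & self.clinical_holdout:
            raise InputError("positives and clinical holdout overlap")
        if (self.positives | self.clinical_holdout) & self.negative_pool:
            raise InputError("negative pool overlaps a labeled set")


def read_catalog(path: str | Path) -> pd.DataFrame:
    """Read the 4-column catalog TSV with header.

    Expected columns: target_id, drug_id, status, indication.  Status must
    come from the closed vocabulary; (target_id, drug_id) pairs are unique.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = ["target_id", "drug_id", "status", "indication"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing catalog columns {missing}")
    bad = set(df["status"]) - STATUSES
    if bad:
        raise InputError(f"{path}: unknown status values {sorted(bad)}")
    if df.duplicated(["target_id", "drug_id"]).any():
        raise InputError(f"{path}: duplicate (target_id, drug_id) pairs")
    return df[required]


def indication_matcher(pattern: str) -> Callable[[str], bool]:
    """Case-insensitive regex predicate over indication strings.

    An empty pattern matches everything.
    """
    if not pattern:
        return lambda _: True
    compiled = re.compile(pattern, re.IGNORECASE)
    return lambda text: bool(compiled.search(text or ""))


def build_study_sets(
    catalog: pd.DataFrame,
    universe: AbstractSet[str],
    indication_filter: Callable[[str], bool] | str = "",
) -> StudySets:
    """Partition the universe into positives, clinical holdout, negative pool.

    Targets with both approved and clinical matching drugs land in the
    positives only.  The negative pool excludes approved-drug targets of any
    indication as well as the clinical holdout.
    """
    if len(universe) == 0:
        raise InputError("empty protein universe")
    if isinstance(indication_filter, str):
        indication_filter = indication_matcher(indication_filter)

    matches = catalog["indication"].map(indication_filter)
    approved_any = set(catalog.loc[catalog["status"] == "approved", "target_id"])
    approved_matching = set(
        catalog.loc[(catalog["status"] == "approved") & matches, "target_id"]
    )
    clinical_matching = set(
        catalog.loc[(catalog["status"] == "clinical") & matches, "target_id"]
    )

    positives = frozenset(approved_matching & universe)
    holdout = frozenset((clinical_matching - approved_any) & universe)
    pool = frozenset(universe - approved_any - holdout)
    if not positives:
        raise InputError("no positive targets match the indication filter")
    return StudySets(positives=positives, clinical_holdout=holdout, negative_pool=pool)
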