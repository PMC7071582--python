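"""Enrichment-rank scoring of proteins against ontology gene-set categories.

Each category (e.g. biological processes, molecular functions, signaling
pathways) is a collection of gene sets.  Sets overlapping the positive
training proteins are rank-ordered by their one-sided Fisher enrichment
p-value; zero-overlap sets all receive the category's maximum rank (= its
set count).  A protein's category score is the mean of the three best ranks
among the sets it belongs to, padding with the maximum rank.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import AbstractSet, Iterable, Mapping

import pandas as pd
from scipy.stats import fisher_exact

from .errors import InputError

__all__ = [
    "OntologyCategory",
    "RankedOntology",
    "fisher_enrichment",
    "rank_ontologies",
    "score_protein",
    "score_all",
    "read_gmt",
]


@dataclass(frozen=True)
class OntologyCategory:
    """A named collection of gene sets; ``total_count`` is the set count."""

    name: str
    sets: Mapping[str, frozenset[str]]

    @property
    def total_count(self) -> int:
        return len(self.sets)


@dataclass(frozen=True)
class RankedOntology:
    """Per-set (p_value, rank) produced by :func:`rank_ontologies`."""

    category: OntologyCategory
    p_values: Mapping[str, float]
    ranks: Mapping[str, int]
    membership: Mapping[str, frozenset[str]] = field(repr=False, default_factory=dict)


def fisher_enrichment(
    set_members: AbstractSet[str],
    positives: AbstractSet[str],
    universe: AbstractSet[str],
) -> float:
    """One-sided Fisher over-representation p-value of positives in a set.

    Equals the hypergeometric upper-tail probability
    P(X >= |set & positives|) with X ~ Hypergeom(|universe|, |positives|,
    |set|).
    """
    if len(universe) == 0:
        raise InputError("empty universe")
    if not positives <= universe:
        raise InputError("positives must be a subset of the universe")
    if not set_members <= universe:
        raise InputError("set members must be a subset of the universe")
    a = len(set_members & positives)
    b = len(set_members) - a
    c = len(positives) - a
    d = len(universe) - len(set_members) - c
    _, p = fisher_exact([[a, b], [c, d]], alternative="greater")
    return float(p)


def rank_ontologies(
    cat: OntologyCategory,
    positives: AbstractSet[str],
    universe: AbstractSet[str],
) -> RankedOntology:
    """Rank every set in the category by enrichment p-value.

    Sets with at least one positive member get ranks 1..k in ascending
    p-value order (ties broken by set id for determinism); sets with no
    positive overlap all get rank = ``cat.total_count``.
    """
    p_values: dict[str, float] = {}
    overlapping: list[str] = []
    for set_id, members in cat.sets.items():
        p_values[set_id] = fisher_enrichment(
            frozenset(members) & universe, positives & universe, universe
        )
        if members & positives:
            overlapping.append(set_id)

    ranks: dict[str, int] = {sid: cat.total_count for sid in cat.sets}
    for i, sid in enumerate(sorted(overlapping, key=lambda s: (p_values[s], s)), start=1):
        ranks[sid] = i
    return RankedOntology(
        category=cat,
        p_values=p_values,
        ranks=ranks,
        membership={sid: frozenset(m) for sid, m in cat.sets.items()},
    )


def score_protein(protein: str, ranked: RankedOntology) -> float:
    """Mean of the protein's three best set ranks, padded with the max rank.

    A protein belonging to fewer than three sets pads the missing slots with
    ``total_count``; one in no set scores ``total_count``.  Lower scores
    mean stronger resemblance to the positive training set.
    """
    total = ranked.category.total_count
    member_ranks = sorted(
        ranked.ranks[sid] for sid, members in ranked.membership.items() if protein in members
    )
    top3 = (member_ranks[:3] + [total, total, total])[:3]
    return sum(top3) / 3.0


def score_all(ranked: RankedOntology, universe: Iterable[str]) -> pd.Series:
    """Vectorized :func:`score_protein` over a protein universe."""
    return pd.Series(
        {p: score_protein(p, ranked) for p in universe},
        name=f"ontology_rank_{ranked.category.name}",
    )


def read_gmt(path: str | Path, name: str | None = None) -> OntologyCategory:
    """Read a GMT file: per line, set id, description, then member ids."""
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise InputError(f"{path}:{lineno}: GMT line needs id, description, members")
            set_id = parts[0]
            if set_id in sets:
                raise InputError(f"{path}:{lineno}: duplicate set id {set_id!r}")
            sets[set_id] = frozenset(m for m in parts[2:] if m)
    return OntologyCategory(name=name or Path(path).stem, sets=sets)
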