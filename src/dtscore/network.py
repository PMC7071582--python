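"""Interaction-network construction and per-protein centrality features.

The scored edge table is thresholded to its top fraction (default 10%) by
score, turned into an unweighted simple graph, and five centralities are
computed per protein: degree, betweenness, closeness, pagerank and
eigenvector centrality.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "filter_top_fraction",
    "build_network",
    "compute_centralities",
    "read_edge_table",
    "CENTRALITY_COLUMNS",
]

CENTRALITY_COLUMNS = ("degree", "betweenness", "closeness", "pagerank", "eigen")

_EDGE_COLUMNS = ["protein_a", "protein_b", "score"]


def read_edge_table(path: str | Path) -> pd.DataFrame:
    """Read a 3-column TSV edge table (protein1, protein2, combined_score).

    A header row is auto-detected: if the third field of the first line is
    not numeric it is treated as a header.
    """
    with open(path) as fh:
        first = fh.readline().rstrip("\n").split("\t")
    has_header = False
    if len(first) >= 3:
        try:
            float(first[2])
        except ValueError:
            has_header = True
    df = pd.read_csv(
        path,
        sep="\t",
        header=0 if has_header else None,
        usecols=[0, 1, 2],
        names=None if has_header else _EDGE_COLUMNS,
        dtype={0: str, 1: str},
    )
    df.columns = _EDGE_COLUMNS
    df["protein_a"] = df["protein_a"].astype(str)
    df["protein_b"] = df["protein_b"].astype(str)
    df["score"] = pd.to_numeric(df["score"])
    return df


def filter_top_fraction(edges: pd.DataFrame, fraction: float) -> pd.DataFrame:
    """Keep the ceil(fraction * n) highest-scored edges after deduplication.

    Reciprocal rows (a-b / b-a) collapse to one record keeping the maximum
    score.  Ties at the cutoff score are all retained, so the result is
    independent of input ordering and may slightly exceed ceil(fraction*n).
    """
    if len(edges) == 0:
        raise InputError("empty edge table")
    if not (0 < fraction <= 1):
        raise InputError(f"fraction must be in (0, 1], got {fraction}")
    if not np.isfinite(edges["score"]).all():
        raise InputError("edge scores must be finite")

    a = edges["protein_a"].astype(str)
    b = edges["protein_b"].astype(str)
    lo = a.where(a <= b, b)
    hi = b.where(a <= b, a)
    dedup = (
        pd.DataFrame({"protein_a": lo, "protein_b": hi, "score": edges["score"]})
        .groupby(["protein_a", "protein_b"], as_index=False)["score"]
        .max()
    )
    n = len(dedup)
    k = math.ceil(fraction * n)
    cutoff = dedup["score"].sort_values(ascending=False).iloc[k - 1]
    kept = dedup[dedup["score"] >= cutoff]
    return kept.sort_values(
        ["score", "protein_a", "protein_b"], ascending=[False, True, True]
    ).reset_index(drop=True)


def build_network(edges: pd.DataFrame) -> nx.Graph:
    """Build an undirected simple graph; self-loops dropped, nodes retained."""
    g = nx.Graph()
    for a, b in zip(edges["protein_a"], edges["protein_b"]):
        g.add_node(a)
        g.add_node(b)
        if a != b:
            g.add_edge(a, b)
    return g


def compute_centralities(
    g: nx.Graph, universe: Sequence[str] | None = None
) -> pd.DataFrame:
    """Five unweighted centralities per protein.

    - ``degree``: raw edge count.
    - ``betweenness``: unnormalized shortest-path betweenness (downstream
      min-max scaling makes the normalization convention immaterial).
    - ``closeness``: per connected component, (n_comp - 1) / sum of
      within-component distances; isolated nodes get 0.
    - ``pagerank``: damping 0.85, tolerance 1e-9.
    - ``eigen``: eigenvector centrality of the largest connected component
      normalized to max 1; 0 outside it.

    Proteins listed in ``universe`` but absent from the graph receive 0 in
    every column.
    """
    nodes = list(g.nodes)
    if nodes:
        degree = dict(g.degree())
        betweenness = nx.betweenness_centrality(g, normalized=False)
        closeness = nx.closeness_centrality(g, wf_improved=False)
        pagerank = nx.pagerank(g, alpha=0.85, tol=1e-9, max_iter=1000)
        eigen = {n: 0.0 for n in nodes}
        components = sorted(nx.connected_components(g), key=len, reverse=True)
        if components and len(components[0]) > 1:
            sub_nodes = sorted(components[0])
            adjacency = nx.to_numpy_array(g, nodelist=sub_nodes)
            eigvals, eigvecs = np.linalg.eigh(adjacency)
            leading = np.abs(eigvecs[:, int(np.argmax(eigvals))])
            leading /= leading.max()
            for n, v in zip(sub_nodes, leading):
                eigen[n] = float(v)
        elif components:  # largest component is a single node
            eigen[next(iter(components[0]))] = 1.0
    else:
        degree = betweenness = closeness = pagerank = eigen = {}

    index = list(universe) if universe is not None else nodes
    table = pd.DataFrame(
        {
            "degree": [float(degree.get(p, 0)) for p in index],
            "betweenness": [betweenness.get(p, 0.0) for p in index],
            "closeness": [closeness.get(p, 0.0) for p in index],
            "pagerank": [pagerank.get(p, 0.0) for p in index],
            "eigen": [eigen.get(p, 0.0) for p in index],
        },
        index=pd.Index(index, name="protein_id"),
    )
    return table
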