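"""Protein-protein interaction network assembly and network propagation.

The interactome carries STRING-style integer confidence scores (0-1000).
Edges are filtered at a confidence threshold, node distances use hop
counts (the confidence is a filter, not a metric length), and compound
relevance to the disease is scored by random walk with restart (RWR)
from the disease seed genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "assemble_interactome",
    "shortest_path_lengths",
    "strongly_connected_nodes",
    "random_walk_restart",
    "compound_relevance",
    "label_compounds",
    "RWRState",
    "CompoundLabel",
]

EFFECTIVE = "effective_candidate"
OTHER = "other"


@dataclass
class RWRState:
    """Fixed point of the restart walk r = (1-c) W r + c e."""

    restart_c: float
    nodes: list
    seed_vector: np.ndarray
    scores: np.ndarray
    residual: float
    iterations: int

    def score_of(self, node) -> float:
        try:
            return float(self.scores[self.nodes.index(node)])
        except ValueError:
            return 0.0

    def as_series(self) -> pd.Series:
        return pd.Series(self.scores, index=self.nodes, name="rwr_score")


@dataclass
class CompoundLabel:
    compound_id: str
    relevance: float
    label: str = OTHER


def assemble_interactome(
    edge_table: pd.DataFrame,
    node_sets: Sequence[Iterable] | None = None,
    min_confidence: int = 700,
) -> nx.Graph:
    """Build the confidence-filtered PPI network.

    ``edge_table`` needs columns protein_a, protein_b, combined_score
    (int 0-1000).  Edges below ``min_confidence`` are dropped; if
    ``node_sets`` is given the graph is restricted to their union (with
    induced edges) and genes that end up edgeless are kept as isolates.
    """
    scores = edge_table["combined_score"].to_numpy()
    if ((scores < 0) | (scores > 1000)).any():
        raise ValueError("combined_score outside [0, 1000]")
    kept = edge_table[edge_table["combined_score"] >= min_confidence]
    g = nx.Graph()
    if node_sets is not None:
        universe = set().union(*map(set, node_sets)) if node_sets else set()
        g.add_nodes_from(sorted(universe))
        kept = kept[
            kept["protein_a"].isin(universe) & kept["protein_b"].isin(universe)
        ]
    for u, v, s in kept[["protein_a", "protein_b", "combined_score"]].itertuples(
        index=False
    ):
        if u != v:
            g.add_edge(u, v, confidence=int(s))
    return g


def isolated_nodes(net: nx.Graph) -> list:
    return sorted(n for n in net if net.degree(n) == 0)


def shortest_path_lengths(net: nx.Graph, sources: Iterable) -> dict:
    """Hop distance from the nearest source gene; unreachable -> inf."""
    sources = [s for s in sources if s in net]
    if not sources:
        raise ValueError("no source gene is present in the network")
    dist = nx.multi_source_dijkstra_path_length(net, sources, weight=None)
    return {n: float(dist.get(n, np.inf)) for n in net.nodes}


def strongly_connected_nodes(distances: Mapping, threshold: int = 3) -> set:
    """Genes with shortest distance strictly below ``threshold`` (the
    "shortest distance of less than three" rule: hops 0, 1, 2)."""
    return {n for n, d in distances.items() if d < threshold}


def random_walk_restart(
    net: nx.Graph,
    seeds: Iterable,
    restart_c: float = 0.75,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> RWRState:
    """Random walk with restart from disease seed genes.

    Iterates r <- (1-c) W r + c e with W the column-normalized adjacency
    and e uniform over the seeds present in the network, until the L1
    change falls below ``tol``.  Dangling (isolated) columns keep their
    mass through the restart term only.
    """
    if not 0 < restart_c <= 1:
        raise ValueError("restart_c must be in (0, 1]")
    nodes = sorted(net.nodes, key=str)
    index = {n: i for i, n in enumerate(nodes)}
    seeds_in = sorted({s for s in seeds if s in index}, key=str)
    if not seeds_in:
        raise ValueError("no seed gene is present in the network")
    n = len(nodes)
    a = nx.to_scipy_sparse_array(net, nodelist=nodes, weight=None, format="csc")
    a = a.astype(float)
    col = np.asarray(a.sum(axis=0)).ravel()
    inv = np.divide(1.0, col, out=np.zeros_like(col), where=col > 0)
    w = a @ sp.diags(inv)
    e = np.zeros(n)
    e[[index[s] for s in seeds_in]] = 1.0 / len(seeds_in)
    r = e.copy()
    c = restart_c
    residual = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        r_new = (1 - c) * (w @ r) + c * e
        # mass lost at dangling columns is returned via the seeds
        lost = 1.0 - r_new.sum()
        if lost > 1e-15:
            r_new += lost * e
        residual = float(np.abs(r_new - r).sum())
        r = r_new
        if residual < tol:
            break
    return RWRState(c, nodes, e, r, residual, it)


def compound_relevance(
    rwr: RWRState,
    compound_targets: Mapping[str, Iterable],
    aggregate: str = "mean",
) -> list[CompoundLabel]:
    """Aggregate RWR scores over each compound's target genes.

    The default is the mean over ALL of the compound's targets: a target
    absent from the network contributes 0 to the numerator but still
    counts in the denominator, so promiscuous off-network binding does
    not inflate relevance.  ``aggregate='max'`` takes the best target.
    """
    scores = dict(zip(rwr.nodes, rwr.scores))
    out = []
    for cid in sorted(compound_targets, key=str):
        targets = list(compound_targets[cid])
        if not targets:
            raise ValueError(f"compound {cid} has no targets")
        vals = [scores.get(t, 0.0) for t in targets]
        rel = max(vals) if aggregate == "max" else float(np.mean(vals))
        out.append(CompoundLabel(cid, rel))
    return out


def label_compounds(
    relevances: Sequence[CompoundLabel],
    quantile_q: float = 0.25,
    polarity: str = "above",
) -> tuple[list[CompoundLabel], float]:
    """Split compounds at the lower quartile of RWR relevance.

    The threshold is the empirical ``quantile_q`` quantile (linear
    interpolation between order statistics); with the default polarity a
    compound is an ``effective_candidate`` iff relevance >= threshold.
    Returns the labelled list and the threshold used.
    """
    if len(relevances) < 4:
        raise ValueError("need at least 4 compounds to take a quartile")
    vals = np.array([r.relevance for r in relevances])
    threshold = float(np.quantile(vals, quantile_q))
    if np.allclose(vals, vals[0]):
        warnings.warn("all relevances identical; labelling all as effective")
        return (
            [CompoundLabel(r.compound_id, r.relevance, EFFECTIVE) for r in relevances],
            threshold,
        )
    if polarity == "above":
        pos = vals >= threshold
    else:
        pos = vals <= threshold
    labelled = [
        CompoundLabel(r.compound_id, r.relevance, EFFECTIVE if p else OTHER)
        for r, p in zip(relevances, pos)
    ]
    return labelled, threshold
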