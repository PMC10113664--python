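"""Over-representation analysis and MCODE complex detection.

ORA tests a query gene set against GMT gene sets with the upper-tail
hypergeometric distribution and Benjamini-Hochberg FDR (significance at
Q < 0.05); MCODE extracts densely connected complexes from the
interactome by vertex weighting and seeded greedy growth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = ["hypergeom_ora", "bh_adjust", "MCODEParams", "mcode"]


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (monotone, <= 1)."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def hypergeom_ora(
    query: Iterable,
    gene_sets: Mapping[str, Iterable],
    universe: Iterable,
    q_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query gene set.

    For each set: p = P(X >= k) with X ~ Hypergeom(N=|universe|,
    K=|set n universe|, n=|query|); q by BH over all tested sets,
    significant at q < ``q_cutoff``.  Query genes outside the universe
    are dropped with a log entry.
    """
    universe = set(universe)
    query = set(query)
    outside = query - universe
    if outside:
        log.info("dropping %d query genes outside the universe", len(outside))
        query &= universe
    if not query:
        raise ValueError("empty query after restricting to the universe")
    n_univ, n_query = len(universe), len(query)
    rows = []
    for name in sorted(gene_sets, key=str):
        members = set(gene_sets[name]) & universe
        k = len(query & members)
        p = float(stats.hypergeom.sf(k - 1, n_univ, len(members), n_query))
        rows.append(
            {
                "set_name": name,
                "universe_n": n_univ,
                "set_k": len(members),
                "query_n": n_query,
                "overlap_k": k,
                "p": p,
            }
        )
    df = pd.DataFrame(rows)
    df["q"] = bh_adjust(df["p"].to_numpy())
    df["significant"] = df["q"] < q_cutoff
    return df.sort_values(["p", "set_name"], kind="stable").reset_index(drop=True)


@dataclass
class MCODEParams:
    degree_cutoff: int = 2
    node_score_cutoff: float = 0.2
    k_core: int = 2
    max_depth: int = 100
    haircut: bool = True
    fluff: bool = False


def _highest_kcore(g: nx.Graph) -> tuple[int, nx.Graph]:
    """Highest k such that the k-core of g is non-empty, and that core."""
    if g.number_of_nodes() == 0:
        return 0, g
    core_num = nx.core_number(g)
    k = max(core_num.values())
    core = g.subgraph([n for n, c in core_num.items() if c == k])
    return k, core


def _vertex_weights(net: nx.Graph, degree_cutoff: int) -> dict:
    """MCODE stage 1: weight = highest-k-core number of the node's closed
    neighbourhood times the density of that highest k-core."""
    w = {}
    for n in net:
        nbrs = list(net.neighbors(n))
        if len(nbrs) < degree_cutoff:
            w[n] = 0.0
            continue
        sub = net.subgraph(nbrs + [n])
        k, core = _highest_kcore(sub)
        nn = core.number_of_nodes()
        density = (
            2 * core.number_of_edges() / (nn * (nn - 1)) if nn > 1 else 0.0
        )
        w[n] = k * density
    return w


def mcode(net: nx.Graph, params: MCODEParams | None = None) -> list[dict]:
    """Molecular complex detection.

    Seeds complexes at the highest-weight unvisited vertex and grows
    outward admitting neighbours with weight >= (1 - node_score_cutoff)
    times the seed weight, up to ``max_depth`` hops; ``haircut`` trims
    singly-connected periphery.  Complexes are ranked by score =
    density x size.
    """
    params = params or MCODEParams()
    if net.number_of_edges() == 0:
        return []
    w = _vertex_weights(net, params.degree_cutoff)
    seen: set = set()
    complexes = []
    for seed in sorted(net.nodes, key=lambda n: (-w[n], str(n))):
        if seed in seen or w[seed] <= 0:
            continue
        threshold = w[seed] * (1 - params.node_score_cutoff)
        members = {seed}
        frontier = [(seed, 0)]
        while frontier:
            node, depth = frontier.pop()
            if depth >= params.max_depth:
                continue
            for nb in net.neighbors(node):
                if nb in members or nb in seen:
                    continue
                if w[nb] >= threshold:
                    members.add(nb)
                    frontier.append((nb, depth + 1))
        sub = net.subgraph(members).copy()
        if params.haircut:
            while True:
                trim = [n for n in sub if sub.degree(n) < 2 and n != seed]
                if not trim or sub.number_of_nodes() <= 2:
                    break
                sub.remove_nodes_from(trim)
        if sub.number_of_nodes() < 2:
            seen.add(seed)
            continue
        nn, ne = sub.number_of_nodes(), sub.number_of_edges()
        density = 2 * ne / (nn * (nn - 1))
        complexes.append(
            {
                "nodes": sorted(sub.nodes, key=str),
                "seed": seed,
                "score": density * nn,
                "density": density,
            }
        )
        seen.update(sub.nodes)
    complexes.sort(key=lambda c: (-c["score"], str(c["seed"])))
    return complexes
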