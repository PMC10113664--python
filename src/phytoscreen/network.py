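"""Weighted co-occurrence networks from prescription/symptom records.

Builds the drug co-prescription network and the symptom co-occurrence
network, extracts core drugs by weighted-core (s-core) peeling and 2x2
relative risk, and detects symptom communities by the fast unfolding
(Louvain) algorithm.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats

__all__ = [
    "PrescriptionRecord",
    "SymptomRecord",
    "CoreExtractionResult",
    "RRResult",
    "CommunityPartition",
    "build_cooccurrence_network",
    "extract_core_drugs",
    "drug_relative_risk",
    "louvain_communities",
    "modularity",
]


@dataclass(frozen=True)
class PrescriptionRecord:
    """One patient's prescription: the set of botanical drugs and the
    case flag (target disease vs. other hypertension)."""

    patient_id: str
    drugs: frozenset
    is_target_disease: bool = True

    def __post_init__(self):
        if not self.drugs:
            raise ValueError(f"record {self.patient_id}: empty drug set")
        object.__setattr__(self, "drugs", frozenset(self.drugs))

    @property
    def items(self) -> frozenset:
        return self.drugs


@dataclass(frozen=True)
class SymptomRecord:
    """One patient's standardized symptom terms."""

    patient_id: str
    symptoms: frozenset

    def __post_init__(self):
        if not self.symptoms:
            raise ValueError(f"record {self.patient_id}: empty symptom set")
        object.__setattr__(self, "symptoms", frozenset(self.symptoms))

    @property
    def items(self) -> frozenset:
        return self.symptoms


@dataclass
class CoreExtractionResult:
    """Shell decomposition of a weighted network.

    ``core_nodes`` are the members of the maximal (innermost) shell ranked
    by strength descending, label ascending on ties; ``ranking`` orders
    every node by (shell desc, strength desc, label asc).
    """

    shell_index: dict
    strength: dict
    core_nodes: list
    ranking: list

    def top(self, n: int) -> list:
        return self.ranking[:n]

    def top_fraction(self, fraction: float) -> list:
        if not 0 < fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")
        return self.ranking[: int(np.ceil(fraction * len(self.ranking)))]


@dataclass
class RRResult:
    """2x2 relative risk of drug use in case vs. non-case prescriptions."""

    a: int  # cases containing the drug
    b: int  # cases without
    c: int  # non-cases containing
    d: int  # non-cases without
    rr: float
    ci_low: float | None
    ci_high: float | None
    p: float
    degenerate: bool = False


@dataclass
class CommunityPartition:
    assignment: dict
    q: float
    passes: list = field(default_factory=list)  # modularity trace per level

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))

    def members(self, cid) -> set:
        return {n for n, c in self.assignment.items() if c == cid}


def build_cooccurrence_network(records: Sequence, min_weight: int = 1) -> nx.Graph:
    """Co-occurrence network: nodes are items (drugs or symptoms), edge
    weight = number of records containing both endpoints.

    Edges with weight < ``min_weight`` are dropped; their endpoints are
    kept as isolates.
    """
    records = list(records)
    if not records:
        raise ValueError("no records supplied")
    counts: Counter = Counter()
    nodes: set = set()
    for rec in records:
        items = sorted(rec.items)
        nodes.update(items)
        counts.update(itertools.combinations(items, 2))
    g = nx.Graph()
    g.add_nodes_from(sorted(nodes))
    g.add_weighted_edges_from(
        (u, v, w) for (u, v), w in counts.items() if w >= min_weight
    )
    return g


def _strengths(g: nx.Graph) -> dict:
    return {n: float(d) for n, d in g.degree(weight="weight")}


def extract_core_drugs(net: nx.Graph) -> CoreExtractionResult:
    """Hierarchical core extraction by weighted k-core (s-core) peeling.

    Repeatedly removes every node whose strength (sum of incident edge
    weights) is <= the current threshold, raising the threshold to the
    minimum surviving strength each round; the shell index of a node is
    the round at which it was removed.  Core nodes are the maximal shell.
    """
    if net.number_of_edges() == 0:
        raise ValueError("core extraction needs at least one edge")
    g = net.copy()
    full_strength = _strengths(net)
    shell_index: dict = {}
    shell = 0
    # isolates fall out at shell 0
    for n in [n for n in g if g.degree(n) == 0]:
        shell_index[n] = 0
        g.remove_node(n)
    while g.number_of_nodes() > 0:
        shell += 1
        threshold = min(_strengths(g).values())
        while True:
            doomed = [n for n, s in _strengths(g).items() if s <= threshold]
            if not doomed:
                break
            for n in doomed:
                shell_index[n] = shell
            g.remove_nodes_from(doomed)
            if g.number_of_nodes() == 0:
                break
    max_shell = max(shell_index.values())
    key = lambda n: (-shell_index[n], -full_strength.get(n, 0.0), str(n))
    ranking = sorted(net.nodes, key=key)
    core_nodes = sorted(
        (n for n, s in shell_index.items() if s == max_shell),
        key=lambda n: (-full_strength.get(n, 0.0), str(n)),
    )
    return CoreExtractionResult(shell_index, full_strength, core_nodes, ranking)


def drug_relative_risk(records: Sequence[PrescriptionRecord], drug) -> RRResult:
    """Relative risk of a drug appearing in case prescriptions.

    Cases (target disease) are the exposed group, other prescriptions the
    unexposed group; containing the drug is the event.  95% CI by the
    log-RR normal approximation, p by Yates-corrected chi-square.
    """
    cases = [r for r in records if r.is_target_disease]
    others = [r for r in records if not r.is_target_disease]
    if not cases or not others:
        raise ValueError("both case and non-case records are required")
    a = sum(drug in r.drugs for r in cases)
    b = len(cases) - a
    c = sum(drug in r.drugs for r in others)
    d = len(others) - c
    if a == 0 or c == 0:
        rr = float("inf") if c == 0 and a > 0 else 0.0
        _, _, p = chisq_2x2(a, b, c, d) if min(a + b, c + d) > 0 else (0, 1, 1.0)
        return RRResult(a, b, c, d, rr, None, None, p, degenerate=True)
    rr = (a / (a + b)) / (c / (c + d))
    se = np.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    ci_low = float(np.exp(np.log(rr) - 1.96 * se))
    ci_high = float(np.exp(np.log(rr) + 1.96 * se))
    _, _, p = chisq_2x2(a, b, c, d)
    return RRResult(a, b, c, d, float(rr), ci_low, ci_high, p)


def chisq_2x2(a: int, b: int, c: int, d: int) -> tuple:
    """Yates-corrected chi-square for a 2x2 table; returns (chi2, df, p)."""
    from .cohort import chisq_test  # single implementation of the test

    return chisq_test(np.array([[a, b], [c, d]]), yates=True)


def modularity(net: nx.Graph, assignment: Mapping) -> float:
    """Weighted Newman-Girvan modularity of a partition.

    Q = sum_c (e_c / m  -  (a_c / 2m)^2) with e_c the within-community
    weight, a_c the community's total strength and m the total weight.
    """
    missing = set(net.nodes) - set(assignment)
    if missing:
        raise ValueError(f"assignment missing nodes: {sorted(missing)[:5]}")
    m = net.size(weight="weight")
    if m == 0:
        return 0.0
    e: Counter = Counter()
    deg: Counter = Counter()
    for u, v, w in net.edges(data="weight", default=1.0):
        if assignment[u] == assignment[v]:
            e[assignment[u]] += w
        deg[assignment[u]] += w
        deg[assignment[v]] += w
    return float(sum(e[c] / m - (deg[c] / (2 * m)) ** 2 for c in deg))


def louvain_communities(
    net: nx.Graph, resolution: float = 1.0, seed: int = 0
) -> CommunityPartition:
    """Fast unfolding (Louvain) community detection.

    Two-phase greedy modularity optimization; the node visit order is
    shuffled by ``seed`` so runs are reproducible.  The returned ``q`` is
    the modularity of the final assignment at resolution 1 regardless of
    the resolution used for optimization; ``passes`` traces q per level.
    """
    if net.number_of_edges() == 0:
        assignment = {n: i for i, n in enumerate(sorted(net.nodes, key=str))}
        return CommunityPartition(assignment, 0.0, [])
    levels = list(
        nx.community.louvain_partitions(
            net, weight="weight", resolution=resolution, seed=seed
        )
    )
    passes = []
    for parts in levels:
        assignment = {n: cid for cid, comm in enumerate(parts) for n in comm}
        passes.append(modularity(net, assignment))
    final = levels[-1]
    # stable community ids: ordered by smallest member label
    ordered = sorted(final, key=lambda c: min(map(str, c)))
    assignment = {n: cid for cid, comm in enumerate(ordered) for n in comm}
    return CommunityPartition(assignment, modularity(net, assignment), passes)
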