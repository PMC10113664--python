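"""Per-compound biological features feeding the effectiveness classifier.

Four features per compound: oral bioavailability (OB, percent), mean
Jaccard overlap with the disease and symptom-community gene sets (Jac),
Wang-method GO biological-process semantic similarity to the disease
genes (GoSim, best-match average), and Manhattan compactness of the
compound's regulation profile across symptom communities (Man).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "OntologyDAG",
    "jaccard",
    "mean_jaccard_feature",
    "wang_term_similarity",
    "geneset_gosim",
    "GoSimScorer",
    "frequency_matrix",
    "manhattan_compactness",
    "build_feature_table",
]

DEFAULT_RELATION_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}


class OntologyDAG:
    """A gene-ontology-style DAG with weighted child->parent relations.

    Edges carry a semantic-contribution weight (is_a 0.8, part_of 0.6 by
    default).  The DAG must be acyclic with every term reaching a root.
    """

    def __init__(self, edges: Iterable[tuple], relation_weights: Mapping | None = None):
        self.w = dict(DEFAULT_RELATION_WEIGHTS)
        if relation_weights:
            self.w.update(relation_weights)
        self.parents: dict = {}
        terms = set()
        for child, parent, relation in edges:
            if relation not in self.w:
                raise ValueError(f"unknown relation {relation!r}")
            self.parents.setdefault(child, []).append((parent, self.w[relation]))
            terms.update((child, parent))
        self.terms = terms
        self._check_acyclic()
        self._svalues_cached = lru_cache(maxsize=None)(self._svalues)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, relation_weights=None) -> "OntologyDAG":
        return cls(
            df[["child", "parent", "relation"]].itertuples(index=False),
            relation_weights,
        )

    def _check_acyclic(self):
        state: dict = {}

        def visit(t, stack):
            if t in stack:
                raise ValueError(f"ontology contains a cycle through {t!r}")
            if state.get(t):
                return
            stack.add(t)
            for p, _ in self.parents.get(t, ()):
                visit(p, stack)
            stack.discard(t)
            state[t] = True

        for t in self.terms:
            visit(t, set())

    def _svalues(self, term) -> dict:
        """Wang S-values: the semantic contribution of each ancestor,
        max over paths of the product of edge weights."""
        if term not in self.terms:
            raise KeyError(f"unknown term {term!r}")
        s = {term: 1.0}
        frontier = [term]
        while frontier:
            t = frontier.pop()
            for parent, w in self.parents.get(t, ()):
                cand = s[t] * w
                if cand > s.get(parent, 0.0):
                    s[parent] = cand
                    frontier.append(parent)
        return s

    def svalues(self, term) -> dict:
        return self._svalues_cached(term)


def wang_term_similarity(t1, t2, dag: OntologyDAG) -> float:
    """Wang semantic similarity between two ontology terms.

    Sim = sum over common ancestors of (S_t1 + S_t2) divided by
    (SV(t1) + SV(t2)); equals 1 iff the terms coincide, 0 when they
    share no ancestor (disjoint DAG components).
    """
    s1, s2 = dag.svalues(t1), dag.svalues(t2)
    common = set(s1) & set(s2)
    if not common:
        return 0.0
    num = sum(s1[t] + s2[t] for t in common)
    return float(num / (sum(s1.values()) + sum(s2.values())))


def _bma(matrix: np.ndarray) -> float:
    """Best-match average of a similarity matrix: mean of row maxima
    averaged with mean of column maxima."""
    if matrix.size == 0:
        return 0.0
    return float((matrix.max(axis=1).mean() + matrix.max(axis=0).mean()) / 2)


def jaccard(a: Iterable, b: Iterable) -> float:
    """|a n b| / |a u b|; two empty sets give 0 by convention."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def mean_jaccard_feature(
    compound_targets: Iterable, reference_sets: Sequence[Iterable]
) -> float:
    """Mean Jaccard overlap of the target set with each reference gene
    set (disease genes plus each symptom-community set)."""
    refs = list(reference_sets)
    if not refs:
        raise ValueError("reference_sets must be non-empty")
    t = set(compound_targets)
    return float(np.mean([jaccard(t, r) for r in refs]))


class GoSimScorer:
    """Cached Wang/BMA gene-set similarity against fixed annotations.

    Genes sharing the same annotation term set ("signature") have equal
    similarity to everything, so the scorer deduplicates genes by
    signature, precomputes the signature-signature BMA matrix in one
    vectorized pass, and reduces every later gene-set query to numpy
    indexing.  Scoring hundreds of compounds against several reference
    gene sets is then cheap.
    """

    def __init__(self, annotations: Mapping[str, Iterable], dag: OntologyDAG):
        self.dag = dag
        self.annotations = {}
        for g, ts in annotations.items():
            kept = sorted(set(t for t in ts if t in dag.terms))
            if kept:
                self.annotations[g] = kept
        sigs = sorted({tuple(ts) for ts in self.annotations.values()})
        self._sig_id = {s: i for i, s in enumerate(sigs)}
        self._gene_sig = {g: self._sig_id[tuple(ts)]
                          for g, ts in self.annotations.items()}
        self._terms = sorted({t for s in sigs for t in s})
        tid = {t: i for i, t in enumerate(self._terms)}
        nt = len(self._terms)
        tmat = np.ones((max(nt, 1), max(nt, 1)))
        for i, a in enumerate(self._terms):
            for j, b in enumerate(self._terms[i + 1:], start=i + 1):
                tmat[i, j] = tmat[j, i] = wang_term_similarity(a, b, dag)
        # pad signatures to equal length; padded slots masked out of the BMA
        ns = len(sigs)
        width = max((len(s) for s in sigs), default=1)
        pad = np.zeros((ns, width), dtype=int)
        valid = np.zeros((ns, width), dtype=bool)
        for i, s in enumerate(sigs):
            pad[i, : len(s)] = [tid[t] for t in s]
            valid[i, : len(s)] = True
        m = tmat[pad[:, None, :, None], pad[None, :, None, :]]
        mask = valid[:, None, :, None] & valid[None, :, None, :]
        m = np.where(mask, m, -np.inf)
        row = np.where(valid[:, None, :], m.max(axis=3), np.nan)  # (ns, ns, w)
        col = np.where(valid[None, :, :], m.max(axis=2), np.nan)
        with np.errstate(invalid="ignore"):
            self._sig_sim = (np.nanmean(row, axis=2) + np.nanmean(col, axis=2)) / 2

    def term_sim(self, t1, t2) -> float:
        return wang_term_similarity(t1, t2, self.dag)

    def _ids(self, genes: Iterable) -> np.ndarray:
        return np.array(
            sorted(self._gene_sig[g] for g in set(genes) if g in self._gene_sig),
            dtype=int,
        )

    def gene_sim(self, g1, g2) -> float:
        return float(self._sig_sim[self._gene_sig[g1], self._gene_sig[g2]])

    def geneset_sim(self, genes_a: Iterable, genes_b: Iterable) -> float:
        ia, ib = self._ids(genes_a), self._ids(genes_b)
        if len(ia) == 0 or len(ib) == 0:
            return np.nan
        return _bma(self._sig_sim[np.ix_(ia, ib)])


def geneset_gosim(
    genes_a: Iterable,
    genes_b: Iterable,
    annotations: Mapping[str, Iterable],
    dag: OntologyDAG,
) -> float:
    """Best-match-average Wang similarity between two gene sets.

    Gene-gene similarity is BMA over the genes' annotation term sets;
    the set-level score is BMA over the gene-gene matrix.  Returns NaN
    (caller imputes 0) when either side has no annotated gene.
    """
    return GoSimScorer(annotations, dag).geneset_sim(genes_a, genes_b)


def frequency_matrix(
    compound_targets: Mapping[str, Iterable],
    community_genes: Mapping[str, Iterable],
) -> pd.DataFrame:
    """Compounds x symptom-communities matrix of regulated-gene counts:
    cell (c, m) = |targets(c) n genes(m)|."""
    if not community_genes:
        raise ValueError("no symptom communities supplied")
    comms = sorted(community_genes, key=str)
    rows = {}
    for cid in sorted(compound_targets, key=str):
        t = set(compound_targets[cid])
        rows[cid] = [len(t & set(community_genes[m])) for m in comms]
    return pd.DataFrame.from_dict(rows, orient="index", columns=comms).astype(int)


def manhattan_compactness(fm: pd.DataFrame) -> pd.Series:
    """Manhattan distance of each compound's community-regulation profile
    from the cohort-mean profile.

    Rows are normalized to proportions (all-zero rows stay zero); the
    reference is the column-wise mean profile.  Lower = more typical.
    """
    if len(fm) < 2:
        warnings.warn("manhattan compactness needs >=2 compounds; returning zeros")
        return pd.Series(0.0, index=fm.index, name="man")
    x = fm.to_numpy(dtype=float)
    sums = x.sum(axis=1, keepdims=True)
    p = np.divide(x, sums, out=np.zeros_like(x), where=sums > 0)
    centroid = p.mean(axis=0)
    man = np.abs(p - centroid).sum(axis=1)
    return pd.Series(man, index=fm.index, name="man")


def build_feature_table(
    ob_table: pd.DataFrame,
    compound_targets: Mapping[str, Iterable],
    reference_sets: Sequence[Iterable],
    annotations: Mapping[str, Iterable],
    dag: OntologyDAG,
    community_genes: Mapping[str, Iterable],
    labels: Mapping[str, str],
    scorer: GoSimScorer | None = None,
) -> pd.DataFrame:
    """Assemble the per-compound feature table (ob, jac, gosim, man, label).

    ``ob_table`` needs columns compound_id, ob_percent.  A compound
    missing from the OB table gets the median OB of the others
    (``ob_imputed`` flag set); a compound with no annotated target gets
    gosim 0 (``gosim_imputed`` flag).  Compounds without a label are
    dropped with a log entry.
    """
    ob = ob_table.set_index("compound_id")["ob_percent"].astype(float)
    scorer = scorer or GoSimScorer(annotations, dag)
    disease_like = reference_sets[0] if reference_sets else set()
    rows = []
    fm = frequency_matrix(compound_targets, community_genes)
    man = manhattan_compactness(fm)
    for cid in sorted(compound_targets, key=str):
        if cid not in labels:
            log.info("compound %s has no label; excluded", cid)
            continue
        targets = set(compound_targets[cid])
        gosim = scorer.geneset_sim(targets, disease_like)
        rows.append(
            {
                "compound_id": cid,
                "ob": ob.get(cid, np.nan),
                "jac": mean_jaccard_feature(targets, reference_sets),
                "gosim": gosim,
                "man": float(man.loc[cid]),
                "label": labels[cid],
            }
        )
    df = pd.DataFrame(rows).set_index("compound_id")
    df["ob_imputed"] = df["ob"].isna()
    if df["ob_imputed"].any():
        median = df["ob"].median()
        log.info(
            "imputing OB median %.2f for %d compounds", median, df["ob_imputed"].sum()
        )
        df["ob"] = df["ob"].fillna(median)
    df["gosim_imputed"] = df["gosim"].isna()
    if df["gosim_imputed"].any():
        log.info("imputing gosim 0 for %d unannotated compounds",
                 df["gosim_imputed"].sum())
        df["gosim"] = df["gosim"].fillna(0.0)
    return df
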