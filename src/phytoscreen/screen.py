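"""Effectiveness screening: kernel KNN classifier, cross-validated ROC
analysis, per-drug effective-compound counts and Ward-clustering formula
selection.

The classifier scores each compound by the kernel-weighted fraction of
positive labels among its k nearest neighbours in standardized feature
space; the operating threshold is the ROC point closest to the (0, 1)
corner of pooled out-of-fold scores.  Baseline models (max-margin,
boosted trees, naive Bayes) run under the identical CV protocol.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import cdist
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "KNNConfig",
    "ROCResult",
    "standardize_features",
    "knn_score",
    "cross_validate",
    "roc_auc",
    "fit_baselines",
    "effective_counts",
    "ward_cluster",
    "select_formula",
    "ScreenModel",
    "ScreenResults",
]

EPS = 1e-12


@dataclass
class KNNConfig:
    k: int = 7
    kernel: str = "inverse_distance"  # uniform | inverse_distance | triangular
    folds: int = 10
    seed: int = 0
    standardize: bool = True


@dataclass
class ROCResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    operating_threshold: float
    operating_point: tuple


@dataclass
class StandardizeStats:
    mean: np.ndarray
    sd: np.ndarray

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean) / self.sd


def standardize_features(x: np.ndarray) -> tuple[np.ndarray, StandardizeStats]:
    """Column z-scores; returns the training statistics for reuse on
    held-out rows so no information leaks across folds.  Zero-variance
    columns are left at 0."""
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 rows to standardize")
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    flat = sd == 0
    if flat.any():
        warnings.warn("zero-variance feature(s) left at 0 after centering")
        sd = np.where(flat, 1.0, sd)
    stats = StandardizeStats(mean, sd)
    return stats.transform(x), stats


def _kernel_weights(d: np.ndarray, kernel: str) -> np.ndarray:
    if kernel == "uniform":
        return np.ones_like(d)
    if kernel == "inverse_distance":
        return 1.0 / (d + EPS)
    if kernel == "triangular":
        dmax = d.max(axis=1, keepdims=True)
        return np.where(dmax > 0, 1.0 - d / (dmax + EPS), 1.0)
    raise ValueError(f"unknown kernel {kernel!r}")


def knn_score(
    train_x: np.ndarray,
    train_y: np.ndarray,
    query_x: np.ndarray,
    cfg: KNNConfig,
) -> np.ndarray:
    """Kernel-weighted positive fraction among the k nearest Euclidean
    neighbours of each query row.

    Distance ties are broken by stable input order (numpy stable argsort).
    """
    train_x = np.atleast_2d(np.asarray(train_x, float))
    query_x = np.atleast_2d(np.asarray(query_x, float))
    train_y = np.asarray(train_y, float)
    if train_x.shape[1] != query_x.shape[1]:
        raise ValueError("feature dimension mismatch between train and query")
    if not 1 <= cfg.k <= len(train_x):
        raise ValueError("k must satisfy 1 <= k <= |train|")
    d = cdist(query_x, train_x)
    order = np.argsort(d, axis=1, kind="stable")[:, : cfg.k]
    dk = np.take_along_axis(d, order, axis=1)
    yk = train_y[order]
    w = _kernel_weights(dk, cfg.kernel)
    return (w * yk).sum(axis=1) / w.sum(axis=1)


def cross_validate(
    x: np.ndarray,
    y: np.ndarray,
    cfg: KNNConfig,
    scorer: Callable | None = None,
) -> tuple[np.ndarray, list[float]]:
    """Stratified k-fold out-of-fold scores and per-fold AUCs.

    Standardization statistics are fit on each training fold only.  A
    custom ``scorer(train_x, train_y, test_x) -> scores`` swaps in a
    baseline model under the identical protocol.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    skf = StratifiedKFold(n_splits=cfg.folds, shuffle=True, random_state=cfg.seed)
    oof = np.full(len(y), np.nan)
    fold_aucs = []
    for tr, te in skf.split(x, y):
        xtr, xte = x[tr], x[te]
        if cfg.standardize:
            xtr, stats = standardize_features(xtr)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                xte = stats.transform(np.asarray(xte, float))
        if scorer is None:
            k = min(cfg.k, len(tr))
            fold_cfg = KNNConfig(k, cfg.kernel, cfg.folds, cfg.seed, cfg.standardize)
            scores = knn_score(xtr, y[tr], xte, fold_cfg)
        else:
            scores = scorer(xtr, y[tr], xte)
        oof[te] = scores
        if len(np.unique(y[te])) == 2:
            fold_aucs.append(roc_auc(y[te], scores).auc)
    assert not np.isnan(oof).any()
    return oof, fold_aucs


def roc_auc(labels: np.ndarray, scores: np.ndarray) -> ROCResult:
    """ROC by threshold sweep over the unique scores; AUC by the
    trapezoidal rule (equals the Mann-Whitney rank statistic); operating
    threshold minimizes the distance to the (fpr, tpr) = (0, 1) corner."""
    y = np.asarray(labels, int)
    s = np.asarray(scores, float)
    pos = y == 1
    if pos.all() or (~pos).all():
        raise ValueError("ROC needs both classes")
    thresholds = np.concatenate(([np.inf], np.unique(s)[::-1]))
    fpr = np.empty(len(thresholds))
    tpr = np.empty(len(thresholds))
    np_, nn = pos.sum(), (~pos).sum()
    for i, t in enumerate(thresholds):
        call = s >= t
        tpr[i] = (call & pos).sum() / np_
        fpr[i] = (call & ~pos).sum() / nn
    auc = float(np.trapezoid(tpr, fpr))
    d = np.sqrt(fpr**2 + (1 - tpr) ** 2)
    best = int(np.argmin(d))
    if not np.isfinite(thresholds[best]):
        best = 1 if len(thresholds) > 1 else 0
    return ROCResult(
        thresholds, fpr, tpr, auc, float(thresholds[best]), (fpr[best], tpr[best])
    )


def _baseline_scorers(seed: int) -> dict:
    from sklearn.ensemble import GradientBoostingClassifier
    from sklearn.naive_bayes import GaussianNB
    from sklearn.svm import SVC

    def make(factory):
        def scorer(xtr, ytr, xte):
            m = factory()
            m.fit(xtr, ytr)
            return m.predict_proba(xte)[:, 1]

        return scorer

    return {
        "svm": make(lambda: SVC(probability=True, random_state=seed)),
        "gbdt": make(lambda: GradientBoostingClassifier(random_state=seed)),
        "bayes": make(GaussianNB),
    }


def fit_baselines(x: np.ndarray, y: np.ndarray, cfg: KNNConfig) -> dict:
    """Out-of-fold AUC of the comparison classifiers (SVM, GBDT, naive
    Bayes) under the same stratified folds as the KNN model."""
    out = {}
    for name, scorer in _baseline_scorers(cfg.seed).items():
        oof, _ = cross_validate(x, y, cfg, scorer=scorer)
        out[name] = roc_auc(y, oof).auc
    return out


def effective_counts(
    effective: Mapping[str, Mapping[str, bool]],
    drug_compounds: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Drugs x modules matrix of effective-compound counts.

    ``effective[column][compound]`` is the thresholded call of the
    column's classifier (symptom-module classifiers plus an ``overall``
    disease-level column).  A drug with no compounds yields a zero row.
    """
    cols = list(effective)
    rows = {}
    for drug in sorted(drug_compounds, key=str):
        comps = drug_compounds[drug]
        if not comps:
            warnings.warn(f"drug {drug} has no compounds; zero row")
        rows[drug] = [
            int(sum(bool(effective[c].get(comp, False)) for comp in comps))
            for c in cols
        ]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def ward_cluster(counts: pd.DataFrame, row_totals: pd.Series | None = None) -> np.ndarray:
    """Ward-linkage agglomerative clustering of the drug count rows
    (Euclidean distance, Lance-Williams update).

    With ``row_totals`` (e.g. each drug's compound count) rows are first
    scaled to per-drug effective fractions so drug size does not dominate
    the Euclidean geometry.  Returns the scipy linkage matrix (n-1
    merges; heights monotone non-decreasing).
    """
    if len(counts) < 2:
        raise ValueError("need at least 2 drugs to cluster")
    x = counts.to_numpy(dtype=float)
    if row_totals is not None:
        tot = row_totals.reindex(counts.index).to_numpy(dtype=float)[:, None]
        x = np.divide(x, tot, out=np.zeros_like(x), where=tot > 0)
    return linkage(x, method="ward")


def select_formula(
    dendro: np.ndarray,
    counts: pd.DataFrame,
    n_clusters: int = 2,
    n_permutations: int = 10_000,
    seed: int = 0,
    overall_column: str | None = None,
) -> dict:
    """Cut the dendrogram and pick the cluster of effective drugs.

    The selected cluster maximizes the mean overall effective count; its
    significance is a permutation test of (selected mean - complement
    mean) under random reassignment of the cluster labels to drugs.
    """
    if len(counts) < 3:
        raise ValueError("need at least 3 drugs")
    labels = cut_tree(dendro, n_clusters=n_clusters).ravel()
    col = counts[overall_column] if overall_column else counts.iloc[:, -1]
    vals = col.to_numpy(dtype=float)
    means = [vals[labels == c].mean() for c in range(n_clusters)]
    order = sorted(
        range(n_clusters), key=lambda c: (-means[c], -(labels == c).sum())
    )
    chosen = order[0]
    tie = len({round(m, 12) for m in means}) < n_clusters
    sel = labels == chosen
    stat = vals[sel].mean() - vals[~sel].mean()
    k, n = int(sel.sum()), len(vals)
    rng = np.random.default_rng(seed)
    # vectorized permutation of which k drugs form the selected cluster
    idx = np.argsort(rng.random((n_permutations, n)), axis=1)[:, :k]
    perm_sel_mean = vals[idx].mean(axis=1)
    total = vals.sum()
    perm_stat = perm_sel_mean - (total - perm_sel_mean * k) / (n - k)
    p = float((np.sum(perm_stat >= stat - 1e-12) + 1) / (n_permutations + 1))
    return {
        "drugs": sorted(counts.index[sel]),
        "p_value": p,
        "statistic": float(stat),
        "cluster_means": means,
        "tie": tie,
    }


@dataclass
class ScreenResults:
    """Fitted screening results: pooled out-of-fold scores, ROC with the
    operating threshold, per-fold and baseline AUCs."""

    oof_scores: pd.Series
    roc: ROCResult
    fold_aucs: list
    baseline_aucs: dict = field(default_factory=dict)
    config: KNNConfig = field(default_factory=KNNConfig)

    @property
    def auc(self) -> float:
        return self.roc.auc

    def effective_calls(self) -> pd.Series:
        return self.oof_scores >= self.roc.operating_threshold

    def summary(self) -> str:
        lines = [
            "Kernel KNN effectiveness screen",
            f"  compounds: {len(self.oof_scores)}   k={self.config.k} "
            f"kernel={self.config.kernel} folds={self.config.folds}",
            f"  out-of-fold AUC: {self.auc:.3f} "
            f"(per-fold mean {np.mean(self.fold_aucs):.3f})",
            f"  operating threshold: {self.roc.operating_threshold:.3f} "
            f"at (fpr, tpr) = ({self.roc.operating_point[0]:.3f}, "
            f"{self.roc.operating_point[1]:.3f})",
            f"  compounds called effective: {int(self.effective_calls().sum())}",
        ]
        for name, auc in self.baseline_aucs.items():
            lines.append(f"  baseline {name}: AUC {auc:.3f}")
        return "\n".join(lines)


class ScreenModel:
    """KNN effectiveness classifier over a compound feature table.

    Feature table rows are compounds with columns ob, jac, gosim, man and
    a binary ``label`` column (effective_candidate = positive).
    """

    FEATURES = ["ob", "jac", "gosim", "man"]

    def __init__(self, table: pd.DataFrame, config: KNNConfig | None = None,
                 features: Sequence[str] | None = None):
        self.table = table
        self.config = config or KNNConfig()
        self.features = list(features or self.FEATURES)

    def fit(self, with_baselines: bool = False) -> ScreenResults:
        x = self.table[self.features].to_numpy(dtype=float)
        y = (self.table["label"] == "effective_candidate").to_numpy(int)
        oof, fold_aucs = cross_validate(x, y, self.config)
        roc = roc_auc(y, oof)
        baselines = fit_baselines(x, y, self.config) if with_baselines else {}
        return ScreenResults(
            pd.Series(oof, index=self.table.index, name="oof_score"),
            roc,
            fold_aucs,
            baselines,
            self.config,
        )
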