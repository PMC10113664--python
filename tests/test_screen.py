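"""KNN screen, ROC analysis, effective counts, Ward clustering and
formula selection."""

import itertools

import numpy as np
import pandas as pd
import pytest

from phytoscreen.screen import (
    KNNConfig,
    ScreenModel,
    cross_validate,
    effective_counts,
    fit_baselines,
    knn_score,
    roc_auc,
    select_formula,
    standardize_features,
    ward_cluster,
)


class TestStandardize:
    def test_zscore_and_constant_column(self):
        x = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        with pytest.warns(UserWarning):
            z, stats = standardize_features(x)
        assert z[:, 0].mean() == pytest.approx(0.0)
        assert z[:, 0].std() == pytest.approx(1.0)
        assert np.all(z[:, 1] == 0.0)

    def test_heldout_rows_use_training_statistics(self):
        train = np.array([[0.0], [1.0], [2.0], [3.0]])
        held = np.array([[4.0], [5.0]])
        _, stats = standardize_features(train)
        transformed = stats.transform(held)
        self_std, _ = standardize_features(held)
        assert not np.allclose(transformed, self_std)
        assert transformed[0, 0] == pytest.approx((4 - 1.5) / train.std())


class TestKnnScore:
    def test_query_on_training_point_k1(self):
        x = np.array([[0.0], [1.0], [2.0]])
        y = np.array([1, 0, 1])
        s = knn_score(x, y, np.array([[1.0]]), KNNConfig(k=1, kernel="uniform"))
        assert s[0] == 0.0

    def test_k_equals_train_size_gives_global_fraction(self):
        x = np.arange(6, dtype=float).reshape(-1, 1)
        y = np.array([1, 1, 0, 0, 0, 0])
        s = knn_score(x, y, np.array([[10.0], [-3.0]]), KNNConfig(k=6, kernel="uniform"))
        assert np.allclose(s, 2 / 6)

    def test_matches_exhaustive_neighbor_oracle(self):
        """Kernel-weighted scores equal a brute-force neighbour search."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=(20, 3))
            y = rng.integers(0, 2, size=20)
            q = rng.normal(size=(5, 3))
            cfg = KNNConfig(k=3, kernel="inverse_distance")
            got = knn_score(x, y, q, cfg)
            for i in range(len(q)):
                d = [float(np.sqrt(((x[j] - q[i]) ** 2).sum())) for j in range(20)]
                order = sorted(range(20), key=lambda j: d[j])[:3]
                w = [1 / (d[j] + 1e-12) for j in order]
                expected = sum(wj * y[j] for wj, j in zip(w, order)) / sum(w)
                assert got[i] == pytest.approx(expected, abs=1e-10)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            knn_score(np.zeros((3, 2)), np.zeros(3), np.zeros((1, 3)), KNNConfig(k=1))


class TestCrossValidate:
    def separable(self, n=60):
        rng = np.random.default_rng(1)
        y = np.repeat([0, 1], n // 2)
        x = rng.normal(size=(n, 2)) + 8 * y[:, None]
        return x, y

    def test_separable_data_perfect_auc(self):
        x, y = self.separable()
        oof, fold_aucs = cross_validate(x, y, KNNConfig(seed=0))
        assert roc_auc(y, oof).auc == 1.0
        assert np.mean(fold_aucs) == 1.0

    def test_every_row_scored_once(self):
        x, y = self.separable()
        oof, _ = cross_validate(x, y, KNNConfig(seed=0))
        assert np.isfinite(oof).all()

    def test_shuffled_labels_give_chance_auc(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(60, 4))
        aucs = []
        for seed in range(30):
            y = np.random.default_rng(seed).permutation([0, 1] * 30)
            oof, _ = cross_validate(x, y, KNNConfig(seed=seed))
            aucs.append(roc_auc(y, oof).auc)
        assert 0.4 <= np.mean(aucs) <= 0.6

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            cross_validate(np.zeros((20, 2)), np.ones(20), KNNConfig())


class TestRocAuc:
    def test_perfect_scores(self):
        r = roc_auc([1, 1, 0, 0], [1.0, 1.0, 0.0, 0.0])
        assert r.auc == 1.0
        assert r.operating_point == (0.0, 1.0)

    def test_anticorrelated_scores(self):
        assert roc_auc([1, 1, 0, 0], [0.0, 0.0, 1.0, 1.0]).auc == 0.0

    def test_three_quarters_example(self):
        assert roc_auc([1, 1, 0, 0], [0.9, 0.4, 0.6, 0.1]).auc == pytest.approx(0.75)

    def test_trapezoid_equals_rank_statistic(self):
        """Trapezoidal AUC equals the Mann-Whitney formulation exactly."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = rng.integers(0, 2, size=50)
            if len(np.unique(y)) < 2:
                continue
            s = np.round(rng.random(50), 2)  # force ties
            pos, neg = s[y == 1], s[y == 0]
            pairs = [(a > b) + 0.5 * (a == b) for a in pos for b in neg]
            mw = np.mean(pairs)
            assert roc_auc(y, s).auc == pytest.approx(mw, abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, size=40)
        s = rng.random(40)
        assert roc_auc(y, s).auc == pytest.approx(
            roc_auc(y, np.exp(3 * s)).auc, abs=1e-12
        )

    def test_fpr_tpr_monotone(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, size=30)
        r = roc_auc(y, rng.random(30))
        assert (np.diff(r.fpr) >= 0).all()
        assert (np.diff(r.tpr) >= 0).all()

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 1], [0.2, 0.4])


class TestBaselines:
    def test_separable_data_all_models_perfect(self):
        rng = np.random.default_rng(0)
        y = np.repeat([0, 1], 30)
        x = rng.normal(size=(60, 2)) + 10 * y[:, None]
        aucs = fit_baselines(x, y, KNNConfig(seed=0, folds=5))
        assert set(aucs) == {"svm", "gbdt", "bayes"}
        assert all(a == 1.0 for a in aucs.values())

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        y = np.repeat([0, 1], 25)
        x = rng.normal(size=(50, 3)) + 0.8 * y[:, None]
        a1 = fit_baselines(x, y, KNNConfig(seed=5, folds=5))
        a2 = fit_baselines(x, y, KNNConfig(seed=5, folds=5))
        assert a1 == a2


class TestEffectiveCounts:
    def test_manual_tally(self):
        calls = {
            "M0": {"c1": True, "c2": False, "c3": True, "c4": False},
            "overall": {"c1": True, "c2": True, "c3": False, "c4": False},
        }
        drugs = {"d1": ["c1", "c2"], "d2": ["c3", "c4"], "d3": []}
        with pytest.warns(UserWarning):
            m = effective_counts(calls, drugs)
        assert m.loc["d1"].tolist() == [1, 2]
        assert m.loc["d2"].tolist() == [1, 0]
        assert m.loc["d3"].tolist() == [0, 0]

    def test_all_effective_rows_sum_to_compound_counts(self):
        calls = {"overall": {c: True for c in "abcdef"}}
        drugs = {"d1": list("abc"), "d2": list("def")}
        m = effective_counts(calls, drugs)
        assert m["overall"].tolist() == [3, 3]


def lance_williams_ward(x):
    """Independent Ward oracle via the Lance-Williams recurrence."""
    n = len(x)
    sizes = {i: 1 for i in range(n)}
    d = {}
    for i in range(n):
        for j in range(i + 1, n):
            d[(i, j)] = float(np.sqrt(((x[i] - x[j]) ** 2).sum()))
    active = set(range(n))
    heights = []
    next_id = n
    while len(active) > 1:
        (i, j), h = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        heights.append(h)
        k = next_id
        next_id += 1
        for m in active - {i, j}:
            dik = d[tuple(sorted((i, m)))]
            djk = d[tuple(sorted((j, m)))]
            dij = d[(i, j)]
            ni, nj, nm = sizes[i], sizes[j], sizes[m]
            val = np.sqrt(
                ((ni + nm) * dik**2 + (nj + nm) * djk**2 - nm * dij**2)
                / (ni + nj + nm)
            )
            d[tuple(sorted((k, m)))] = float(val)
        for key in [key for key in d if i in key or j in key]:
            del d[key]
        sizes[k] = sizes[i] + sizes[j]
        active -= {i, j}
        active.add(k)
    return heights


class TestWardCluster:
    def test_identical_rows_merge_at_zero(self):
        counts = pd.DataFrame([[1, 2], [1, 2], [5, 9]], index=list("abc"))
        z = ward_cluster(counts)
        assert z[0, 2] == pytest.approx(0.0)

    def test_1d_merge_order(self):
        counts = pd.DataFrame([[0.0], [1.0], [10.0]], index=list("abc"))
        z = ward_cluster(counts)
        assert sorted(z[0, :2].astype(int)) == [0, 1]  # 0 and 1 merge first

    def test_heights_monotone(self, rng):
        counts = pd.DataFrame(rng.random((10, 4)))
        z = ward_cluster(counts)
        assert (np.diff(z[:, 2]) >= -1e-12).all()

    def test_matches_lance_williams_oracle(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = rng.random((8, 5))
            z = ward_cluster(pd.DataFrame(x))
            assert np.allclose(sorted(z[:, 2]), sorted(lance_williams_ward(x)), atol=1e-9)

    def test_row_totals_normalization(self):
        counts = pd.DataFrame([[10, 20], [1, 2]], index=["big", "small"])
        totals = pd.Series({"big": 20, "small": 2})
        z = ward_cluster(counts, row_totals=totals)
        assert z[0, 2] == pytest.approx(0.0)  # identical fractions


class TestSelectFormula:
    def counts(self, highs, lows):
        rows = [[v] for v in highs + lows]
        idx = [f"h{i}" for i in range(len(highs))] + [f"l{i}" for i in range(len(lows))]
        return pd.DataFrame(rows, index=idx, columns=["overall"])

    def test_planted_block_selected(self):
        counts = self.counts([30, 32, 31], [2, 3, 1, 2])
        sel = select_formula(ward_cluster(counts), counts, seed=0)
        assert set(sel["drugs"]) == {"h0", "h1", "h2"}
        assert sel["p_value"] < 0.05

    def test_identical_rows_null_p(self):
        counts = self.counts([5, 5, 5], [5, 5, 5])
        sel = select_formula(ward_cluster(counts), counts, seed=0)
        assert sel["p_value"] > 0.5

    def test_permutation_p_matches_exhaustive_enumeration(self):
        """Monte-Carlo p within binomial error of the exact enumeration."""
        vals = np.array([9.0, 7.5, 8.2, 1.0, 2.1, 1.4])
        counts = pd.DataFrame({"overall": vals}, index=list("abcdef"))
        sel = select_formula(
            ward_cluster(counts), counts, n_permutations=20_000, seed=1
        )
        k = len(sel["drugs"])
        obs = sel["statistic"]
        stats = []
        for combo in itertools.combinations(range(6), k):
            s = vals[list(combo)].mean() - np.delete(vals, list(combo)).mean()
            stats.append(s)
        exact = np.mean([s >= obs - 1e-12 for s in stats])
        se = np.sqrt(exact * (1 - exact) / 20_000) + 1 / 20_000
        assert abs(sel["p_value"] - exact) <= 4 * se + 1e-4

    def test_too_few_drugs_rejected(self):
        counts = self.counts([5], [1])
        with pytest.raises(ValueError):
            select_formula(ward_cluster(counts), counts)


class TestScreenModel:
    def test_fit_returns_results_with_summary(self):
        rng = np.random.default_rng(0)
        n = 80
        label = np.repeat(["effective_candidate", "other"], n // 2)
        table = pd.DataFrame(
            {
                "ob": rng.normal(40, 5, n) - 15 * (label == "other"),
                "jac": rng.random(n),
                "gosim": rng.random(n),
                "man": rng.random(n),
                "label": label,
            },
            index=[f"c{i}" for i in range(n)],
        )
        res = ScreenModel(table, KNNConfig(seed=0)).fit(with_baselines=False)
        assert res.auc > 0.9
        assert 0 < res.effective_calls().sum() < n
        text = res.summary()
        assert "out-of-fold AUC" in text and "operating threshold" in text
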