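import numpy as np
import pandas as pd
import pytest

from psylang.classify import (
    CvScheme,
    FeatureSetConfig,
    case_report,
    cv_accuracy,
    fit_shallow_tree,
    rank_features,
    select_top_decorrelated,
)


def planted_signal_table(seed, n_per_class=45, n_features=30, n_signal=5, delta=1.5):
    """Binary cohort where exactly ``n_signal`` features carry a
    standardized mean difference ``delta``; the rest are pure noise."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    X = rng.standard_normal((n, n_features))
    y = np.array(["A"] * n_per_class + ["B"] * n_per_class, dtype=object)
    signal_cols = [f"f{j}" for j in range(n_signal)]
    X[:n_per_class, :n_signal] += delta
    data = pd.DataFrame(X, columns=[f"f{j}" for j in range(n_features)],
                        index=[f"s{i}" for i in range(n)])
    return data, y, signal_cols


class TestRankFeatures:
    def test_planted_signal_recovered_in_top10(self):
        hits = []
        for seed in range(10):
            data, y, signal = planted_signal_table(seed)
            ranking = rank_features(data, y, seed=seed, n_estimators=200)
            top10 = ranking.features()[:10]
            hits.append(sum(f in top10 for f in signal))
        assert np.median(hits) >= 4

    def test_noise_importances_below_permutation_null(self):
        rng = np.random.default_rng(0)
        data = pd.DataFrame(rng.standard_normal((60, 10)), columns=[f"f{j}" for j in range(10)])
        y = np.array(["A", "B"] * 30, dtype=object)
        obs = max(i for _, i in rank_features(data, y, seed=1, n_estimators=100).entries)
        null_max = []
        for k in range(20):
            yp = rng.permutation(y)
            null_max.append(max(i for _, i in rank_features(data, yp, seed=k, n_estimators=100).entries))
        assert obs <= np.quantile(null_max, 0.95) * 1.2

    def test_deterministic_given_seed(self):
        data, y, _ = planted_signal_table(3)
        r1 = rank_features(data, y, seed=7, n_estimators=100)
        r2 = rank_features(data, y, seed=7, n_estimators=100)
        assert r1.entries == r2.entries

    def test_constant_labels_rejected(self):
        data, _, _ = planted_signal_table(0)
        with pytest.raises(ValueError):
            rank_features(data, np.array(["A"] * len(data), dtype=object), seed=0)


class TestSelectTopDecorrelated:
    def test_exact_duplicate_skipped(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal(100)
        data = pd.DataFrame({"a": a, "b": a.copy(), "c": rng.standard_normal(100)})
        ranking = rank_features(data, np.array(["X", "Y"] * 50, dtype=object), seed=0, n_estimators=50)
        # force a known order: a first, its duplicate b second
        from psylang.classify import ImportanceRanking

        forced = ImportanceRanking(entries=(("a", 3.0), ("b", 2.0), ("c", 1.0)),
                                   method="forced", seed=0, contrast="t")
        cfg = select_top_decorrelated(forced, data, n=2, r_max=0.7)
        assert cfg.columns == ("a", "c")

    def test_independent_features_keep_ranking_order(self):
        rng = np.random.default_rng(2)
        data = pd.DataFrame(rng.standard_normal((200, 6)), columns=list("abcdef"))
        from psylang.classify import ImportanceRanking

        forced = ImportanceRanking(entries=tuple((c, 6.0 - i) for i, c in enumerate("abcdef")),
                                   method="forced", seed=0, contrast="t")
        cfg = select_top_decorrelated(forced, data, n=4, r_max=0.7)
        assert cfg.columns == ("a", "b", "c", "d")

    def test_selected_set_pairwise_below_rmax(self):
        rng = np.random.default_rng(3)
        base = rng.standard_normal((120, 5))
        cols = {}
        for j in range(5):
            cols[f"f{j}"] = base[:, j]
            cols[f"f{j}_dup"] = base[:, j] + 0.05 * rng.standard_normal(120)
        data = pd.DataFrame(cols)
        y = np.array(["X", "Y"] * 60, dtype=object)
        ranking = rank_features(data, y, seed=4, n_estimators=50)
        cfg = select_top_decorrelated(ranking, data, n=5, r_max=0.7)
        corr = data[list(cfg.columns)].corr().abs().to_numpy()
        off_diag = corr[~np.eye(len(cfg.columns), dtype=bool)]
        assert (off_diag < 0.7).all()

    def test_invalid_n(self):
        data, y, _ = planted_signal_table(0)
        ranking = rank_features(data, y, seed=0, n_estimators=50)
        with pytest.raises(ValueError):
            select_top_decorrelated(ranking, data, n=0)


class TestCvAccuracy:
    def test_perfectly_separable_single_feature(self):
        data = pd.DataFrame({"f": np.r_[np.zeros(20), np.ones(20)]},
                            index=[f"s{i}" for i in range(40)])
        y = np.array(["A"] * 20 + ["B"] * 20, dtype=object)
        rep = cv_accuracy(data, y, FeatureSetConfig(id="one", columns=("f",)),
                          CvScheme(folds=5, repeats=2, seed=0, n_estimators=50))
        assert rep.mean_accuracy == pytest.approx(1.0)

    def test_null_features_near_chance(self):
        rng = np.random.default_rng(5)
        data = pd.DataFrame(rng.standard_normal((90, 10)),
                            columns=[f"f{j}" for j in range(10)],
                            index=[f"s{i}" for i in range(90)])
        y = np.array(["A", "B"] * 45, dtype=object)
        rep = cv_accuracy(data, y, FeatureSetConfig(id="all", columns=tuple(data.columns)),
                          CvScheme(folds=5, repeats=4, seed=1, n_estimators=100))
        assert 0.42 <= rep.mean_accuracy <= 0.58  # 99% binomial band at n=90

    def test_strong_signal_high_accuracy(self):
        data, y, _ = planted_signal_table(6, n_features=10, n_signal=10, delta=1.5)
        rep = cv_accuracy(data, y, FeatureSetConfig(id="all", columns=tuple(data.columns)),
                          CvScheme(folds=5, repeats=2, seed=2, n_estimators=100))
        assert rep.mean_accuracy >= 0.85

    def test_missing_values_imputed_within_fold(self):
        data, y, _ = planted_signal_table(7, n_features=6, n_signal=6)
        data.iloc[::7, 0] = np.nan
        rep = cv_accuracy(data, y, FeatureSetConfig(id="all", columns=tuple(data.columns)),
                          CvScheme(folds=5, repeats=1, seed=0, n_estimators=50))
        assert rep.mean_accuracy > 0.8

    def test_too_many_folds_rejected(self):
        data = pd.DataFrame({"f": np.arange(8.0)})
        y = np.array(["A"] * 4 + ["B"] * 4, dtype=object)
        with pytest.raises(ValueError, match="folds"):
            cv_accuracy(data, y, FeatureSetConfig(id="one", columns=("f",)),
                        CvScheme(folds=5, repeats=1))

    def test_reproducible_given_seed(self):
        data, y, _ = planted_signal_table(8, n_per_class=20)
        scheme = CvScheme(folds=4, repeats=2, seed=9, n_estimators=50)
        cfg = FeatureSetConfig(id="all", columns=tuple(data.columns))
        r1 = cv_accuracy(data, y, cfg, scheme)
        r2 = cv_accuracy(data, y, cfg, scheme)
        assert np.array_equal(r1.fold_accuracies, r2.fold_accuracies)
        assert np.array_equal(r1.majority_vote(), r2.majority_vote())


class TestCaseReport:
    def _reports(self):
        data, y, _ = planted_signal_table(10, n_per_class=20, n_features=8, n_signal=8)
        scheme = CvScheme(folds=4, repeats=3, seed=0, n_estimators=50)
        r1 = cv_accuracy(data, y, FeatureSetConfig(id="all", columns=tuple(data.columns)), scheme)
        r2 = cv_accuracy(data, y, FeatureSetConfig(id="first", columns=("f0",)), scheme)
        return [r1, r2], y

    def test_matrix_shape_and_match_flags(self):
        reports, y = self._reports()
        matrix = case_report(reports)
        assert matrix.shape == (5, 40)  # reference + 2 configs + 2 match rows
        for rep in reports:
            votes = rep.majority_vote()
            stored = matrix.loc[rep.feature_set].to_numpy()
            assert (stored == votes).all()
            match = matrix.loc[f"{rep.feature_set}_match"].to_numpy().astype(int)
            assert (match == (votes == np.asarray(y, dtype=object)).astype(int)).all()

    def test_subject_mismatch_rejected(self):
        reports, _ = self._reports()
        import dataclasses

        broken = dataclasses.replace(reports[1])
        broken.subject_ids = tuple(reversed(reports[1].subject_ids))
        with pytest.raises(ValueError):
            case_report([reports[0], broken])


class TestShallowTree:
    def test_single_separating_feature_gives_depth_one(self):
        data = pd.DataFrame({"f": np.r_[np.zeros(20), np.ones(20)],
                             "g": np.random.default_rng(0).standard_normal(40)})
        y = np.array(["A"] * 20 + ["B"] * 20, dtype=object)
        tree = fit_shallow_tree(data, y, FeatureSetConfig(id="t", columns=("f", "g")), seed=0)
        assert tree.tree.get_depth() == 1
        assert "f" in tree.to_text()

    def test_self_consistent_predictions(self):
        data, y, _ = planted_signal_table(11, n_per_class=25, n_features=6, n_signal=3)
        tree = fit_shallow_tree(data, y, FeatureSetConfig(id="t", columns=tuple(data.columns)), seed=0)
        stored = tree.tree.predict(np.nan_to_num(data.to_numpy()))
        assert (tree.predict(data) == stored).all()

    def test_hierarchical_split_uses_primary_feature_at_root(self):
        roots = []
        for seed in range(9):
            rng = np.random.default_rng(seed)
            n = 200
            # y = a AND b with asymmetric marginals: splitting on a is
            # strictly more informative, b refines within a = 1
            a = rng.random(n) < 0.5
            b = rng.random(n) < 0.8
            y = np.where(a & b, "A", "B").astype(object)
            data = pd.DataFrame({"a": a.astype(float) + 0.01 * rng.random(n),
                                 "b": b.astype(float) + 0.01 * rng.random(n)})
            tree = fit_shallow_tree(data, y, FeatureSetConfig(id="t", columns=("a", "b")), seed=seed)
            roots.append(tree.columns[tree.tree.tree_.feature[0]])
        assert sum(r == "a" for r in roots) >= 5  # median-over-seeds root

    def test_depth_bound_respected(self):
        data, y, _ = planted_signal_table(12)
        tree = fit_shallow_tree(data, y, FeatureSetConfig(id="t", columns=tuple(data.columns)),
                                max_depth=3, seed=0)
        assert tree.tree.get_depth() <= 3
        assert tree.to_graph_description().startswith("digraph")
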