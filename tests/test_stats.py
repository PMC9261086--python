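import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from psylang.corpus import FeatureTable, LANGUAGE_FEATURES
from psylang.stats import (
    EXACT_MAX_N,
    compare_groups,
    correlation_clusters,
    kruskal_wallis,
    mann_whitney,
    normality_screen,
    symptom_correlations,
)


def _oracle_mw_two_sided(a, b):
    """Exact two-sided Mann-Whitney p via rank-sum enumeration (independent
    of the implementation's value-comparison route)."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n1 = len(a)
    u_obs = sps.rankdata(pooled)[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    for c in itertools.combinations(range(len(pooled)), n1):
        us.append(ranks[list(c)].sum() - n1 * (n1 + 1) / 2)
    us = np.array(us)
    eps = 1e-12
    return min(1.0, 2 * min((us <= u_obs + eps).mean(), (us >= u_obs - eps).mean()))


class TestNormalityScreen:
    def test_gaussian_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(0)
        rejections = sum(normality_screen(rng.standard_normal(200))[1] < 0.05 for _ in range(200))
        assert 2 <= rejections <= 22  # ~5% of 200, generous binomial band

    def test_large_gaussian_sample_not_rejected_usually(self):
        rng = np.random.default_rng(1)
        w, p = normality_screen(rng.standard_normal(5000))
        assert w > 0.99

    def test_skewed_sample_rejected(self):
        rng = np.random.default_rng(2)
        _, p = normality_screen(rng.exponential(size=100))
        assert p < 0.01

    def test_small_or_constant_samples_rejected(self):
        with pytest.raises(ValueError):
            normality_screen([1.0, 2.0])
        with pytest.raises(ValueError):
            normality_screen([3.0] * 10)


class TestMannWhitney:
    def test_identical_samples_u_half_p_one(self):
        u, p, exact = mann_whitney([1, 2, 3], [1, 2, 3])
        assert u == pytest.approx(4.5)  # n1*n2/2
        assert p == pytest.approx(1.0)
        assert exact

    def test_fully_separated_small_samples(self):
        u, p, exact = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2/20
        assert exact

    def test_exact_mode_matches_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        for n1 in range(2, 7):
            for n2 in range(n1, 7):
                a = rng.normal(size=n1)
                b = rng.normal(size=n2) + rng.choice([0, 1.5])
                _, p, exact = mann_whitney(a, b)
                assert exact
                assert p == pytest.approx(_oracle_mw_two_sided(a, b), abs=1e-12)

    def test_exact_mode_handles_ties(self):
        a, b = [1, 1, 2], [1, 2, 2]
        _, p, exact = mann_whitney(a, b)
        assert exact and 0 < p <= 1
        assert p == pytest.approx(_oracle_mw_two_sided(np.array(a, float), np.array(b, float)), abs=1e-12)

    def test_large_samples_use_approximation(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=30), rng.normal(size=30)
        _, p, exact = mann_whitney(a, b)
        assert not exact
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        assert p == pytest.approx(float(ref))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestKruskalWallis:
    def test_three_identical_groups_h_zero(self):
        h, p, _ = kruskal_wallis([1, 2, 3], [1, 2, 3], [1, 2, 3])
        assert h == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_exact_matches_label_permutation_oracle(self):
        rng = np.random.default_rng(5)
        for sizes in [(2, 2, 2), (3, 3, 3), (2, 3, 4), (4, 4, 4)]:
            groups = [rng.normal(size=n) + i for i, n in enumerate(sizes)]
            h_obs, p, exact = kruskal_wallis(*groups)
            assert exact
            pooled = np.concatenate(groups)
            count = total = 0
            idx = list(range(len(pooled)))
            for c1 in itertools.combinations(idx, sizes[0]):
                rest = [i for i in idx if i not in c1]
                for c2 in itertools.combinations(rest, sizes[1]):
                    c3 = [i for i in rest if i not in c2]
                    parts = [pooled[list(c1)], pooled[list(c2)], pooled[list(c3)]]
                    h = sps.kruskal(*parts).statistic if np.ptp(pooled) > 0 else 0.0
                    total += 1
                    count += h >= h_obs - 1e-12
            assert p == pytest.approx(count / total, abs=1e-12)

    def test_large_samples_match_chi_square_backend(self):
        rng = np.random.default_rng(6)
        groups = [rng.normal(size=20), rng.normal(size=20), rng.normal(size=20) + 1]
        h, p, exact = kruskal_wallis(*groups)
        assert not exact
        ref = sps.kruskal(*groups)
        assert p == pytest.approx(float(ref.pvalue))


class TestCompareGroups:
    def _table(self):
        rng = np.random.default_rng(7)
        data = pd.DataFrame({"f": np.concatenate([rng.normal(size=20), rng.normal(2, 1, 20), rng.normal(4, 1, 20)])})
        data.index = [f"s{i}" for i in range(60)]
        labels = ["HC"] * 20 + ["FEP"] * 20 + ["SZ"] * 20
        return data, labels

    def test_pairwise_and_three_group_results(self):
        data, labels = self._table()
        results = compare_groups(data, "f", labels)
        tests = {(r.test, r.groups) for r in results}
        assert ("kruskal-wallis", ("FEP", "HC", "SZ")) in tests
        assert len([r for r in results if r.test == "mann-whitney-U"]) == 3
        for r in results:
            assert 0 <= r.p_value <= 1

    def test_significance_stars(self):
        data, labels = self._table()
        kw = [r for r in compare_groups(data, "f", labels) if r.test == "kruskal-wallis"][0]
        assert kw.stars() == "***"  # p < 0.001 for well-separated groups


class TestSymptomCorrelations:
    def _table(self, n=40):
        rng = np.random.default_rng(8)
        data = pd.DataFrame(
            rng.random((n, 30)), columns=LANGUAGE_FEATURES, index=[f"s{i}" for i in range(n)]
        )
        data["panss_neg"] = np.arange(n, dtype=float)
        data["ttr500"] = data["panss_neg"] * 2 + 1  # exact linear relation
        data["ttr750"] = 5.0  # zero variance
        return FeatureTable(data=data)

    def test_exact_linear_relation(self):
        res = {r.feature: r for r in symptom_correlations(self._table(), "panss_neg")}
        assert res["ttr500"].r == pytest.approx(1.0)
        assert res["ttr500"].p < 1e-10

    def test_bonferroni_definition_and_clamp(self):
        res = {r.feature: r for r in symptom_correlations(self._table(), "panss_neg", k=30)}
        for r in res.values():
            if not np.isnan(r.p):
                assert r.p_bonferroni == pytest.approx(min(1.0, 30 * r.p))

    def test_zero_variance_feature_flagged_nan(self):
        res = {r.feature: r for r in symptom_correlations(self._table(), "panss_neg")}
        assert np.isnan(res["ttr750"].r)

    def test_p_matches_permutation_oracle(self):
        rng = np.random.default_rng(9)
        n = 40
        x = rng.standard_normal(n)
        y = 0.5 * x + np.sqrt(1 - 0.25) * rng.standard_normal(n)
        r, p = sps.pearsonr(x, y)
        assert abs(r - 0.5) < 0.25
        perm = np.array(
            [abs(sps.pearsonr(x, rng.permutation(y))[0]) for _ in range(2000)]
        )
        p_perm = (perm >= abs(r)).mean()
        assert p == pytest.approx(p_perm, abs=0.02)


class TestCorrelationClusters:
    def test_impossible_threshold_gives_singletons(self):
        rng = np.random.default_rng(10)
        data = pd.DataFrame(rng.random((30, 5)), columns=list("abcde"))
        cs = correlation_clusters(data, threshold=1.1)
        assert cs.clusters == ()
        assert len(cs.singletons) == 5

    def test_exact_duplicates_cluster(self):
        rng = np.random.default_rng(11)
        a = rng.random(50)
        data = pd.DataFrame({"a": a, "b": a.copy(), "c": rng.random(50)})
        cs = correlation_clusters(data, threshold=0.99)
        assert cs.clusters == (frozenset({"a", "b"}),)

    def test_planted_blocks_recovered(self):
        rng = np.random.default_rng(12)
        n = 300
        blocks = []
        cols = {}
        for b in range(3):
            base = rng.standard_normal(n)
            names = [f"b{b}f{j}" for j in range(3)]
            for name in names:
                cols[name] = 0.9 * base + np.sqrt(1 - 0.81) * rng.standard_normal(n)
            blocks.append(frozenset(names))
        data = pd.DataFrame(cols)
        cs = correlation_clusters(data, threshold=0.7)
        assert set(cs.clusters) == set(blocks)

    def test_partition_invariant_to_column_order(self):
        rng = np.random.default_rng(13)
        a = rng.random(50)
        data = pd.DataFrame({"a": a, "b": a + 0.01 * rng.random(50), "c": rng.random(50), "d": rng.random(50)})
        c1 = correlation_clusters(data, threshold=0.9)
        c2 = correlation_clusters(data[["d", "c", "b", "a"]], threshold=0.9)
        assert set(c1.clusters) == set(c2.clusters)
        assert c1.singletons == c2.singletons
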