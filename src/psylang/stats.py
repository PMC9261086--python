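"""Univariate group statistics for the feature table.

Normality is screened with Shapiro-Wilk; group location differences use
nonparametric tests throughout — Mann-Whitney U for pairs and
Kruskal-Wallis for the three groups — with exact permutation
enumeration for combined n <= 12 and the tie-corrected normal/chi-square
approximation otherwise.  Feature-symptom associations are Pearson
correlations with Bonferroni correction at a stated family size k.
Redundant features are grouped as connected components of the
|Pearson r| >= tau feature graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from psylang.corpus import FeatureTable

__all__ = [
    "GroupTestResult",
    "CorrelationResult",
    "FeatureClusterSet",
    "normality_screen",
    "mann_whitney",
    "kruskal_wallis",
    "compare_groups",
    "symptom_correlations",
    "correlation_clusters",
    "EXACT_MAX_N",
]

EXACT_MAX_N = 12  # combined sample size up to which p-values are enumerated exactly

SIGNIFICANCE_LEVELS = (0.001, 0.01, 0.05)


@dataclass(frozen=True)
class GroupTestResult:
    feature: str
    test: str  # "mann-whitney-U" | "kruskal-wallis"
    groups: tuple[str, ...]
    n: tuple[int, ...]
    statistic: float
    p_value: float
    exact: bool
    normality: Mapping[str, tuple[float, float]] = field(default_factory=dict)  # group -> (W, p)

    def stars(self) -> str:
        for i, alpha in enumerate(SIGNIFICANCE_LEVELS):
            if self.p_value < alpha:
                return "*" * (len(SIGNIFICANCE_LEVELS) - i)
        return ""


@dataclass(frozen=True)
class CorrelationResult:
    feature: str
    covariate: str
    n: int
    r: float
    p: float
    p_bonferroni: float
    k: int


@dataclass(frozen=True)
class FeatureClusterSet:
    clusters: tuple[frozenset[str], ...]  # components of size >= 2
    singletons: frozenset[str]
    threshold: float


def normality_screen(sample: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk (W, p).  Requires n >= 3 and a non-constant sample."""
    x = np.asarray(sample, dtype=np.float64)
    x = x[~np.isnan(x)]
    if x.size < 3:
        raise ValueError("normality_screen requires n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: normality test undefined")
    res = sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U for sample a (ties counted half)."""
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float(gt + 0.5 * eq)


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, bool]:
    """Two-sided Mann-Whitney U.

    Exact permutation enumeration (ties handled naturally, doubled
    one-tail convention) for combined n <= EXACT_MAX_N; otherwise the
    tie-corrected normal approximation with continuity correction.
    Returns (U for sample a, p, exact_flag).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")
    u_obs = _u_statistic(a, b)
    n1, n2 = a.size, b.size
    if n1 + n2 <= EXACT_MAX_N:
        pooled = np.concatenate([a, b])
        idx = range(n1 + n2)
        us = np.array(
            [_u_statistic(pooled[list(c)], np.delete(pooled, list(c))) for c in combinations(idx, n1)]
        )
        eps = 1e-12
        p_le = np.mean(us <= u_obs + eps)
        p_ge = np.mean(us >= u_obs - eps)
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return u_obs, float(p), True
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return u_obs, float(res.pvalue), False


def _h_statistic(groups: list[np.ndarray]) -> float:
    """Kruskal-Wallis H with mid-ranks and tie correction."""
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    offset = 0
    h = 0.0
    for g in groups:
        r = ranks[offset : offset + g.size]
        h += r.sum() ** 2 / g.size
        offset += g.size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie_corr = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    if tie_corr == 0:
        return 0.0
    return h / tie_corr


def kruskal_wallis(*groups: Sequence[float]) -> tuple[float, float, bool]:
    """Kruskal-Wallis across k groups; exact permutation enumeration for
    combined n <= EXACT_MAX_N (upper-tail p), chi-square otherwise."""
    gs = [np.asarray(g, dtype=np.float64) for g in groups]
    if any(g.size == 0 for g in gs):
        raise ValueError("empty group")
    h_obs = _h_statistic(gs)
    n_total = sum(g.size for g in gs)
    if n_total <= EXACT_MAX_N:
        # ranks (and the tie correction) are permutation-invariant, so
        # enumerate label assignments over precomputed ranks only
        pooled = np.concatenate(gs)
        sizes = [g.size for g in gs]
        ranks = sps.rankdata(pooled)
        _, counts_t = np.unique(pooled, return_counts=True)
        tie_corr = 1.0 - (counts_t**3 - counts_t).sum() / (n_total**3 - n_total)
        if tie_corr == 0:
            return 0.0, 1.0, True
        coef = 12.0 / (n_total * (n_total + 1))

        def h_from(parts: Sequence[np.ndarray]) -> float:
            return (coef * sum(r.sum() ** 2 / r.size for r in parts) - 3 * (n_total + 1)) / tie_corr

        eps = 1e-12
        count = 0
        total = 0

        def recurse(remaining: np.ndarray, size_idx: int, chosen: list[np.ndarray]):
            nonlocal count, total
            if size_idx == len(sizes) - 1:
                total += 1
                if h_from(chosen + [remaining]) >= h_obs - eps:
                    count += 1
                return
            for c in combinations(range(remaining.size), sizes[size_idx]):
                mask = np.zeros(remaining.size, dtype=bool)
                mask[list(c)] = True
                recurse(remaining[~mask], size_idx + 1, chosen + [remaining[mask]])

        recurse(ranks, 0, [])
        return h_obs, count / total, True
    try:
        _, p = sps.kruskal(*gs)
    except ValueError:  # all pooled values identical
        return 0.0, 1.0, False
    return h_obs, float(p), False


def compare_groups(
    table: FeatureTable | pd.DataFrame,
    feature: str,
    labels: Sequence[str],
    pairs: Optional[Sequence[tuple[str, str]]] = None,
    with_normality: bool = True,
) -> list[GroupTestResult]:
    """Mann-Whitney U per requested group pair plus Kruskal-Wallis over
    all groups (when >= 3); missing feature values are dropped."""
    data = table.data if isinstance(table, FeatureTable) else table
    values = data[feature].to_numpy(dtype=np.float64)
    labels = np.asarray(labels, dtype=object)
    keep = ~np.isnan(values)
    values, labels = values[keep], labels[keep]
    group_names = sorted(set(labels))
    if len(group_names) < 2:
        raise ValueError("need >= 2 groups")
    samples = {g: values[labels == g] for g in group_names}
    if any(s.size < 2 for s in samples.values()):
        raise ValueError("every group needs n >= 2")
    normality = {}
    if with_normality:
        for g, s in samples.items():
            try:
                normality[g] = normality_screen(s)
            except ValueError:
                normality[g] = (float("nan"), float("nan"))
    if pairs is None:
        pairs = list(combinations(group_names, 2))
    results = []
    for g1, g2 in pairs:
        u, p, exact = mann_whitney(samples[g1], samples[g2])
        results.append(
            GroupTestResult(
                feature=feature,
                test="mann-whitney-U",
                groups=(g1, g2),
                n=(samples[g1].size, samples[g2].size),
                statistic=u,
                p_value=p,
                exact=exact,
                normality={g: normality.get(g, (np.nan, np.nan)) for g in (g1, g2)},
            )
        )
    if len(group_names) >= 3:
        h, p, exact = kruskal_wallis(*[samples[g] for g in group_names])
        results.append(
            GroupTestResult(
                feature=feature,
                test="kruskal-wallis",
                groups=tuple(group_names),
                n=tuple(samples[g].size for g in group_names),
                statistic=h,
                p_value=p,
                exact=exact,
                normality=normality,
            )
        )
    return results


def symptom_correlations(
    table: FeatureTable,
    covariate: str,
    k: int = 30,
    features: Optional[Sequence[str]] = None,
) -> list[CorrelationResult]:
    """Pearson r of each language feature against a clinical covariate,
    with Bonferroni-corrected p at family size ``k``.  Zero-variance or
    undersized samples give NaN r (flagged by the NaN, not dropped)."""
    data = table.data
    if covariate not in data.columns:
        raise KeyError(f"covariate {covariate!r} not in table")
    if features is None:
        features = table.language_columns()
    results = []
    cov = data[covariate].to_numpy(dtype=np.float64)
    for feat in features:
        x = data[feat].to_numpy(dtype=np.float64)
        keep = ~(np.isnan(x) | np.isnan(cov))
        xs, ys = x[keep], cov[keep]
        if xs.size < 3 or np.ptp(xs) == 0 or np.ptp(ys) == 0:
            r, p = float("nan"), float("nan")
        else:
            res = sps.pearsonr(xs, ys)
            r, p = float(res.statistic), float(res.pvalue)
        p_bonf = float("nan") if np.isnan(p) else min(1.0, k * p)
        results.append(
            CorrelationResult(
                feature=feat, covariate=covariate, n=int(xs.size), r=r, p=p, p_bonferroni=p_bonf, k=k
            )
        )
    return results


def correlation_clusters(
    table: FeatureTable | pd.DataFrame,
    threshold: float = 0.7,
    features: Optional[Sequence[str]] = None,
) -> FeatureClusterSet:
    """Connected components of the feature graph with edges where
    |Pearson r| >= threshold; components of size >= 2 are clusters."""
    data = table.data if isinstance(table, FeatureTable) else table
    if features is None:
        features = table.language_columns() if isinstance(table, FeatureTable) else list(data.columns)
    feats = sorted(features)
    corr = data[feats].corr(method="pearson").abs().to_numpy()
    parent = list(range(len(feats)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(feats)):
        for j in range(i + 1, len(feats)):
            if not np.isnan(corr[i, j]) and corr[i, j] >= threshold:
                parent[find(i)] = find(j)
    comps: dict[int, set[str]] = {}
    for i, f in enumerate(feats):
        comps.setdefault(find(i), set()).add(f)
    clusters = tuple(sorted((frozenset(c) for c in comps.values() if len(c) >= 2), key=sorted))
    singles = frozenset(f for c in comps.values() if len(c) == 1 for f in c)
    return FeatureClusterSet(clusters=clusters, singletons=singles, threshold=threshold)


def group_stats_report(
    table: FeatureTable,
    labels: Sequence[str],
    pairs: Optional[Sequence[tuple[str, str]]] = None,
) -> pd.DataFrame:
    """Flat per-feature report: one row per (feature, test)."""
    rows = []
    for feat in table.language_columns():
        try:
            results = compare_groups(table, feat, labels, pairs=pairs)
        except ValueError:
            continue
        for r in results:
            rows.append(
                {
                    "feature": feat,
                    "test": r.test,
                    "groups": "|".join(r.groups),
                    "n": "|".join(str(x) for x in r.n),
                    "statistic": r.statistic,
                    "p_value": r.p_value,
                    "exact": r.exact,
                    "significance": r.stars(),
                }
            )
    return pd.DataFrame(rows)
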