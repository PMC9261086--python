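"""Random-forest ranking, decorrelated top-10 selection and
cross-validated classification.

The workflow mirrors a two-stage design: an initial random forest
ranks variables by mean impurity-decrease importance; a greedy scan of
that ranking keeps the top ``n`` features whose pairwise |Pearson r|
with already-kept features stays below ``r_max``; repeated stratified
k-fold cross-validation (default 10 folds x 12 repeats) then estimates
accuracy per feature-set configuration, with per-subject majority-vote
predictions for case-by-case reporting, and a depth-limited decision
tree gives an interpretable export.

Missing feature values are imputed with the *training-fold* median,
never across folds, to avoid leakage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier, export_text

from psylang.corpus import FeatureTable

__all__ = [
    "ImportanceRanking",
    "FeatureSetConfig",
    "CvScheme",
    "CvReport",
    "ShallowTree",
    "rank_features",
    "select_top_decorrelated",
    "cv_accuracy",
    "case_report",
    "fit_shallow_tree",
]

DEFAULT_N_TREES = 500


@dataclass(frozen=True)
class ImportanceRanking:
    """(feature, importance) pairs in non-increasing importance order."""

    entries: tuple[tuple[str, float], ...]
    method: str
    seed: int
    contrast: str

    def __post_init__(self) -> None:
        imps = [imp for _, imp in self.entries]
        if any(i < 0 for i in imps):
            raise ValueError("importances must be >= 0")
        if any(a < b for a, b in zip(imps, imps[1:])):
            raise ValueError("ranking must be non-increasing")

    def features(self) -> list[str]:
        return [f for f, _ in self.entries]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["feature", "importance"])


@dataclass(frozen=True)
class FeatureSetConfig:
    id: str
    columns: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.columns)) != len(self.columns):
            raise ValueError("duplicate columns in feature set")


@dataclass(frozen=True)
class CvScheme:
    folds: int = 10
    repeats: int = 12
    seed: int = 0
    n_estimators: int = DEFAULT_N_TREES


@dataclass
class CvReport:
    contrast: str
    feature_set: str
    scheme: CvScheme
    fold_accuracies: np.ndarray  # (repeats * folds,)
    subject_ids: tuple[str, ...]
    true_labels: tuple[str, ...]
    predictions: np.ndarray  # (repeats, n_subjects) object array of labels

    @property
    def mean_accuracy(self) -> float:
        return float(self.fold_accuracies.mean())

    @property
    def balanced_accuracy(self) -> float:
        """Mean per-class recall of the majority-vote predictions."""
        pred = self.majority_vote()
        true = np.asarray(self.true_labels, dtype=object)
        recalls = [np.mean(pred[true == c] == c) for c in sorted(set(true))]
        return float(np.mean(recalls))

    def majority_vote(self) -> np.ndarray:
        out = []
        for j in range(self.predictions.shape[1]):
            labels, counts = np.unique(self.predictions[:, j].astype(str), return_counts=True)
            out.append(labels[np.argmax(counts)])  # ties broken alphabetically
        return np.asarray(out, dtype=object)

    def to_row(self) -> dict:
        return {
            "contrast": self.contrast,
            "feature_set": self.feature_set,
            "folds": self.scheme.folds,
            "repeats": self.scheme.repeats,
            "seed": self.scheme.seed,
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": float(self.fold_accuracies.std(ddof=1)) if self.fold_accuracies.size > 1 else 0.0,
            "balanced_accuracy": self.balanced_accuracy,
        }


def _matrix(table: FeatureTable | pd.DataFrame, columns: Sequence[str]) -> np.ndarray:
    data = table.data if isinstance(table, FeatureTable) else table
    missing = [c for c in columns if c not in data.columns]
    if missing:
        raise KeyError(f"columns not in table: {missing}")
    return data[list(columns)].to_numpy(dtype=np.float64)


def _impute_median(train: np.ndarray, apply_to: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    med = np.nanmedian(train, axis=0)
    med = np.where(np.isnan(med), 0.0, med)
    fill = lambda X: np.where(np.isnan(X), med[None, :], X)
    return fill(train), fill(apply_to)


def rank_features(
    table: FeatureTable | pd.DataFrame,
    labels: Sequence[str],
    seed: int = 0,
    columns: Optional[Sequence[str]] = None,
    n_estimators: int = DEFAULT_N_TREES,
    contrast: str = "",
) -> ImportanceRanking:
    """Random-forest mean-impurity-decrease importance ranking.

    Ties are broken by column order for a fully deterministic ranking.
    """
    data = table.data if isinstance(table, FeatureTable) else table
    if columns is None:
        columns = table.language_columns() if isinstance(table, FeatureTable) else list(data.columns)
    y = np.asarray(labels, dtype=object)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("labels are constant; ranking needs >= 2 classes")
    if counts.min() < 10:
        warnings.warn(f"smallest class has n={counts.min()} (< 10); importances will be noisy")
    X = _matrix(table, columns)
    X, _ = _impute_median(X, X)
    rf = RandomForestClassifier(n_estimators=n_estimators, random_state=int(seed) % (2**31), n_jobs=1)
    rf.fit(X, y)
    imps = rf.feature_importances_
    order = np.lexsort((np.arange(len(columns)), -imps))
    entries = tuple((columns[i], float(imps[i])) for i in order)
    return ImportanceRanking(entries=entries, method="rf-impurity-decrease", seed=seed, contrast=contrast)


def select_top_decorrelated(
    ranking: ImportanceRanking,
    table: FeatureTable | pd.DataFrame,
    n: int = 10,
    r_max: float = 0.7,
    set_id: str = "top10-all",
) -> FeatureSetConfig:
    """Greedy scan of the ranking: keep a feature iff its max |Pearson
    r| with already-kept features is < r_max; stop at ``n``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    data = table.data if isinstance(table, FeatureTable) else table
    selected: list[str] = []
    for feat, _ in ranking.entries:
        if len(selected) == n:
            break
        if not selected:
            selected.append(feat)
            continue
        r = data[selected + [feat]].corr(method="pearson")[feat].iloc[:-1].abs()
        if bool((r.fillna(0.0) < r_max).all()):
            selected.append(feat)
    if len(selected) < n:
        warnings.warn(f"ranking exhausted: only {len(selected)} of {n} decorrelated features found")
    return FeatureSetConfig(id=set_id, columns=tuple(selected))


def cv_accuracy(
    table: FeatureTable | pd.DataFrame,
    labels: Sequence[str],
    config: FeatureSetConfig,
    scheme: CvScheme | None = None,
    contrast: str = "",
) -> CvReport:
    """Repeated stratified k-fold CV with a random forest per fold.

    Reports per-fold accuracies and per-subject predictions (each
    subject is predicted exactly once per repeat; the case report uses
    the across-repeat majority vote).
    """
    if scheme is None:
        scheme = CvScheme()
    data = table.data if isinstance(table, FeatureTable) else table
    X_all = _matrix(table, config.columns)
    y = np.asarray(labels, dtype=object)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need >= 2 classes")
    if counts.min() < scheme.folds:
        raise ValueError(
            f"smallest class (n={counts.min()}) < folds={scheme.folds}: a fold would miss a class; "
            "use a smaller k"
        )
    n = len(y)
    fold_acc = []
    predictions = np.empty((scheme.repeats, n), dtype=object)
    base = np.random.SeedSequence([int(scheme.seed) % (2**31), 0xC5])
    rep_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in base.spawn(scheme.repeats)]
    for rep, rep_seed in enumerate(rep_seeds):
        skf = StratifiedKFold(n_splits=scheme.folds, shuffle=True, random_state=rep_seed)
        for fold, (tr, te) in enumerate(skf.split(X_all, y)):
            X_tr, X_te = _impute_median(X_all[tr], X_all[te])
            rf = RandomForestClassifier(
                n_estimators=scheme.n_estimators,
                random_state=(rep_seed + fold) % (2**31),
                n_jobs=1,
            )
            rf.fit(X_tr, y[tr])
            pred = rf.predict(X_te)
            fold_acc.append(float(np.mean(pred == y[te])))
            predictions[rep, te] = pred
    ids = tuple(str(i) for i in (data.index if hasattr(data, "index") else range(n)))
    return CvReport(
        contrast=contrast,
        feature_set=config.id,
        scheme=scheme,
        fold_accuracies=np.asarray(fold_acc),
        subject_ids=ids,
        true_labels=tuple(str(v) for v in y),
        predictions=predictions,
    )


def case_report(reports: Sequence[CvReport]) -> pd.DataFrame:
    """Per-subject matrix: rows = feature-set configs (plus a reference
    row), columns = subjects, cells = majority-vote predicted label.
    A ``<id>_match`` row flags agreement with the reference labels."""
    if not reports:
        raise ValueError("no reports")
    ids = reports[0].subject_ids
    truth = reports[0].true_labels
    for r in reports[1:]:
        if r.subject_ids != ids:
            raise ValueError("subject sets differ across reports")
        if r.true_labels != truth:
            raise ValueError("reference labels differ across reports")
    rows = {"reference": list(truth)}
    for r in reports:
        vote = r.majority_vote()
        rows[r.feature_set] = list(vote)
        rows[f"{r.feature_set}_match"] = [int(v == t) for v, t in zip(vote, truth)]
    return pd.DataFrame(rows, index=list(ids)).T


@dataclass
class ShallowTree:
    """Depth-limited decision tree for interpretability export."""

    tree: DecisionTreeClassifier
    columns: tuple[str, ...]
    max_depth: int
    medians: np.ndarray

    def predict(self, table: FeatureTable | pd.DataFrame) -> np.ndarray:
        X = _matrix(table, self.columns)
        X = np.where(np.isnan(X), self.medians[None, :], X)
        return self.tree.predict(X)

    def to_text(self) -> str:
        return export_text(self.tree, feature_names=list(self.columns), decimals=3)

    def to_graph_description(self) -> str:
        """Graph description (DOT-like) of nodes and edges."""
        t = self.tree.tree_
        lines = ["digraph shallow_tree {"]
        classes = [str(c) for c in self.tree.classes_]
        for node in range(t.node_count):
            counts = t.value[node][0]
            if t.children_left[node] == -1:
                label = f"leaf: {classes[int(np.argmax(counts))]} {counts.astype(int).tolist()}"
            else:
                label = f"{self.columns[t.feature[node]]} <= {t.threshold[node]:.3f}"
            lines.append(f'  n{node} [label="{label}"];')
            if t.children_left[node] != -1:
                lines.append(f"  n{node} -> n{t.children_left[node]} [label=\"yes\"];")
                lines.append(f"  n{node} -> n{t.children_right[node]} [label=\"no\"];")
        lines.append("}")
        return "\n".join(lines)


def fit_shallow_tree(
    table: FeatureTable | pd.DataFrame,
    labels: Sequence[str],
    config: FeatureSetConfig,
    max_depth: int = 3,
    seed: int = 0,
) -> ShallowTree:
    """Single depth-<= ``max_depth`` tree fit on the full table (an
    interpretability export, not an accuracy estimate)."""
    X = _matrix(table, config.columns)
    med = np.nanmedian(X, axis=0)
    med = np.where(np.isnan(med), 0.0, med)
    X = np.where(np.isnan(X), med[None, :], X)
    y = np.asarray(labels, dtype=object)
    if np.unique(y).size < 2:
        raise ValueError("need >= 2 classes")
    tree = DecisionTreeClassifier(max_depth=max_depth, random_state=int(seed) % (2**31))
    tree.fit(X, y)
    return ShallowTree(tree=tree, columns=config.columns, max_depth=max_depth, medians=med)
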