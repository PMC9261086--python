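"""End-to-end runs: simulate/ingest -> extract -> stats -> classify -> report.

A run is governed by one :class:`RunConfig` (and one master seed) and
writes every result to a run directory as delimited text, so each
number in the report is traceable to an intermediate file:

    features.csv     per-subject feature table (category-tagged CSV)
    stats.csv        univariate group statistics
    importances.csv  random-forest variable ranking(s)
    cv_reports.csv   one row per (contrast, feature set) CV result
    case_matrix.csv  per-subject majority-vote predictions (longitudinal)
    trees/*.txt      shallow decision-tree exports (longitudinal)
    manifest.json    config, seed, package/library versions, warnings

Cross-sectional contrasts: HC vs FEP, HC vs SZ, HC vs FEP+SZ (patients
pooled).  Longitudinal contrast: C-SZ vs NC-SZ within FEP, over the
feature-set ladder demographics / panss / demographics+panss /
language / top10-all, plus per-category (fluency, productivity,
coherence) sets in both analyses.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from psylang import __version__
from psylang.classify import (
    CvReport,
    CvScheme,
    FeatureSetConfig,
    case_report,
    cv_accuracy,
    fit_shallow_tree,
    rank_features,
    select_top_decorrelated,
)
from psylang.corpus import FeatureTable, write_feature_table
from psylang.features import extract_table
from psylang.stats import correlation_clusters, group_stats_report
from psylang.synthetic import (
    CohortSample,
    CohortSpec,
    conversion_profiles,
    default_profiles,
    null_profiles,
    sample_cohort,
)

__all__ = ["RunConfig", "CohortReport", "run_cross_sectional", "run_longitudinal"]

CATEGORY_SETS = ("fluency", "productivity", "coherence")


@dataclass
class RunConfig:
    """One artifact of record per run; one master seed for every
    stochastic stage."""

    out_dir: str
    seed: int = 0
    input_mode: str = "synthetic"  # "synthetic" | "features"
    effect: str = "strong"  # "strong" | "null" (synthetic mode)
    features_path: Optional[str] = None  # features mode: existing table
    folds: int = 10
    repeats: int = 12
    n_estimators: int = 500
    top_n: int = 10
    r_max: float = 0.7
    cluster_tau: float = 0.7
    pause_threshold_s: float = 2.0
    ranking_mode: str = "per-contrast"  # "per-contrast" | "three-class"
    cohort_sizes: Optional[dict] = None  # override synthetic group sizes
    fep_split: Optional[dict] = None

    def scheme(self) -> CvScheme:
        return CvScheme(folds=self.folds, repeats=self.repeats, seed=self.seed,
                        n_estimators=self.n_estimators)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class CohortReport:
    table: FeatureTable
    stats: pd.DataFrame
    importances: pd.DataFrame
    cv_reports: list[CvReport]
    cv_summary: pd.DataFrame
    case_matrix: Optional[pd.DataFrame] = None
    manifest: dict = field(default_factory=dict)


def _load_table(config: RunConfig) -> tuple[FeatureTable, Optional[CohortSample]]:
    if config.input_mode == "synthetic":
        if config.effect == "strong":
            profiles = {**default_profiles(), **conversion_profiles()}
        elif config.effect == "null":
            profiles = null_profiles()
        else:
            raise ValueError(f"unknown effect {config.effect!r}")
        spec = CohortSpec()
        if config.cohort_sizes is not None:
            spec.sizes = dict(config.cohort_sizes)
        if config.fep_split is not None:
            spec.fep_split = dict(config.fep_split)
        cohort = sample_cohort(spec, profiles, seed=config.seed)
        table = extract_table(cohort.interviews, cohort.embedding_model(), cohort.preprocessor())
        return table, cohort
    if config.input_mode == "features":
        from psylang.corpus import read_feature_table

        if config.features_path is None:
            raise ValueError("features mode requires features_path")
        return read_feature_table(config.features_path, require_language_schema=True), None
    raise ValueError(f"unknown input_mode {config.input_mode!r}")


def _group_labels(table: FeatureTable, cohort: Optional[CohortSample]) -> np.ndarray:
    if cohort is not None:
        return cohort.labels("group")
    if "group" not in table.data.columns:
        raise ValueError("feature table needs a 'group' column when no cohort is given")
    return table.data["group"].to_numpy(dtype=object)


def _category_config(table: FeatureTable, category: str) -> FeatureSetConfig:
    return FeatureSetConfig(id=f"{category}-only", columns=tuple(table.columns_of(category)))


def _write_common(out: Path, config: RunConfig, report: CohortReport, extra_manifest: dict) -> None:
    out.mkdir(parents=True, exist_ok=True)
    write_feature_table(report.table, out / "features.csv")
    report.stats.to_csv(out / "stats.csv", index=False, float_format="%.12g")
    report.importances.to_csv(out / "importances.csv", index=False, float_format="%.12g")
    report.cv_summary.to_csv(out / "cv_reports.csv", index=False, float_format="%.12g")
    if report.case_matrix is not None:
        report.case_matrix.to_csv(out / "case_matrix.csv")
    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": _library_versions(),
        **extra_manifest,
    }
    report.manifest = manifest
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1), encoding="utf-8")


def _library_versions() -> dict:
    import sklearn
    import scipy

    return {
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "scikit-learn": sklearn.__version__,
    }


def run_cross_sectional(config: RunConfig) -> CohortReport:
    """Extraction -> group statistics -> ranking -> decorrelated top-10
    -> repeated CV for HC vs FEP, HC vs SZ and HC vs FEP+SZ, plus the
    per-category feature sets."""
    out = Path(config.out_dir)
    table, cohort = _load_table(config)
    groups = _group_labels(table, cohort)
    stats_df = group_stats_report(table, groups)
    clusters = correlation_clusters(table, threshold=config.cluster_tau)

    contrasts = {
        "HC_vs_FEP": np.isin(groups, ["HC", "FEP"]),
        "HC_vs_SZ": np.isin(groups, ["HC", "SZ"]),
        "HC_vs_FEP+SZ": np.ones(len(groups), dtype=bool),
    }
    scheme = config.scheme()
    imp_rows = []
    reports: list[CvReport] = []
    three_class_ranking = None
    if config.ranking_mode == "three-class":
        three_class_ranking = rank_features(table, groups, seed=config.seed, contrast="HC_vs_FEP_vs_SZ")
    for name, mask in contrasts.items():
        sub = FeatureTable(
            data=table.data.loc[mask], categories=dict(table.categories)
        )
        y = np.where(groups[mask] == "HC", "HC", "patient") if name == "HC_vs_FEP+SZ" else groups[mask]
        ranking = (
            three_class_ranking
            if three_class_ranking is not None
            else rank_features(sub, y, seed=config.seed, contrast=name)
        )
        for feat, imp in ranking.entries:
            imp_rows.append({"contrast": name, "feature": feat, "importance": imp})
        top = select_top_decorrelated(ranking, sub, n=config.top_n, r_max=config.r_max)
        reports.append(cv_accuracy(sub, y, top, scheme, contrast=name))
        for category in CATEGORY_SETS:
            reports.append(cv_accuracy(sub, y, _category_config(table, category), scheme, contrast=name))
    cv_summary = pd.DataFrame([r.to_row() for r in reports])
    report = CohortReport(
        table=table,
        stats=stats_df,
        importances=pd.DataFrame(imp_rows),
        cv_reports=reports,
        cv_summary=cv_summary,
    )
    _write_common(
        out,
        config,
        report,
        {
            "analysis": "cross-sectional",
            "n_interviews": int(len(table.data)),
            "correlation_clusters": [sorted(c) for c in clusters.clusters],
            "cluster_tau": config.cluster_tau,
        },
    )
    return report


LONGITUDINAL_SETS = ("demographics", "panss", "demographics+panss", "language", "top10-all")


def _longitudinal_config(table: FeatureTable, set_id: str, top: FeatureSetConfig) -> FeatureSetConfig:
    demo = tuple(table.columns_of("demographic"))
    clin = tuple(table.columns_of("clinical"))
    if set_id == "demographics":
        return FeatureSetConfig(id=set_id, columns=demo)
    if set_id == "panss":
        return FeatureSetConfig(id=set_id, columns=clin)
    if set_id == "demographics+panss":
        return FeatureSetConfig(id=set_id, columns=demo + clin)
    if set_id == "language":
        return FeatureSetConfig(id=set_id, columns=tuple(table.language_columns()))
    if set_id == "top10-all":
        return top
    raise ValueError(set_id)


def run_longitudinal(config: RunConfig) -> CohortReport:
    """Conversion prediction within FEP (C-SZ vs NC-SZ) over the
    feature-set ladder, with the case matrix and the three shallow
    interpretability trees (clinical-only, language-only, top-10)."""
    out = Path(config.out_dir)
    table, cohort = _load_table(config)
    if cohort is not None:
        conv = cohort.labels("conversion")
        mask = np.array([c is not None for c in conv])
    else:
        if "conversion" not in table.data.columns:
            raise ValueError("feature table needs a 'conversion' column when no cohort is given")
        conv = table.data["conversion"].to_numpy(dtype=object)
        mask = ~pd.isna(conv)
    sub = FeatureTable(data=table.data.loc[mask], categories=dict(table.categories))
    y = np.asarray([str(c) for c in conv[mask]], dtype=object)

    stats_df = group_stats_report(sub, y)
    # ranking over language + demographic + clinical columns combined
    all_cols = sub.language_columns() + sub.columns_of("demographic") + sub.columns_of("clinical")
    ranking = rank_features(sub, y, seed=config.seed, columns=all_cols, contrast="C-SZ_vs_NC-SZ")
    top = select_top_decorrelated(ranking, sub, n=config.top_n, r_max=config.r_max)

    scheme = config.scheme()
    folds = min(scheme.folds, int(min(np.unique(y, return_counts=True)[1])))
    scheme = CvScheme(folds=folds, repeats=scheme.repeats, seed=scheme.seed, n_estimators=scheme.n_estimators)
    reports = []
    for set_id in LONGITUDINAL_SETS:
        cfg = _longitudinal_config(sub, set_id, top)
        reports.append(cv_accuracy(sub, y, cfg, scheme, contrast="C-SZ_vs_NC-SZ"))
    for category in CATEGORY_SETS:
        reports.append(cv_accuracy(sub, y, _category_config(sub, category), scheme, contrast="C-SZ_vs_NC-SZ"))
    matrix = case_report(reports)

    trees_dir = out / "trees"
    trees_dir.mkdir(parents=True, exist_ok=True)
    tree_specs = {
        "clinical_only": _longitudinal_config(sub, "demographics+panss", top),
        "language_only": _longitudinal_config(sub, "language", top),
        "top10": top,
    }
    for name, cfg in tree_specs.items():
        tree = fit_shallow_tree(sub, y, cfg, max_depth=3, seed=config.seed)
        (trees_dir / f"{name}.txt").write_text(tree.to_text(), encoding="utf-8")
        (trees_dir / f"{name}.dot").write_text(tree.to_graph_description(), encoding="utf-8")

    report = CohortReport(
        table=sub,
        stats=stats_df,
        importances=ranking.to_frame().assign(contrast="C-SZ_vs_NC-SZ"),
        cv_reports=reports,
        cv_summary=pd.DataFrame([r.to_row() for r in reports]),
        case_matrix=matrix,
    )
    _write_common(
        out,
        config,
        report,
        {"analysis": "longitudinal", "n_interviews": int(len(sub.data)), "cv_folds_used": folds},
    )
    return report
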