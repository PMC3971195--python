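"""SVM-based feature selection, cross-validated classification, relative
gains, and the feature-distribution overlap metric.

Three diagnostic tasks are supported: the 3-class problem (controls vs mild
vs moderate-to-severe), early detection (controls vs mild) and disease
progression (mild vs moderate-to-severe).  For each task, 25% of the rows
are set aside for SVM recursive feature elimination down to the 24 most
relevant features, and the remaining 75% are classified with a polynomial
kernel SVM under stratified 10-fold cross-validation — the selection and
training pools are disjoint to avoid optimistic bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.feature_selection import RFE
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC

from .features import COMBINED_SETS, FEATURE_SETS, FeatureTable

__all__ = [
    "TaskSpec", "ClassifierConfig", "ClassificationResult",
    "EvaluationReport", "TASKS",
    "select_top_features", "crossval_classify", "relative_gain",
    "distribution_overlap", "benchmark_matrix",
]


@dataclass(frozen=True)
class TaskSpec:
    """A diagnostic classification task over group labels.

    For 2-class tasks `positive_class` designates the more impaired group
    whose recall is reported as sensitivity.
    """

    name: str
    classes: tuple[str, ...]
    positive_class: str | None = None

    def __post_init__(self) -> None:
        if len(self.classes) < 2:
            raise ValueError("a task needs at least two classes")
        if len(self.classes) == 2:
            if self.positive_class is None:
                object.__setattr__(self, "positive_class", self.classes[-1])
            if self.positive_class not in self.classes:
                raise ValueError("positive_class must be one of the classes")


TASKS: dict[str, TaskSpec] = {
    "task1": TaskSpec("task1", ("N", "AD1", "AD2")),
    "task2": TaskSpec("task2", ("N", "AD1"), positive_class="AD1"),
    "task3": TaskSpec("task3", ("AD1", "AD2"), positive_class="AD2"),
}


@dataclass(frozen=True)
class ClassifierConfig:
    """SVM selection/classification settings.

    Defaults mirror a standard polynomial-kernel SVM configuration: degree-1
    polynomial kernel, C = 1, gamma = 0.01, 10-fold stratified CV, a 25%
    selection split, and 24 selected features.
    """

    poly_degree: int = 1
    C: float = 1.0
    gamma: float = 0.01
    folds: int = 10
    selection_fraction: float = 0.25
    n_selected: int = 24
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be at least 2")
        if not 0 < self.selection_fraction < 1:
            raise ValueError("selection_fraction must be in (0, 1)")
        if self.n_selected < 1:
            raise ValueError("n_selected must be at least 1")


@dataclass
class ClassificationResult:
    task: str
    accuracy: float                    # percent
    sensitivity: float | None          # percent, 2-class only
    specificity: float | None
    selected_features: list[str]
    fold_accuracies: list[float]
    n_rows: int

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "selected_features": list(self.selected_features),
            "fold_accuracies": list(self.fold_accuracies),
            "n_rows": self.n_rows,
        }


def _task_rows(table: FeatureTable, task: TaskSpec) -> tuple[np.ndarray,
                                                             np.ndarray]:
    mask = table.meta["group"].isin(task.classes).to_numpy()
    X = table.values.to_numpy(dtype=np.float64)[mask]
    y = table.meta["group"].to_numpy()[mask]
    return X, y


def _split_selection(X: np.ndarray, y: np.ndarray,
                     cfg: ClassifierConfig) -> tuple:
    """Stratified disjoint split into (selection, cv-pool) rows."""
    idx = np.arange(len(y))
    sel_idx, cv_idx = train_test_split(
        idx, train_size=cfg.selection_fraction, stratify=y,
        random_state=cfg.seed, shuffle=True)
    return np.sort(sel_idx), np.sort(cv_idx)


def select_top_features(table: FeatureTable, task: TaskSpec,
                        cfg: ClassifierConfig = ClassifierConfig()
                        ) -> list[str]:
    """Rank features on the 25% selection split and return the top 24.

    Recursive feature elimination with a linear-kernel maximum-margin
    classifier: features are repeatedly dropped by smallest squared weight
    until `n_selected` remain.  Deterministic given the seed; ties resolve
    toward the canonical column order.
    """
    X, y = _task_rows(table, task)
    if len(set(y)) < 2:
        raise ValueError("task classes missing from the table")
    cols = np.array(table.values.columns)
    if len(cols) < cfg.n_selected:
        raise ValueError(f"table has {len(cols)} columns, fewer than "
                         f"n_selected = {cfg.n_selected}")
    sel_idx, _ = _split_selection(X, y, cfg)
    Xs, ys = X[sel_idx], y[sel_idx]
    if len(set(ys)) < len(set(y)):
        raise ValueError("a class is absent from the selection split")
    Xs = MinMaxScaler().fit_transform(Xs)
    est = SVC(kernel="linear", C=cfg.C)
    rfe = RFE(est, n_features_to_select=cfg.n_selected, step=0.1)
    rfe.fit(Xs, ys)
    chosen = cols[rfe.support_]
    return list(chosen)


def crossval_classify(table: FeatureTable, task: TaskSpec,
                      selected: list[str],
                      cfg: ClassifierConfig = ClassifierConfig()
                      ) -> ClassificationResult:
    """Stratified k-fold CV of the polynomial-kernel SVM on the 75% pool.

    Min-max scaling is fit on each fold's training rows only.  Accuracy is
    pooled correct over total; for 2-class tasks sensitivity is the recall
    of the positive (more impaired) class and specificity the recall of the
    other.
    """
    X, y = _task_rows(table, task)
    cols = list(table.values.columns)
    col_idx = [cols.index(c) for c in selected]
    _, cv_idx = _split_selection(X, y, cfg)
    Xp, yp = X[cv_idx][:, col_idx], y[cv_idx]

    folds = cfg.folds
    class_counts = pd.Series(yp).value_counts()
    if class_counts.min() < folds:
        import warnings
        folds = max(int(class_counts.min()), 2)
        warnings.warn(f"reducing folds to {folds}: smallest class has "
                      f"{class_counts.min()} rows")
    skf = StratifiedKFold(n_splits=folds, shuffle=True,
                          random_state=cfg.seed)
    y_true, y_pred, fold_acc = [], [], []
    for tr, te in skf.split(Xp, yp):
        scaler = MinMaxScaler().fit(Xp[tr])
        # For the degree-1 kernel gamma is mathematically a pure rescaling
        # of C (gamma*K with cost C == K with cost gamma*C) and in that
        # regime every sample hits the dual bound, leaving the intercept
        # numerically ill-determined; the reference polynomial kernel is the
        # plain dot product, so gamma shapes the kernel only at degree >= 2.
        gamma = cfg.gamma if cfg.poly_degree > 1 else 1.0
        clf = SVC(kernel="poly", degree=cfg.poly_degree, C=cfg.C,
                  gamma=gamma, coef0=0.0,
                  decision_function_shape="ovo")
        clf.fit(scaler.transform(Xp[tr]), yp[tr])
        pred = clf.predict(scaler.transform(Xp[te]))
        y_true.append(yp[te])
        y_pred.append(pred)
        fold_acc.append(100.0 * float(np.mean(pred == yp[te])))
    y_true = np.concatenate(y_true)
    y_pred = np.concatenate(y_pred)
    accuracy = 100.0 * float(np.mean(y_pred == y_true))

    sensitivity = specificity = None
    if len(task.classes) == 2:
        pos = task.positive_class
        neg = [c for c in task.classes if c != pos][0]
        pos_mask, neg_mask = y_true == pos, y_true == neg
        sensitivity = 100.0 * float(np.mean(y_pred[pos_mask] == pos)) \
            if pos_mask.any() else float("nan")
        specificity = 100.0 * float(np.mean(y_pred[neg_mask] == neg)) \
            if neg_mask.any() else float("nan")
    return ClassificationResult(task=task.name, accuracy=accuracy,
                                sensitivity=sensitivity,
                                specificity=specificity,
                                selected_features=list(selected),
                                fold_accuracies=fold_acc, n_rows=len(yp))


def relative_gain(perf_aar: float, perf_base: float) -> float:
    """Percent change of a performance metric relative to the raw baseline:
    (perf_aar - perf_base) / perf_base x 100."""
    if perf_base <= 0:
        raise ValueError("baseline performance must be positive")
    return (perf_aar - perf_base) / perf_base * 100.0


def distribution_overlap(values_before, values_after,
                         n_bins: int = 50) -> float:
    """Histogram overlap of a feature before and after artifact removal,
    in percent.

    Both samples are histogrammed on a common equal-width grid spanning the
    pooled range; the overlap is the summed bin-wise minimum of the two
    normalized histograms.  100 means no change in the feature's
    distribution, 0 a complete change; values above 80 are conventionally
    treated as irrelevant changes.
    """
    a = np.asarray(values_before, dtype=np.float64).ravel()
    b = np.asarray(values_after, dtype=np.float64).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if lo == hi:
        return 100.0
    edges = np.linspace(lo, hi, n_bins + 1)
    pa, _ = np.histogram(a, bins=edges)
    pb, _ = np.histogram(b, bins=edges)
    pa = pa / pa.sum()
    pb = pb / pb.sum()
    return float(np.minimum(pa, pb).sum() * 100.0)


@dataclass
class EvaluationReport:
    """Benchmark results across tasks, feature sets and AAR methods.

    `baseline` maps (task, feature_set) to the raw-data ClassificationResult;
    `results` maps (task, feature_set, method) to results after artifact
    removal; `gains` holds the corresponding relative gains in percent and
    `overlaps` the per-feature distribution-overlap percentages for the
    wICA-selected features.
    """

    baseline: dict = field(default_factory=dict)
    results: dict = field(default_factory=dict)
    gains: dict = field(default_factory=dict)
    overlaps: dict = field(default_factory=dict)

    def gain_table(self, task: str) -> pd.DataFrame:
        """Relative-gain matrix (methods x feature sets) for one task."""
        sets = list(FEATURE_SETS) + list(COMBINED_SETS)
        methods = sorted({m for (t, s, m) in self.gains if t == task})
        data = {s: [self.gains.get((task, s, m), np.nan) for m in methods]
                for s in sets}
        return pd.DataFrame(data, index=methods)

    def to_dict(self) -> dict:
        return {
            "baseline": {f"{t}|{s}": r.to_dict()
                         for (t, s), r in self.baseline.items()},
            "results": {f"{t}|{s}|{m}": r.to_dict()
                        for (t, s, m), r in self.results.items()},
            "gains": {f"{t}|{s}|{m}": g
                      for (t, s, m), g in self.gains.items()},
            "overlaps": {f"{t}|{f2}": v
                         for (t, f2), v in self.overlaps.items()},
        }


def benchmark_matrix(tables: dict[str, FeatureTable],
                     tasks: list[str] | None = None,
                     feature_sets: list[str] | None = None,
                     cfg: ClassifierConfig = ClassifierConfig()
                     ) -> EvaluationReport:
    """Run selection + CV for every task x feature set x AAR method.

    `tables` maps method names to feature tables and must contain the
    ``"none"`` baseline.  Gains are computed against the baseline accuracy;
    distribution overlaps compare each wICA-selected feature between the
    baseline and wICA tables.
    """
    if "none" not in tables:
        raise ValueError('tables must include the "none" baseline')
    tasks = tasks or list(TASKS)
    feature_sets = feature_sets or (list(FEATURE_SETS) + list(COMBINED_SETS))
    report = EvaluationReport()

    for tname in tasks:
        task = TASKS[tname]
        for fset in feature_sets:
            base_sub = tables["none"].restrict(fset)
            selected = select_top_features(base_sub, task, cfg)
            base_res = crossval_classify(base_sub, task, selected, cfg)
            report.baseline[(tname, fset)] = base_res
            for method, tab in tables.items():
                if method == "none":
                    continue
                sub = tab.restrict(fset)
                sel_m = select_top_features(sub, task, cfg)
                res = crossval_classify(sub, task, sel_m, cfg)
                report.results[(tname, fset, method)] = res
                report.gains[(tname, fset, method)] = relative_gain(
                    res.accuracy, base_res.accuracy)

        if "wICA" in tables:
            wica_sub = tables["wICA"].restrict("All")
            sel_w = select_top_features(wica_sub, task, cfg)
            for feat in sel_w:
                before = tables["none"].values[feat].to_numpy()
                after = tables["wICA"].values[feat].to_numpy()
                report.overlaps[(tname, feat)] = distribution_overlap(
                    before, after)
    return report
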