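"""Class balancing, classifier tuning and stratified cross-validated evaluation.

Eight classifier families are supported: k-nearest neighbours (KNN),
linear discriminant analysis (LDA), support vector machine (SVM), random
forest (RF), extra trees (ET), logistic regression (LR), Gaussian naive
Bayes (NB) and quadratic discriminant analysis (QDA).  Each family has a
small fixed default hyperparameter grid; tuning draws a stratified 10%
subset of the balanced data, splits it 80/20 (stratified), and picks the
grid point with the best weighted F-score on the 20% portion.  The tuned
model is then assessed by 10-fold stratified cross-validation with
per-class precision/recall/F-scores and a fold-averaged, row-normalized
confusion matrix.

All randomness flows from one master seed: stage seeds are derived with
``numpy.random.SeedSequence([master, length_index, family_index, stage])``
so every report is exactly reproducible from the logged configuration.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .features import FilterSpec, featurize_dataset
from .io_formats import ValidationError, feature_columns
from .selection import (
    DEFAULT_R_THRESHOLD,
    DEFAULT_VAR_THRESHOLD,
    SelectionReport,
    apply_selection,
    fit_selection,
)
from .windowing import DEFAULT_WINDOW_LENGTHS, MERGED_LABELS, WindowedDataset

FAMILIES = ("KNN", "LDA", "SVM", "RF", "ET", "LR", "NB", "QDA")

#: Default hyperparameter grids, expanded in a fixed order (ties in the
#: tuning score resolve to the earlier grid point).
DEFAULT_GRIDS: dict[str, list[dict]] = {
    "KNN": [{"n_neighbors": k} for k in (1, 3, 5, 9, 15)],
    "LDA": [{}],
    "SVM": [
        {"C": c, "kernel": k}
        for c, k in itertools.product((0.1, 1.0, 10.0), ("rbf", "linear"))
    ],
    "RF": [
        {"n_estimators": 100, "max_depth": None},
        {"n_estimators": 100, "max_depth": 10},
    ],
    "ET": [
        {"n_estimators": 100, "max_depth": None},
        {"n_estimators": 100, "max_depth": 10},
    ],
    "LR": [{"C": c} for c in (0.1, 1.0, 10.0)],
    "NB": [{}],
    "QDA": [{"reg_param": r} for r in (0.0, 0.01, 0.1)],
}


def stage_seed(master: int, *key: int) -> int:
    """Derive a sub-2^31 stage seed from the master seed and an index key."""
    ss = np.random.SeedSequence([int(master), *[int(k) for k in key]])
    return int(ss.generate_state(1)[0] % 2**31)


@dataclass(frozen=True)
class ModelSpec:
    """A classifier family with pinned hyperparameters and seed."""

    family: str
    hyperparameters: dict = field(default_factory=dict)
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValidationError(
                f"unknown family {self.family!r}; expected one of {FAMILIES}"
            )


def build_estimator(spec: ModelSpec):
    """Instantiate the scikit-learn estimator a ModelSpec describes."""
    hp = dict(spec.hyperparameters)
    if spec.family == "KNN":
        return KNeighborsClassifier(**hp)
    if spec.family == "LDA":
        return LinearDiscriminantAnalysis(**hp)
    if spec.family == "SVM":
        return SVC(random_state=spec.random_seed, **hp)
    if spec.family == "RF":
        return RandomForestClassifier(random_state=spec.random_seed, n_jobs=1, **hp)
    if spec.family == "ET":
        return ExtraTreesClassifier(random_state=spec.random_seed, n_jobs=1, **hp)
    if spec.family == "LR":
        return LogisticRegression(max_iter=2000, **hp)
    if spec.family == "NB":
        return GaussianNB(**hp)
    if spec.family == "QDA":
        return QuadraticDiscriminantAnalysis(**hp)
    raise ValidationError(f"unknown family {spec.family!r}")


def balance_classes(matrix: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Downsample every class to the minority count, then shuffle (seeded)."""
    counts = matrix["label"].value_counts()
    absent = [c for c in MERGED_LABELS if c not in counts.index]
    if absent:
        raise ValidationError(f"cannot balance: class(es) with 0 rows: {absent}")
    n_min = int(counts.min())
    rng = np.random.default_rng(seed)
    kept_idx: list[np.ndarray] = []
    for label in MERGED_LABELS:
        idx = matrix.index[matrix["label"] == label].to_numpy()
        kept_idx.append(rng.choice(idx, size=n_min, replace=False))
    all_idx = np.concatenate(kept_idx)
    all_idx = all_idx[rng.permutation(len(all_idx))]
    return matrix.loc[all_idx].reset_index(drop=True)


def f_scores(true_labels, predicted_labels, labels=MERGED_LABELS) -> dict:
    """Per-class precision/recall/F and the support-weighted average F.

    F is 0 when precision + recall is 0; a class with zero support
    contributes nothing to the weighted average.
    """
    y_true = np.asarray(true_labels)
    y_pred = np.asarray(predicted_labels)
    if len(y_true) != len(y_pred):
        raise ValidationError(
            f"label vectors differ in length: {len(y_true)} vs {len(y_pred)}"
        )
    if len(y_true) == 0:
        raise ValidationError("empty label vectors")
    per_class = {}
    n = len(y_true)
    weighted = 0.0
    for c in labels:
        tp = int(np.sum((y_true == c) & (y_pred == c)))
        fp = int(np.sum((y_true != c) & (y_pred == c)))
        fn = int(np.sum((y_true == c) & (y_pred != c)))
        support = tp + fn
        precision = tp / (tp + fp) if tp + fp > 0 else 0.0
        recall = tp / (tp + fn) if tp + fn > 0 else 0.0
        f = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
        per_class[c] = {
            "precision": precision,
            "recall": recall,
            "f": f,
            "support": support,
        }
        weighted += support / n * f
    return {"per_class": per_class, "weighted_f": weighted}


def confusion_counts(true_labels, predicted_labels, labels=MERGED_LABELS) -> np.ndarray:
    y_true = np.asarray(true_labels)
    y_pred = np.asarray(predicted_labels)
    mat = np.zeros((len(labels), len(labels)))
    for i, ci in enumerate(labels):
        for j, cj in enumerate(labels):
            mat[i, j] = np.sum((y_true == ci) & (y_pred == cj))
    return mat


def confusion(true_labels, predicted_labels, labels=MERGED_LABELS) -> pd.DataFrame:
    """Row-normalized confusion matrix in percent (rows = true class).

    A true class absent from the input yields a row of NaN — undefined,
    never silently zero.
    """
    if len(np.asarray(true_labels)) == 0:
        raise ValidationError("empty label vectors")
    mat = confusion_counts(true_labels, predicted_labels, labels)
    row_sums = mat.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = 100.0 * mat / row_sums
    norm[row_sums[:, 0] == 0] = np.nan
    return pd.DataFrame(norm, index=list(labels), columns=list(labels))


@dataclass
class EvaluationReport:
    """Cross-validated performance of one model on one windowed dataset."""

    spec: ModelSpec
    window_length: float
    per_class_f: dict[str, float]
    per_class_precision: dict[str, float]
    per_class_recall: dict[str, float]
    weighted_f: float
    per_fold: list[dict]
    confusion_matrix: pd.DataFrame  # fold-averaged, row-normalized percent
    supports: dict[str, int]
    n_samples: int
    n_features: int
    selection: SelectionReport | None = None

    def to_dict(self) -> dict:
        return {
            "family": self.spec.family,
            "hyperparameters": self.spec.hyperparameters,
            "random_seed": self.spec.random_seed,
            "window_length_s": self.window_length,
            "per_class_f": self.per_class_f,
            "per_class_precision": self.per_class_precision,
            "per_class_recall": self.per_class_recall,
            "weighted_f": self.weighted_f,
            "per_fold": self.per_fold,
            "confusion_matrix_percent": {
                "labels": list(self.confusion_matrix.index),
                "rows": [
                    [round(v, 6) for v in row]
                    for row in self.confusion_matrix.to_numpy().tolist()
                ],
            },
            "supports": self.supports,
            "n_samples": self.n_samples,
            "n_features": self.n_features,
            "selection": self.selection.to_dict() if self.selection else None,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def tune(
    matrix: pd.DataFrame,
    family: str,
    grid: list[dict] | None = None,
    seed: int = 0,
    tuning_fraction: float = 0.10,
    selection_thresholds: tuple[float, float] | None = None,
) -> ModelSpec:
    """Pick the best grid point on a stratified 10% subset, split 80/20.

    When ``selection_thresholds`` (r, var) is given, scaling/pruning is
    fitted on the 80% portion only (leakage-safe); otherwise the matrix
    is assumed already selected.
    """
    if grid is None:
        grid = DEFAULT_GRIDS[family]
    if not grid:
        raise ValidationError("hyperparameter grid is empty")
    y = matrix["label"].to_numpy()
    counts = pd.Series(y).value_counts()
    min_subset = (counts * tuning_fraction).apply(np.floor)
    if (min_subset < 2).any():
        small = sorted(counts.index[min_subset < 2])
        raise ValidationError(
            f"class(es) {small} would have < 2 members in the "
            f"{tuning_fraction:.0%} tuning subset; use a larger fraction"
        )
    try:
        subset, _ = train_test_split(
            matrix, train_size=tuning_fraction, stratify=y,
            random_state=seed % 2**31,
        )
        train, test = train_test_split(
            subset,
            train_size=0.8,
            stratify=subset["label"],
            random_state=(seed + 1) % 2**31,
        )
    except ValueError as exc:
        raise ValidationError(
            f"the {tuning_fraction:.0%} tuning subset is too small for a "
            f"stratified 80/20 split; use a larger fraction ({exc})"
        ) from exc
    if selection_thresholds is not None:
        r_thr, var_thr = selection_thresholds
        train, rep = fit_selection(train, r_thr, var_thr)
        test = apply_selection(test, rep)
    feats = feature_columns(train)
    best_spec: ModelSpec | None = None
    best_f = -1.0
    for hp in grid:
        spec = ModelSpec(family=family, hyperparameters=hp, random_seed=seed)
        est = build_estimator(spec)
        est.fit(train[feats].to_numpy(), train["label"].to_numpy())
        pred = est.predict(test[feats].to_numpy())
        f = f_scores(test["label"].to_numpy(), pred)["weighted_f"]
        if f > best_f:  # strict: ties keep the earlier grid point
            best_f = f
            best_spec = spec
    assert best_spec is not None
    return best_spec


def cross_validate(
    matrix: pd.DataFrame,
    spec: ModelSpec,
    k: int = 10,
    seed: int = 0,
    selection_thresholds: tuple[float, float] | None = None,
) -> EvaluationReport:
    """k-fold stratified cross-validation of one ModelSpec.

    Per fold, the model is fitted on k-1 folds and scored on the held-out
    fold.  Reported per-class metrics are fold means; the weighted F is
    the support-weighted mean of the fold-averaged class Fs; the
    confusion matrix is the row-normalized mean of the per-fold count
    matrices.  With ``selection_thresholds`` the scaling/pruning is
    refitted inside every training fold (leakage-safe mode).
    """
    y = matrix["label"].to_numpy()
    counts = pd.Series(y).value_counts()
    if (counts < k).any():
        small = sorted(counts.index[counts < k])
        raise ValidationError(f"class(es) {small} have fewer than k={k} rows")
    window_length = (
        float(matrix["window_length_s"].iloc[0])
        if "window_length_s" in matrix.columns
        else float("nan")
    )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % 2**31)
    fold_metrics: list[dict] = []
    count_mats = []
    selection_report: SelectionReport | None = None
    for fold_i, (tr, te) in enumerate(skf.split(matrix, y)):
        train = matrix.iloc[tr]
        test = matrix.iloc[te]
        if selection_thresholds is not None:
            r_thr, var_thr = selection_thresholds
            train, selection_report = fit_selection(train, r_thr, var_thr)
            test = apply_selection(test, selection_report)
        feats = feature_columns(train)
        est = build_estimator(spec)
        est.fit(train[feats].to_numpy(), train["label"].to_numpy())
        pred = est.predict(test[feats].to_numpy())
        scores = f_scores(test["label"].to_numpy(), pred)
        fold_metrics.append({"fold": fold_i, **scores})
        count_mats.append(confusion_counts(test["label"].to_numpy(), pred))
    per_class_f = {
        c: float(np.mean([m["per_class"][c]["f"] for m in fold_metrics]))
        for c in MERGED_LABELS
    }
    per_class_p = {
        c: float(np.mean([m["per_class"][c]["precision"] for m in fold_metrics]))
        for c in MERGED_LABELS
    }
    per_class_r = {
        c: float(np.mean([m["per_class"][c]["recall"] for m in fold_metrics]))
        for c in MERGED_LABELS
    }
    supports = {c: int(np.sum(y == c)) for c in MERGED_LABELS}
    n = len(y)
    weighted_f = sum(supports[c] / n * per_class_f[c] for c in MERGED_LABELS)
    mean_counts = np.mean(count_mats, axis=0)
    row_sums = mean_counts.sum(axis=1, keepdims=True)
    conf = pd.DataFrame(
        100.0 * mean_counts / row_sums,
        index=list(MERGED_LABELS),
        columns=list(MERGED_LABELS),
    )
    n_features = len(feature_columns(matrix if selection_thresholds is None else train))
    return EvaluationReport(
        spec=spec,
        window_length=window_length,
        per_class_f=per_class_f,
        per_class_precision=per_class_p,
        per_class_recall=per_class_r,
        weighted_f=float(weighted_f),
        per_fold=fold_metrics,
        confusion_matrix=conf,
        supports=supports,
        n_samples=n,
        n_features=n_features,
        selection=selection_report,
    )


@dataclass
class ExperimentConfig:
    """Every knob of the full pipeline, with the study defaults."""

    window_lengths: tuple[float, ...] = DEFAULT_WINDOW_LENGTHS
    overlap_fraction: float = 0.5
    filter_order: int = 4
    filter_cutoff: float = 5.0
    r_threshold: float = DEFAULT_R_THRESHOLD
    var_threshold: float = DEFAULT_VAR_THRESHOLD
    families: tuple[str, ...] = FAMILIES
    k_folds: int = 10
    tuning_fraction: float = 0.10
    truncate_days: float = 3.0
    master_seed: int = 0
    leakage_safe: bool = False
    grids: dict[str, list[dict]] = field(default_factory=lambda: dict(DEFAULT_GRIDS))

    def __post_init__(self) -> None:
        unknown = [f for f in self.families if f not in FAMILIES]
        if unknown:
            raise ValidationError(
                f"unknown classifier family/families {unknown}; allowed: {FAMILIES}"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["window_lengths"] = list(self.window_lengths)
        d["families"] = list(self.families)
        return d


def evaluate_dataset(
    dataset: WindowedDataset,
    family: str,
    config: ExperimentConfig,
    length_index: int = 0,
    family_index: int = 0,
) -> EvaluationReport:
    """Featurize → select → balance → tune → cross-validate one dataset."""
    spec = FilterSpec(
        order=config.filter_order,
        cutoff=config.filter_cutoff,
        sample_rate=dataset.sample_rate,
    )
    features = featurize_dataset(dataset, spec)
    thresholds = (config.r_threshold, config.var_threshold)
    if config.leakage_safe:
        matrix = features
        sel_thr = thresholds
        selection_report = None
    else:
        matrix, selection_report = fit_selection(features, *thresholds)
        sel_thr = None
    bal_seed = stage_seed(config.master_seed, length_index, family_index, 0)
    balanced = balance_classes(matrix, bal_seed)
    tune_seed = stage_seed(config.master_seed, length_index, family_index, 1)
    best = tune(
        balanced,
        family,
        grid=config.grids.get(family, DEFAULT_GRIDS[family]),
        seed=tune_seed,
        tuning_fraction=config.tuning_fraction,
        selection_thresholds=sel_thr,
    )
    cv_seed = stage_seed(config.master_seed, length_index, family_index, 2)
    report = cross_validate(
        balanced, best, k=config.k_folds, seed=cv_seed, selection_thresholds=sel_thr
    )
    if report.selection is None:
        report.selection = selection_report
    return report


def run_experiment(
    datasets: list[WindowedDataset],
    families=None,
    config: ExperimentConfig | None = None,
) -> list[EvaluationReport]:
    """The full sweep: one report per (window length, classifier family)."""
    if config is None:
        config = ExperimentConfig()
    if families is None:
        families = config.families
    if not datasets or not families:
        raise ValidationError("need at least one dataset and one family")
    reports = []
    for li, ds in enumerate(datasets):
        for fi, fam in enumerate(families):
            try:
                reports.append(evaluate_dataset(ds, fam, config, li, fi))
            except ValidationError as exc:
                raise ValidationError(
                    f"(window length {ds.window_length} s, family {fam}): {exc}"
                ) from exc
    return reports


def f_table(reports: list[EvaluationReport]) -> pd.DataFrame:
    """Weighted-F vs window-length table (families as rows)."""
    rows: dict[str, dict[float, float]] = {}
    for r in reports:
        rows.setdefault(r.spec.family, {})[r.window_length] = r.weighted_f
    df = pd.DataFrame(rows).T
    return df[sorted(df.columns)]


def per_class_table(reports: list[EvaluationReport], window_length: float) -> pd.DataFrame:
    """Per-class F plus weighted F for every family at one window length."""
    rows = {}
    for r in reports:
        if r.window_length == window_length:
            rows[r.spec.family] = {
                **{c: r.per_class_f[c] for c in MERGED_LABELS},
                "weighted_f": r.weighted_f,
            }
    return pd.DataFrame(rows).T
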