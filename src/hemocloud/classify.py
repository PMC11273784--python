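"""Feature groups, cross-validated classifier benchmarking and metrics.

Feature groups follow the A / B1–B4 design: Group A is the tabular block
(geometry + hemodynamics); Groups B1–B4 append 1024-, 64-, 32- and
16-dimensional cloud features from the point-cloud extractor.  Five
algorithms are benchmarked — XGBoost, LightGBM, histogram gradient boosting
(scikit-learn), an RBF-kernel SVM with calibrated probabilities, and logistic
regression — under seeded stratified k-fold cross-validation (10 folds by
default; the 40/149 class imbalance makes unstratified folds fragile).

Leakage control: within each fold, normalisation statistics and (for Group B)
the extractor itself are fit on the training folds only.  Out-of-fold scores
are pooled and metrics computed once on the pooled predictions; the positive
class is *ruptured*.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .io import get_logger
from .pointnet import (
    CHANNEL_PRESETS,
    ExtractorConfig,
    extract_features,
    sample_input_points,
    train_extractor,
)
from .types import HemodynamicCloud, ValidationError

logger = get_logger()

#: group id -> cloud-feature dimension (None = tabular only)
GROUP_DIMS: dict[str, int | None] = {"A": None, "B1": 1024, "B2": 64, "B3": 32, "B4": 16}

ALGORITHMS = ("XGBoost", "HistGB", "SVM", "LightGBM", "LR")


@dataclass
class MetricsRecord:
    algorithm: str
    group: str
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    roc: np.ndarray  # (k, 2) columns fpr, tpr
    fold_assignments: np.ndarray
    seed: int

    def validate(self) -> "MetricsRecord":
        for name in ("accuracy", "sensitivity", "specificity", "auc"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValidationError(f"{name} outside [0, 1]")
        fpr = self.roc[:, 0]
        if not (self.roc[0] == [0.0, 0.0]).all() or not (self.roc[-1] == [1.0, 1.0]).all():
            raise ValidationError("ROC must run from (0,0) to (1,1)")
        if (np.diff(fpr) < 0).any():
            raise ValidationError("ROC FPR must be nondecreasing")
        return self


# ---------------------------------------------------------------------------
# metrics


def roc_points(y_true: np.ndarray, y_score: np.ndarray) -> np.ndarray:
    """ROC polygon from pooled scores; ties are grouped (midrank convention)."""
    y_true = np.asarray(y_true, dtype=int)
    y_score = np.asarray(y_score, dtype=float)
    n_pos = int(y_true.sum())
    n_neg = len(y_true) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both classes required for a ROC curve")
    order = np.argsort(-y_score, kind="stable")
    sorted_scores = y_score[order]
    sorted_true = y_true[order]
    tp = np.cumsum(sorted_true)
    fp = np.cumsum(1 - sorted_true)
    # keep only the last point of each tied-score run
    distinct = np.r_[np.diff(sorted_scores) != 0, True]
    tpr = np.r_[0.0, tp[distinct] / n_pos]
    fpr = np.r_[0.0, fp[distinct] / n_neg]
    return np.column_stack([fpr, tpr])


def auc_from_roc(roc: np.ndarray) -> float:
    """Trapezoid area under the ROC polygon."""
    return float(np.trapezoid(roc[:, 1], roc[:, 0]))


def compute_metrics(
    y_true: np.ndarray, y_score: np.ndarray, threshold: float = 0.5
) -> dict[str, float]:
    """Accuracy / sensitivity / specificity at a fixed threshold, plus trapezoidal AUC.

    Sensitivity is the true-positive rate on ruptured cases (label 1),
    specificity the true-negative rate on unruptured ones.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_score = np.asarray(y_score, dtype=float)
    if len(np.unique(y_true)) < 2:
        raise ValidationError("both classes required")
    pred = (y_score >= threshold).astype(int)
    tp = int(((pred == 1) & (y_true == 1)).sum())
    tn = int(((pred == 0) & (y_true == 0)).sum())
    fp = int(((pred == 1) & (y_true == 0)).sum())
    fn = int(((pred == 0) & (y_true == 1)).sum())
    roc = roc_points(y_true, y_score)
    return {
        "accuracy": (tp + tn) / len(y_true),
        "sensitivity": tp / (tp + fn),
        "specificity": tn / (tn + fp),
        "auc": auc_from_roc(roc),
    }


def normalize_features(
    train: np.ndarray, test: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None]:
    """Z-score with training-fold statistics; constant columns map to zero."""
    train = np.asarray(train, dtype=float)
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    safe = np.where(sd > 0, sd, 1.0)
    train_z = np.where(sd > 0, (train - mu) / safe, 0.0)
    if test is None:
        return train_z, None
    test = np.asarray(test, dtype=float)
    test_z = np.where(sd > 0, (test - mu) / safe, 0.0)
    return train_z, test_z


# ---------------------------------------------------------------------------
# classifiers


def make_classifier(name: str, seed: int):
    """Library defaults with a fixed seed; the benchmark tunes nothing."""
    if name == "XGBoost":
        from xgboost import XGBClassifier

        return XGBClassifier(
            random_state=seed, n_jobs=1, eval_metric="logloss", verbosity=0
        )
    if name == "LightGBM":
        from lightgbm import LGBMClassifier

        return LGBMClassifier(random_state=seed, n_jobs=1, verbose=-1)
    if name == "HistGB":
        from sklearn.ensemble import HistGradientBoostingClassifier

        return HistGradientBoostingClassifier(random_state=seed)
    if name == "SVM":
        from sklearn.calibration import CalibratedClassifierCV
        from sklearn.svm import SVC

        # RBF-kernel SVM with Platt-style sigmoid calibration for probability scores
        return CalibratedClassifierCV(
            SVC(kernel="rbf", random_state=seed), method="sigmoid", ensemble=False, cv=3
        )
    if name == "LR":
        from sklearn.linear_model import LogisticRegression

        return LogisticRegression(max_iter=2000, random_state=seed)
    raise ValidationError(f"unknown algorithm {name!r}")


def _predict_proba(clf, X: np.ndarray) -> np.ndarray:
    """Positive-class scores; silences LightGBM's spurious feature-name warning."""
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="X does not have valid feature names"
        )
        return clf.predict_proba(X)[:, 1]


# ---------------------------------------------------------------------------
# feature assembly


def assemble_feature_group(
    tabular: pd.DataFrame,
    cloud_features: pd.DataFrame | None,
    group: str,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Design matrix + labels for one group; rows aligned by case_id.

    Column order: geometry block, hemodynamics block (as stored in the
    parameter table), then the cloud-feature block.
    """
    if group not in GROUP_DIMS:
        raise ValidationError(f"unknown group {group!r}")
    dim = GROUP_DIMS[group]
    feature_cols = [c for c in tabular.columns if c not in ("case_id", "label")]
    X = tabular[feature_cols].to_numpy(dtype=float)
    y = tabular["label"].to_numpy(dtype=int)
    cols = list(feature_cols)
    if dim is not None:
        if cloud_features is None:
            raise ValidationError(f"group {group} requires cloud features")
        missing = set(tabular["case_id"]) - set(cloud_features["case_id"])
        if missing:
            raise ValidationError(f"cases missing cloud features: {sorted(missing)[:5]}")
        feat_cols = [c for c in cloud_features.columns if c.startswith("f")]
        if len(feat_cols) != dim:
            raise ValidationError(
                f"group {group} expects {dim}-dimensional cloud features, got {len(feat_cols)}"
            )
        aligned = (
            cloud_features.set_index("case_id").loc[tabular["case_id"], feat_cols]
        )
        X = np.column_stack([X, aligned.to_numpy(dtype=float)])
        cols += feat_cols
    return X, y, cols


def cloud_features_frame(vectors) -> pd.DataFrame:
    """CloudFeatureVector list -> DataFrame (case_id, f1..fC4)."""
    rows = []
    for vec in vectors:
        row = {"case_id": vec.case_id}
        row.update({f"f{i + 1}": v for i, v in enumerate(vec.values)})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cross-validation


def _stratified_splits(y: np.ndarray, folds: int, seed: int):
    y = np.asarray(y, dtype=int)
    counts = np.bincount(y, minlength=2)
    if (counts == 0).any():
        raise ValidationError("both classes required for stratified CV")
    if folds > counts.min():
        raise ValidationError(
            f"folds ({folds}) exceeds minority class count ({counts.min()})"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


def run_cv(
    X: np.ndarray,
    y: np.ndarray,
    algorithm: str,
    folds: int = 10,
    seed: int = 0,
    group: str = "A",
    threshold: float = 0.5,
) -> MetricsRecord:
    """Stratified k-fold CV on a fixed design matrix; pooled out-of-fold scoring."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    splits = _stratified_splits(y, folds, seed)
    scores = np.full(len(y), np.nan)
    fold_of = np.full(len(y), -1)
    for k, (train_idx, test_idx) in enumerate(splits):
        Xtr, Xte = normalize_features(X[train_idx], X[test_idx])
        clf = make_classifier(algorithm, seed)
        clf.fit(Xtr, y[train_idx])
        scores[test_idx] = _predict_proba(clf, Xte)
        fold_of[test_idx] = k
    assert not np.isnan(scores).any(), "every case must be scored exactly once"
    metrics = compute_metrics(y, scores, threshold=threshold)
    return MetricsRecord(
        algorithm=algorithm, group=group, roc=roc_points(y, scores),
        fold_assignments=fold_of, seed=seed, **metrics,
    ).validate()


def run_group_cv(
    tabular: pd.DataFrame,
    clouds: list[HemodynamicCloud] | None,
    group: str,
    algorithms: tuple[str, ...] = ALGORITHMS,
    extractor_config: ExtractorConfig | None = None,
    folds: int = 10,
    seed: int = 0,
    threshold: float = 0.5,
) -> list[MetricsRecord]:
    """CV for one feature group, sharing per-fold extractor training across algorithms.

    For Group B the extractor is trained on the training folds of each split
    only, then used to embed every case of that split; this keeps the learned
    cloud features free of test-fold leakage.
    """
    y = tabular["label"].to_numpy(dtype=int)
    splits = _stratified_splits(y, folds, seed)
    dim = GROUP_DIMS[group]
    fold_matrices = []
    for k, (train_idx, test_idx) in enumerate(splits):
        if dim is None:
            X, _, _ = assemble_feature_group(tabular, None, group)
        else:
            if clouds is None:
                raise ValidationError(f"group {group} requires clouds")
            cfg = extractor_config or ExtractorConfig(channels=CHANNEL_PRESETS[dim])
            if cfg.channels[3] != dim:
                cfg = dataclasses.replace(cfg, channels=CHANNEL_PRESETS[dim])
            fold_cfg = dataclasses.replace(cfg, seed=cfg.seed + 1000 * k)
            net = train_extractor(
                [clouds[i] for i in train_idx], y[train_idx], fold_cfg
            )
            rng = np.random.default_rng(fold_cfg.seed + 1)
            vectors = [
                extract_features(
                    c, net,
                    points=sample_input_points(c, fold_cfg.n_input_points, rng),
                )
                for c in clouds
            ]
            X, _, _ = assemble_feature_group(
                tabular, cloud_features_frame(vectors), group
            )
        fold_matrices.append((train_idx, test_idx, X))

    records = []
    for algorithm in algorithms:
        scores = np.full(len(y), np.nan)
        fold_of = np.full(len(y), -1)
        for k, (train_idx, test_idx, X) in enumerate(fold_matrices):
            Xtr, Xte = normalize_features(X[train_idx], X[test_idx])
            clf = make_classifier(algorithm, seed)
            clf.fit(Xtr, y[train_idx])
            scores[test_idx] = _predict_proba(clf, Xte)
            fold_of[test_idx] = k
        metrics = compute_metrics(y, scores, threshold=threshold)
        records.append(
            MetricsRecord(
                algorithm=algorithm, group=group, roc=roc_points(y, scores),
                fold_assignments=fold_of, seed=seed, **metrics,
            ).validate()
        )
        logger.info(
            "group %s %s: acc %.3f sens %.3f spec %.3f auc %.3f",
            group, algorithm, metrics["accuracy"], metrics["sensitivity"],
            metrics["specificity"], metrics["auc"],
        )
    return records


def run_experiment_grid(
    tabular: pd.DataFrame,
    clouds: list[HemodynamicCloud],
    groups: tuple[str, ...] = ("A", "B1", "B2", "B3", "B4"),
    algorithms: tuple[str, ...] = ALGORITHMS,
    extractor_config: ExtractorConfig | None = None,
    folds: int = 10,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[tuple[str, str], np.ndarray]]:
    """Full algorithms x groups benchmark.

    Returns the report table (Algorithm, Feature, Accuracy, Sensitivity,
    Specificity, AUC) and the ROC polygon per (algorithm, group) cell.
    """
    rows = []
    rocs: dict[tuple[str, str], np.ndarray] = {}
    for group in groups:
        records = run_group_cv(
            tabular, clouds, group, algorithms=algorithms,
            extractor_config=extractor_config, folds=folds, seed=seed,
        )
        for rec in records:
            rows.append(
                {
                    "Algorithm": rec.algorithm,
                    "Feature": f"Group {rec.group}",
                    "Accuracy": rec.accuracy,
                    "Sensitivity": rec.sensitivity,
                    "Specificity": rec.specificity,
                    "AUC": rec.auc,
                }
            )
            rocs[(rec.algorithm, rec.group)] = rec.roc
    report = pd.DataFrame(rows)
    return report, rocs
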