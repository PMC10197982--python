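"""Binary hyperkalemia classification at multiple potassium thresholds.

The labelled feature table (48 morphological features + serum potassium)
is binarised at a diagnostic threshold (positive iff K >= threshold),
split 8:2 into training and test sets, and each of five model families —
logistic regression (LR), RBF support-vector machine (SVM), gradient
boosted trees (XGB), AdaBoost with stumps, and a compact 1-D convolutional
network (CNN) — is tuned by 5-fold stratified cross-validation on mean
validation AUC before refitting on the full training split.

Per-feature standardisation is fitted on training data only and applied
inside every fold, so no test information leaks into model selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from ._convnet import ConvNetClassifier
from .errors import SplitError, TrainingError, ValidationError
from .features import FEATURE_VECTOR_NAMES

__all__ = [
    "MODEL_FAMILIES",
    "DEFAULT_THRESHOLDS",
    "LabeledDataset",
    "DatasetSplit",
    "ModelSpec",
    "TrainedModel",
    "default_model_specs",
    "binarize_labels",
    "split_dataset",
    "tune_and_train",
    "predict_scores",
]

MODEL_FAMILIES = ("LR", "SVM", "XGB", "AdaBoost", "CNN")
DEFAULT_THRESHOLDS = (5.0, 5.5, 6.0, 6.5)


@dataclass
class LabeledDataset:
    """Aligned feature matrix, potassium values and record identifiers."""

    features: np.ndarray
    k: np.ndarray
    record_ids: Sequence[str]
    subject_ids: Sequence[str] | None = None
    feature_names: tuple = FEATURE_VECTOR_NAMES

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.k = np.asarray(self.k, dtype=float)
        n = self.features.shape[0]
        if self.k.shape != (n,) or len(self.record_ids) != n:
            raise ValidationError("features, k and record_ids disagree in length")
        if self.subject_ids is not None and len(self.subject_ids) != n:
            raise ValidationError("subject_ids length mismatch")
        if not np.all(np.isfinite(self.features)):
            raise ValidationError("feature matrix contains missing values")
        if self.features.shape[1] != len(self.feature_names):
            raise ValidationError(
                f"expected {len(self.feature_names)} feature columns, "
                f"got {self.features.shape[1]}"
            )

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LabeledDataset":
        """Build from a features table with record_id and k_mmol_per_l columns."""
        missing = [c for c in ("record_id", "k_mmol_per_l") if c not in df.columns]
        if missing:
            raise ValidationError(f"features table lacks columns {missing}")
        absent = [c for c in FEATURE_VECTOR_NAMES if c not in df.columns]
        if absent:
            raise ValidationError(f"features table lacks feature columns {absent[:3]}...")
        return cls(
            features=df[list(FEATURE_VECTOR_NAMES)].to_numpy(dtype=float),
            k=df["k_mmol_per_l"].to_numpy(dtype=float),
            record_ids=[str(r) for r in df["record_id"]],
        )

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(self.features, columns=list(self.feature_names))
        out.insert(0, "record_id", list(self.record_ids))
        out["k_mmol_per_l"] = self.k
        return out


@dataclass(frozen=True)
class DatasetSplit:
    """Disjoint train/test row indices produced by :func:`split_dataset`."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    test_fraction: float
    seed: int

    def __post_init__(self) -> None:
        tr = set(self.train_indices.tolist())
        te = set(self.test_indices.tolist())
        if tr & te:
            raise ValidationError("train and test indices overlap")


@dataclass(frozen=True)
class ModelSpec:
    """One model family plus its cross-validated hyperparameter grid."""

    family: str
    hyperparameter_grid: Mapping[str, Sequence] = field(default_factory=dict)
    cv_folds: int = 5
    scoring: str = "auc"

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ValidationError(
                f"unknown family {self.family!r}; expected one of {MODEL_FAMILIES}"
            )
        if self.cv_folds < 2:
            raise ValidationError("cv_folds must be >= 2")
        if not self.hyperparameter_grid:
            raise ValidationError("hyperparameter grid must be non-empty")
        for key, values in self.hyperparameter_grid.items():
            if len(list(values)) == 0:
                raise ValidationError(f"empty value list for hyperparameter {key!r}")


@dataclass
class TrainedModel:
    """A tuned, refitted model with its train-only standardisation."""

    family: str
    chosen_hyperparameters: dict
    estimator: object
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    cv_results: pd.DataFrame
    score_kind: str  # "probability" or "margin_rank"
    train_decision_values: np.ndarray | None = None
    decision_threshold: float = 0.5


def default_model_specs() -> dict[str, ModelSpec]:
    """The default hyperparameter grids of the five families.

    Grids are deliberately small and defensible; every entry can be
    overridden through the pipeline configuration.
    """
    return {
        "LR": ModelSpec("LR", {"C": [0.01, 0.1, 1.0, 10.0]}),
        "SVM": ModelSpec("SVM", {"C": [0.1, 1.0, 10.0],
                                 "gamma": ["scale", 0.01, 0.1]}),
        "XGB": ModelSpec("XGB", {"n_estimators": [100, 300],
                                 "max_depth": [2, 3, 4],
                                 "learning_rate": [0.05, 0.1]}),
        "AdaBoost": ModelSpec("AdaBoost", {"n_estimators": [100, 300],
                                           "learning_rate": [0.5, 1.0]}),
        "CNN": ModelSpec("CNN", {"learning_rate": [0.01]}),
    }


# ---------------------------------------------------------------------------
# Labels and splitting
# ---------------------------------------------------------------------------

def binarize_labels(k, threshold: float) -> np.ndarray:
    """Label 1 iff serum potassium >= threshold (mmol/L).

    The canonical diagnostic thresholds are 5.0, 5.5, 6.0 and 6.5 mmol/L;
    other values are allowed with a warning.
    """
    k = np.asarray(k, dtype=float)
    if float(threshold) not in DEFAULT_THRESHOLDS:
        warnings.warn(
            f"threshold {threshold} mmol/L is outside the canonical set "
            f"{DEFAULT_THRESHOLDS}", stacklevel=2,
        )
    return (k >= threshold).astype(int)


def split_dataset(
    n: int,
    test_fraction: float = 0.2,
    seed: int = 0,
    stratify_labels: np.ndarray | None = None,
) -> DatasetSplit:
    """Random 8:2 (by default) row split, deterministic given the seed.

    ``|test| = round(test_fraction * n)``. With ``stratify_labels`` the
    per-class test counts follow largest-remainder apportionment, so class
    proportions in both parts match the full data within one sample.
    """
    if n < 10:
        raise SplitError(f"need at least 10 rows to split, got {n}")
    if not 0.0 < test_fraction < 1.0:
        raise SplitError("test_fraction must lie in (0, 1)")
    n_test = int(round(test_fraction * n))
    if n_test == 0 or n_test == n:
        raise SplitError("split would leave an empty part")
    rng = np.random.default_rng(seed)
    if stratify_labels is None:
        perm = rng.permutation(n)
        test_idx = np.sort(perm[:n_test])
        train_idx = np.sort(perm[n_test:])
    else:
        y = np.asarray(stratify_labels)
        if y.shape != (n,):
            raise SplitError("stratify_labels length mismatch")
        classes, counts = np.unique(y, return_counts=True)
        if np.any(counts < 2):
            raise SplitError(
                "a class with fewer than 2 members cannot appear in both parts"
            )
        exact = counts * n_test / n
        alloc = np.floor(exact).astype(int)
        remainder = exact - alloc
        for cls_pos in np.argsort(-remainder)[: n_test - alloc.sum()]:
            alloc[cls_pos] += 1
        alloc = np.minimum(alloc, counts - 1)  # keep every class in training
        test_parts = []
        for cls, take in zip(classes, alloc):
            idx = np.nonzero(y == cls)[0]
            rng.shuffle(idx)
            test_parts.append(idx[:take])
        test_idx = np.sort(np.concatenate(test_parts))
        mask = np.ones(n, dtype=bool)
        mask[test_idx] = False
        train_idx = np.nonzero(mask)[0]
    return DatasetSplit(
        train_indices=train_idx, test_indices=test_idx,
        test_fraction=test_fraction, seed=seed,
    )


# ---------------------------------------------------------------------------
# Model construction and tuning
# ---------------------------------------------------------------------------

def _make_estimator(family: str, params: dict, seed: int):
    if family == "LR":
        return LogisticRegression(max_iter=5000, random_state=seed, **params)
    if family == "SVM":
        return SVC(kernel="rbf", random_state=seed, **params)
    if family == "XGB":
        return XGBClassifier(
            objective="binary:logistic", eval_metric="logloss",
            tree_method="hist", n_jobs=1, random_state=seed, **params,
        )
    if family == "AdaBoost":
        return AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=1),
            random_state=seed, **params,
        )
    if family == "CNN":
        return ConvNetClassifier(random_state=seed, **params)
    raise ValidationError(f"unknown family {family!r}")


def _decision_values(family: str, estimator, X: np.ndarray) -> np.ndarray:
    """Continuous positive-class propensity before any [0, 1] mapping."""
    if family == "SVM":
        return estimator.decision_function(X)
    return estimator.predict_proba(X)[:, 1]


def _grid_points(grid: Mapping[str, Sequence]) -> list[dict]:
    keys = list(grid.keys())
    return [dict(zip(keys, combo)) for combo in product(*(grid[k] for k in keys))]


def tune_and_train(
    spec: ModelSpec,
    train_features: np.ndarray,
    train_labels: np.ndarray,
    seed: int = 0,
) -> TrainedModel:
    """Select hyperparameters by 5-fold CV on AUC and refit on all training data.

    For every grid point the mean validation AUC over stratified folds is
    computed with standardisation refitted inside each fold; the first grid
    point attaining the maximal mean AUC wins (ties break in grid order).
    The returned model carries the train-only standardisation moments.
    """
    X = np.asarray(train_features, dtype=float)
    y = np.asarray(train_labels).astype(int)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValidationError("train_features and train_labels disagree")
    if np.unique(y).size < 2:
        raise TrainingError("training data contains a single class")
    points = _grid_points(spec.hyperparameter_grid)
    skf = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))

    rows = []
    mean_aucs = []
    for point in points:
        fold_aucs = []
        for tr, va in folds:
            scaler = StandardScaler().fit(X[tr])
            est = _make_estimator(spec.family, point, seed)
            est.fit(scaler.transform(X[tr]), y[tr])
            dv = _decision_values(spec.family, est, scaler.transform(X[va]))
            fold_aucs.append(roc_auc_score(y[va], dv))
        mean_auc = float(np.mean(fold_aucs))
        mean_aucs.append(mean_auc)
        rows.append({"params": point, "mean_val_auc": mean_auc,
                     "fold_aucs": fold_aucs})
    best = int(np.argmax(mean_aucs))  # argmax returns the first maximum
    chosen = points[best]

    scaler = StandardScaler().fit(X)
    est = _make_estimator(spec.family, chosen, seed)
    est.fit(scaler.transform(X), y)
    score_kind = "margin_rank" if spec.family == "SVM" else "probability"
    train_dv = None
    if score_kind == "margin_rank":
        train_dv = np.sort(_decision_values(spec.family, est,
                                            scaler.transform(X)))
    return TrainedModel(
        family=spec.family,
        chosen_hyperparameters=chosen,
        estimator=est,
        scaler_mean=scaler.mean_.copy(),
        scaler_scale=scaler.scale_.copy(),
        cv_results=pd.DataFrame(rows),
        score_kind=score_kind,
        train_decision_values=train_dv,
        decision_threshold=0.5,
    )


def predict_scores(model: TrainedModel, features) -> np.ndarray:
    """Continuous scores in [0, 1], monotone in positive-class propensity.

    Probability families return the calibrated positive-class probability.
    The margin family (SVM) maps its decision values through the empirical
    CDF of the training-set decision values, so 0.5 corresponds to the
    training median margin — a rank-preserving [0, 1] mapping.

    ``features`` may be an ndarray with columns in canonical order or a
    DataFrame carrying the canonical column names (any storage order).
    """
    if isinstance(features, pd.DataFrame):
        missing = [c for c in FEATURE_VECTOR_NAMES if c not in features.columns]
        if missing:
            raise ValidationError(f"missing feature columns {missing[:3]}...")
        X = features[list(FEATURE_VECTOR_NAMES)].to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.scaler_mean.size:
        raise ValidationError(
            f"expected {model.scaler_mean.size} feature columns, got {X.shape}"
        )
    Xs = (X - model.scaler_mean) / model.scaler_scale
    dv = _decision_values(model.family, model.estimator, Xs)
    if model.score_kind == "margin_rank":
        ref = model.train_decision_values
        # mid-rank ECDF: strictly monotone in dv, ties get the average rank
        lo = np.searchsorted(ref, dv, side="left")
        hi = np.searchsorted(ref, dv, side="right")
        return (lo + hi) / (2.0 * ref.size)
    return dv
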