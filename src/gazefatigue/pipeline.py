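"""Fatigue classification pipeline and the streaming assessment scenario.

The pipeline follows the training protocol of the method: z-score
normalization, removal of quasi-constant features, removal of Kendall-tau
correlated features, PCA to a kept-variance target, then a grid of
classifier families (random forest, decision tree, k-NN, MLP, logistic
regression, SVM) each evaluated on a balanced random split *and* under
stratified k-fold cross-validation.  The best configuration is the one with
the highest random-split accuracy; F1 (positive class = fatigued, i.e. low
mental performance) is reported alongside.

All preprocessing steps are sklearn-compatible transformers assembled into
a ``Pipeline``, so cross-validation refits them per fold and the fitted
artifact carries everything needed to transform future windows identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin, clone
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, confusion_matrix, f1_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .characteristics import recording_features
from .events import EventConfig
from .recording import GazeDataError, GazeRecording, InvalidParameterError
from .relevance import AU_THRESHOLD_DEFAULT, label_by_mental_performance

POSITIVE_CLASS = "low"  # fatigued = low mental performance

ARTIFACT_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class PipelineConfig:
    """Preprocessing, split and cross-validation settings."""

    normalize: bool = True
    quasi_constant_threshold: float = 0.99
    kendall_tau_threshold: float = 0.9
    pca_variance_kept: float = 0.95
    au_threshold: float = AU_THRESHOLD_DEFAULT
    test_per_class: int = 100
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.quasi_constant_threshold <= 1:
            raise InvalidParameterError("quasi_constant_threshold must be in (0, 1]")
        if not 0 < self.kendall_tau_threshold <= 1:
            raise InvalidParameterError("kendall_tau_threshold must be in (0, 1]")
        if not 0 < self.pca_variance_kept <= 1:
            raise InvalidParameterError("pca_variance_kept must be in (0, 1]")
        if self.cv_folds < 2:
            raise InvalidParameterError("cv_folds must be >= 2")


# ---------------------------------------------------------------------------
# preprocessing primitives
# ---------------------------------------------------------------------------

def zscore_normalize(
    matrix: np.ndarray | pd.DataFrame,
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Z-score each column with the population-SD convention (divide by n).

    Returns the normalized matrix and ``(mean, sd)`` to transform future
    data identically.  The population convention makes the transform
    idempotent: renormalizing an already normalized matrix changes nothing.
    A zero-variance column is an error — such columns belong to the
    quasi-constant removal step, not to a division.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise InvalidParameterError("need a 2-D matrix with at least 2 rows")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # ddof=0
    zero = np.nonzero(sd == 0)[0]
    if zero.size:
        raise InvalidParameterError(
            f"zero-variance column at index {int(zero[0])}: remove quasi-constant "
            "features before normalization"
        )
    return (X - mean) / sd, (mean, sd)


def apply_normalization(
    matrix: np.ndarray | pd.DataFrame, params: tuple[np.ndarray, np.ndarray]
) -> np.ndarray:
    mean, sd = params
    return (np.asarray(matrix, dtype=float) - mean) / sd


def quasi_constant_mask(matrix: np.ndarray, threshold: float) -> np.ndarray:
    """Boolean keep-mask: False where the modal value's relative frequency
    is at or above ``threshold``."""
    X = np.asarray(matrix, dtype=float)
    n = X.shape[0]
    keep = np.empty(X.shape[1], dtype=bool)
    for j in range(X.shape[1]):
        _, counts = np.unique(X[:, j], return_counts=True)
        keep[j] = counts.max() / n < threshold
    return keep


def remove_quasi_constant(
    matrix: pd.DataFrame | np.ndarray, threshold: float = 0.99
) -> pd.DataFrame | np.ndarray:
    """Drop columns dominated by a single value (survivor order preserved)."""
    X = np.asarray(matrix, dtype=float)
    keep = quasi_constant_mask(X, threshold)
    if not keep.any():
        raise GazeDataError("all columns are quasi-constant at this threshold")
    if isinstance(matrix, pd.DataFrame):
        return matrix.loc[:, matrix.columns[keep]]
    return X[:, keep]


def kendall_keep_mask(matrix: np.ndarray, tau_threshold: float) -> np.ndarray:
    """Left-to-right scan: drop a column whose |Kendall tau| with any
    already-kept column reaches the threshold."""
    X = np.asarray(matrix, dtype=float)
    ncol = X.shape[1]
    keep: list[int] = []
    for j in range(ncol):
        redundant = False
        for i in keep:
            tau = stats.kendalltau(X[:, i], X[:, j]).statistic
            if np.isfinite(tau) and abs(tau) >= tau_threshold:
                redundant = True
                break
        if not redundant:
            keep.append(j)
    mask = np.zeros(ncol, dtype=bool)
    mask[keep] = True
    return mask


def remove_kendall_correlated(
    matrix: pd.DataFrame | np.ndarray, tau_threshold: float = 0.9
) -> pd.DataFrame | np.ndarray:
    X = np.asarray(matrix, dtype=float)
    mask = kendall_keep_mask(X, tau_threshold)
    if isinstance(matrix, pd.DataFrame):
        return matrix.loc[:, matrix.columns[mask]]
    return X[:, mask]


def pca_reduce(
    matrix: np.ndarray | pd.DataFrame, variance_kept: float = 0.95
) -> tuple[np.ndarray, PCA]:
    """Project onto the smallest component count reaching the kept-variance
    target; the fitted transform is returned for inference."""
    if not 0 < variance_kept <= 1:
        raise InvalidParameterError("variance_kept must be in (0, 1]")
    X = np.asarray(matrix, dtype=float)
    if variance_kept == 1.0:
        pca = PCA(n_components=min(X.shape[0] - 1, X.shape[1]))
    else:
        pca = PCA(n_components=variance_kept, svd_solver="full")
    Xr = pca.fit_transform(X)
    return Xr, pca


class FeaturePreprocessor(BaseEstimator, TransformerMixin):
    """Quasi-constant removal -> z-score -> Kendall removal -> PCA.

    sklearn-compatible so cross-validation refits it inside each fold.
    Any step can be disabled through :class:`PipelineConfig`.
    """

    def __init__(self, config: PipelineConfig | None = None):
        self.config = config

    def fit(self, X, y=None):
        cfg = self.config or PipelineConfig()
        X = np.asarray(X, dtype=float)
        self.n_features_in_ = X.shape[1]
        self.qc_mask_ = quasi_constant_mask(X, cfg.quasi_constant_threshold)
        if not self.qc_mask_.any():
            raise GazeDataError("all columns are quasi-constant")
        X = X[:, self.qc_mask_]
        if cfg.normalize:
            X, self.norm_params_ = zscore_normalize(X)
        else:
            self.norm_params_ = None
        self.kendall_mask_ = kendall_keep_mask(X, cfg.kendall_tau_threshold)
        X = X[:, self.kendall_mask_]
        _, self.pca_ = pca_reduce(X, cfg.pca_variance_kept)
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise GazeDataError(
                f"expected {self.n_features_in_} feature columns, got {X.shape[1]}"
            )
        X = X[:, self.qc_mask_]
        if self.norm_params_ is not None:
            X = apply_normalization(X, self.norm_params_)
        return self.pca_.transform(X[:, self.kendall_mask_])


# ---------------------------------------------------------------------------
# model grid
# ---------------------------------------------------------------------------

TREE_CRITERIA = ("gini", "entropy", "log_loss")


def _default_grids() -> dict[str, list[dict]]:
    return {
        "random_forest": [
            {"n_estimators": n, "criterion": c}
            for n in range(10, 101, 10)
            for c in TREE_CRITERIA
        ],
        "decision_tree": [{"criterion": c} for c in TREE_CRITERIA],
        "knn": [
            {"n_neighbors": k, "weights": w}
            for k in range(1, 11)
            for w in ("uniform", "distance")
        ],
        "mlp": [
            {"solver": s, "activation": a, "hidden_layer_sizes": (h,)}
            for s in ("lbfgs", "sgd", "adam")
            for a in ("identity", "logistic", "tanh", "relu")
            for h in range(1, 21)
        ],
        "logistic_regression": [
            {"solver": s} for s in ("lbfgs", "liblinear", "newton-cg", "sag", "saga")
        ],
        "svm": [{"kernel": k} for k in ("linear", "poly", "rbf", "sigmoid")],
    }


@dataclass
class ModelGrid:
    """Per-family hyperparameter grids (defaults mirror the method's table)."""

    families: dict[str, list[dict]] = field(default_factory=_default_grids)

    def __post_init__(self) -> None:
        known = set(_default_grids())
        for fam, grid in self.families.items():
            if fam not in known:
                raise InvalidParameterError(f"unknown classifier family {fam!r}")
            if not grid:
                raise InvalidParameterError(f"empty grid for family {fam!r}")

    @classmethod
    def subset(cls, *families: str) -> "ModelGrid":
        defaults = _default_grids()
        return cls(families={f: defaults[f] for f in families})

    def __iter__(self):
        for fam, grid in self.families.items():
            for params in grid:
                yield fam, params


def build_estimator(family: str, params: dict, seed: int = 0):
    """Instantiate one grid configuration as a seeded sklearn estimator.

    Loss functions are fixed per family: log-loss for the MLP and logistic
    regression, hinge for the SVM; k-NN stores the data and has none.
    """
    if family == "random_forest":
        return RandomForestClassifier(random_state=seed, **params)
    if family == "decision_tree":
        return DecisionTreeClassifier(random_state=seed, **params)
    if family == "knn":
        return KNeighborsClassifier(**params)
    if family == "mlp":
        return MLPClassifier(random_state=seed, max_iter=500, **params)
    if family == "logistic_regression":
        return LogisticRegression(random_state=seed, max_iter=1000, **params)
    if family == "svm":
        return SVC(random_state=seed, probability=False, **params)
    raise InvalidParameterError(f"unknown classifier family {family!r}")


# ---------------------------------------------------------------------------
# split / evaluation / grid training
# ---------------------------------------------------------------------------

def make_balanced_split(
    labels: Sequence[str], test_per_class: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Random split holding out exactly ``test_per_class`` rows per class."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    for cls in np.unique(labels):
        idx = np.nonzero(labels == cls)[0]
        if len(idx) <= test_per_class:
            raise InvalidParameterError(
                f"class {cls!r} has {len(idx)} rows; cannot hold out "
                f"{test_per_class} and still train"
            )
        test_idx.extend(rng.choice(idx, size=test_per_class, replace=False))
    test = np.sort(np.asarray(test_idx))
    train = np.setdiff1d(np.arange(len(labels)), test)
    return train, test


def evaluate_model(model, X_test, y_test) -> dict:
    """Accuracy, F1 (positive class = fatigued/low) and confusion matrix."""
    y_pred = model.predict(X_test)
    classes = sorted(set(y_test) | set(y_pred))
    return {
        "accuracy": float(accuracy_score(y_test, y_pred)),
        "f1": float(
            f1_score(y_test, y_pred, pos_label=POSITIVE_CLASS, zero_division=0)
        ),
        "confusion_matrix": confusion_matrix(y_test, y_pred, labels=classes),
        "classes": classes,
    }


@dataclass
class ModelReport:
    """Grid evaluation results; best = argmax random-split accuracy."""

    results: pd.DataFrame
    best_family: str
    best_params: dict
    best_pipeline: Pipeline
    config: PipelineConfig

    @property
    def best_row(self) -> pd.Series:
        m = (self.results["family"] == self.best_family) & (
            self.results["params"] == repr(self.best_params)
        )
        return self.results[m].iloc[0]


def labels_from_au(au: Sequence[float], threshold: float) -> np.ndarray:
    labs = [label_by_mental_performance(a, threshold) for a in au]
    if any(l is None for l in labs):
        raise GazeDataError("absent Au value; drop those rows before training")
    return np.asarray(labs)


def grid_train(
    X: pd.DataFrame | np.ndarray,
    labels: Sequence[str],
    grid: ModelGrid | None = None,
    cfg: PipelineConfig | None = None,
) -> ModelReport:
    """Train/evaluate every grid configuration; report split and CV metrics.

    Each configuration is an sklearn ``Pipeline`` (preprocessor + model):
    the random split holds out ``test_per_class`` rows per class, and the
    stratified k-fold CV refits preprocessing inside each fold.  Fully
    seeded from the pipeline config.
    """
    grid = grid or ModelGrid()
    cfg = cfg or PipelineConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise GazeDataError("need both classes present for training")
    train_idx, test_idx = make_balanced_split(y, cfg.test_per_class, cfg.seed)
    skf = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True, random_state=cfg.seed)

    rows = []
    best = None  # (accuracy, family, params, pipeline)
    for family, params in grid:
        pipe = Pipeline(
            [
                ("prep", FeaturePreprocessor(cfg)),
                ("clf", build_estimator(family, params, cfg.seed)),
            ]
        )
        pipe.fit(X[train_idx], y[train_idx])
        split = evaluate_model(pipe, X[test_idx], y[test_idx])
        cv_acc, cv_f1 = [], []
        for tr, te in skf.split(X, y):
            fold = clone(pipe)
            fold.fit(X[tr], y[tr])
            m = evaluate_model(fold, X[te], y[te])
            cv_acc.append(m["accuracy"])
            cv_f1.append(m["f1"])
        rows.append(
            {
                "family": family,
                "params": repr(params),
                "split_accuracy": split["accuracy"],
                "split_f1": split["f1"],
                "cv_accuracy": float(np.mean(cv_acc)),
                "cv_f1": float(np.mean(cv_f1)),
            }
        )
        if best is None or split["accuracy"] > best[0]:
            best = (split["accuracy"], family, params, pipe)
    results = pd.DataFrame(rows)
    return ModelReport(
        results=results,
        best_family=best[1],
        best_params=best[2],
        best_pipeline=best[3],
        config=cfg,
    )


# ---------------------------------------------------------------------------
# model artifact + streaming assessment
# ---------------------------------------------------------------------------

@dataclass
class FatigueModel:
    """A trained classifier bundled with its exact feature definition."""

    pipeline: Pipeline
    feature_columns: list[str]
    feature_sets: str
    event_config: EventConfig
    window_s: float = 60.0
    meta: dict = field(default_factory=dict)


def save_model(model: FatigueModel, path: str | Path) -> None:
    joblib.dump({"schema_version": ARTIFACT_SCHEMA_VERSION, "model": model}, path)


def load_model(path: str | Path) -> FatigueModel:
    blob = joblib.load(path)
    if blob.get("schema_version") != ARTIFACT_SCHEMA_VERSION:
        raise GazeDataError(
            f"unsupported model artifact schema {blob.get('schema_version')!r}"
        )
    return blob["model"]


def assess_stream(
    model: FatigueModel,
    rec: GazeRecording,
    step_s: float = 1.0,
) -> pd.DataFrame:
    """Fatigue estimates over a sliding window of a gaze stream.

    One row per step: ``status`` ('ok' or 'insufficient data'), the
    predicted ``label`` and a fatigue ``score`` (probability of the
    fatigued class when the classifier exposes probabilities, else the
    signed distance of its decision function, else NaN).  Steps before the
    first full window report insufficient data explicitly.
    """
    if step_s <= 0:
        raise InvalidParameterError("step_s must be positive")
    t0 = float(rec.t[0]) if len(rec) else 0.0
    dur = rec.duration
    out = []
    e = step_s
    while e <= dur + 1e-9:
        end = t0 + e
        if e < model.window_s:
            out.append({"t": end, "status": "insufficient data",
                        "label": None, "score": np.nan})
            e += step_s
            continue
        win = rec.time_slice(end - model.window_s, end + 1e-12)
        feats = recording_features(win, model.event_config, model.feature_sets)
        missing = [c for c in model.feature_columns if c not in feats]
        if missing:
            raise GazeDataError(
                f"feature definition mismatch: window lacks columns {missing}"
            )
        row = np.array(
            [[np.nan if feats[c] is None else feats[c] for c in model.feature_columns]]
        )
        if not np.all(np.isfinite(row)):
            out.append({"t": end, "status": "insufficient data",
                        "label": None, "score": np.nan})
            e += step_s
            continue
        label = model.pipeline.predict(row)[0]
        clf = model.pipeline
        if hasattr(clf, "predict_proba"):
            try:
                proba = clf.predict_proba(row)[0]
                classes = list(clf.classes_)
                score = float(proba[classes.index(POSITIVE_CLASS)])
            except AttributeError:
                score = np.nan
        else:
            score = np.nan
        out.append({"t": end, "status": "ok", "label": label, "score": score})
        e += step_s
    return pd.DataFrame(out, columns=["t", "status", "label", "score"])
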