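"""Supervised identification workflow for per-event glycan classification.

Stages, in run order: dataset assembly with a stratified 70/15/15
train/validation/test split; one-way ANOVA-F feature ranking on standardized
values (listwise deletion per feature) and top-k selection (k = 12 of the 19
descriptors by default); leak-free preprocessing (train-median imputation with
missingness-indicator columns, then standardization — every statistic fitted
on training rows only and fingerprinted); density-based denoising of the
training set (HDBSCAN noise points dropped, validation/test untouched); a
ten-model zoo evaluated by repeated stratified 10-fold cross-validation with
the winner chosen by macro-F1; final-model training, event-level prediction,
and diagnostics (normalized confusion matrix, learning curve, 2-D embedding).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.cluster import HDBSCAN
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import (
    RepeatedStratifiedKFold,
    cross_validate,
    learning_curve,
)
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import LabelEncoder
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .features import FEATURE_NAMES
from .trace_io import ValidationError

__all__ = [
    "DatasetSplit",
    "Preprocessor",
    "CVReport",
    "ClassModelBundle",
    "assemble_dataset",
    "rank_features_anova",
    "select_top_k",
    "fit_preprocessor",
    "apply_preprocessor",
    "denoise_training",
    "default_model_zoo",
    "evaluate_models",
    "train_final",
    "predict_events",
    "confusion_and_learning_curve",
    "embed_2d",
    "save_bundle",
    "load_bundle",
]


@dataclass
class DatasetSplit:
    """Disjoint stratified train/validation/test row indices."""

    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray
    seed: int
    per_class_counts: dict = field(default_factory=dict)


@dataclass
class CVReport:
    """Cross-validation summary per candidate model."""

    metrics: dict                 # model -> {metric: (mean, sd)}
    chosen: str                   # argmax mean macro-F1
    n_splits: int
    n_repeats: int


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

def assemble_dataset(
    tables_by_class: dict,
    per_class_n: int = 10_000,
    seed: int = 0,
    fractions: tuple = (0.70, 0.15, 0.15),
) -> tuple[pd.DataFrame, DatasetSplit]:
    """Subsample per class and build a stratified 70/15/15 split.

    ``tables_by_class`` maps label → feature DataFrame. Classes with fewer
    than ``per_class_n`` events contribute all their events (with a warning).
    The split is deterministic under ``seed`` and stratified exactly: within
    each class the subset sizes hit the target fractions to within one event.
    """
    if len(tables_by_class) < 2:
        raise ValidationError("need >= 2 classes")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValidationError("split fractions must sum to 1")
    rng = np.random.default_rng(seed)
    parts = []
    for label in sorted(tables_by_class):
        tbl = tables_by_class[label]
        if len(tbl) == 0:
            raise ValidationError(f"class {label!r} has no events")
        tbl = tbl.copy()
        tbl["label"] = label
        if len(tbl) > per_class_n:
            idx = rng.choice(len(tbl), size=per_class_n, replace=False)
            tbl = tbl.iloc[np.sort(idx)]
        elif len(tbl) < per_class_n:
            warnings.warn(
                f"class {label!r} has only {len(tbl)} events (< {per_class_n}); using all",
                stacklevel=2,
            )
        parts.append(tbl)
    data = pd.concat(parts, ignore_index=True)

    train_idx, val_idx, test_idx = [], [], []
    counts = {}
    for label in sorted(tables_by_class):
        rows = np.flatnonzero((data["label"] == label).to_numpy())
        rows = rng.permutation(rows)
        n = rows.size
        n_train = int(round(fractions[0] * n))
        n_val = int(round(fractions[1] * n))
        train_idx.append(rows[:n_train])
        val_idx.append(rows[n_train : n_train + n_val])
        test_idx.append(rows[n_train + n_val :])
        counts[label] = n
    split = DatasetSplit(
        train=np.sort(np.concatenate(train_idx)),
        validation=np.sort(np.concatenate(val_idx)),
        test=np.sort(np.concatenate(test_idx)),
        seed=seed,
        per_class_counts=counts,
    )
    return data, split


# ---------------------------------------------------------------------------
# Feature ranking / selection
# ---------------------------------------------------------------------------

def rank_features_anova(train: pd.DataFrame, feature_names=None) -> pd.DataFrame:
    """One-way ANOVA F per feature on standardized values, descending.

    Missing values are dropped listwise per feature. A feature with zero
    within-class variance gets F = +inf (ranked first, flagged); ties break on
    the canonical feature order.
    """
    feature_names = list(feature_names or FEATURE_NAMES)
    labels = train["label"].to_numpy()
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValidationError("ANOVA ranking needs >= 2 classes")
    rows = []
    for order, feat in enumerate(feature_names):
        x = train[feat].to_numpy(dtype=float)
        ok = np.isfinite(x)
        xs = x[ok]
        if xs.size < 2 * classes.size or np.std(xs) == 0:
            rows.append((feat, 0.0, order, False))
            continue
        xs = (xs - np.mean(xs)) / np.std(xs)
        groups = [xs[labels[ok] == c] for c in classes]
        groups = [g for g in groups if g.size >= 2]
        if len(groups) < 2:
            rows.append((feat, 0.0, order, False))
            continue
        if all(np.ptp(g) == 0 for g in groups):
            rows.append((feat, np.inf, order, True))
            continue
        f_val = stats.f_oneway(*groups).statistic
        rows.append((feat, float(f_val) if np.isfinite(f_val) else np.inf, order, False))
    df = pd.DataFrame(rows, columns=["feature", "F", "canonical_order", "degenerate"])
    return df.sort_values(["F", "canonical_order"], ascending=[False, True]).reset_index(drop=True)


def select_top_k(ranked: pd.DataFrame, k: int = 12) -> list:
    """First k features by ANOVA rank."""
    if k <= 0:
        raise ValidationError("k must be positive")
    if k > len(ranked):
        raise ValidationError(f"k={k} exceeds the {len(ranked)} ranked features")
    selected = ranked["feature"].head(k).tolist()
    expected = {"std", "skew", "mean", "median"}
    if not expected <= set(selected):
        warnings.warn(
            f"informative-feature check: {sorted(expected - set(selected))} not in the top set",
            stacklevel=2,
        )
    return selected


# ---------------------------------------------------------------------------
# Preprocessing (leak-free)
# ---------------------------------------------------------------------------

@dataclass
class Preprocessor:
    """Train-fitted median imputation + missingness indicators + standardization.

    ``transform`` produces columns = selected features followed by one
    indicator per feature that had any missingness in training; all columns
    are standardized with train statistics. The fingerprint ties the fitted
    state to the exact training rows.
    """

    features: list
    medians: dict
    indicator_features: list
    means: np.ndarray
    sds: np.ndarray
    train_fingerprint: str

    @property
    def output_columns(self) -> list:
        return self.features + [f"missing_{f}" for f in self.indicator_features]


def _fingerprint(matrix: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(matrix).tobytes()).hexdigest()


def fit_preprocessor(train: pd.DataFrame, features: list) -> Preprocessor:
    """Fit imputation/indicator/standardization statistics on training rows only."""
    if len(train) == 0:
        raise ValidationError("empty training table")
    raw = train[features].to_numpy(dtype=float)
    medians = {}
    indicator_features = []
    for j, feat in enumerate(features):
        col = raw[:, j]
        ok = np.isfinite(col)
        if ok.all():
            medians[feat] = float(np.median(col))
        elif ok.any():
            medians[feat] = float(np.median(col[ok]))
            indicator_features.append(feat)
        else:
            warnings.warn(f"feature {feat!r} entirely missing in train; imputing 0", stacklevel=2)
            medians[feat] = 0.0
            indicator_features.append(feat)
    mat = _assemble_matrix(raw, features, medians, indicator_features)
    means = mat.mean(axis=0)
    sds = mat.std(axis=0)
    sds[sds == 0] = 1.0
    return Preprocessor(
        features=list(features),
        medians=medians,
        indicator_features=indicator_features,
        means=means,
        sds=sds,
        train_fingerprint=_fingerprint(raw),
    )


def _assemble_matrix(raw, features, medians, indicator_features):
    cols = []
    for j, feat in enumerate(features):
        col = raw[:, j].copy()
        col[~np.isfinite(col)] = medians[feat]
        cols.append(col)
    for feat in indicator_features:
        j = features.index(feat)
        cols.append((~np.isfinite(raw[:, j])).astype(float))
    return np.column_stack(cols)


def apply_preprocessor(pp: Preprocessor, table: pd.DataFrame) -> np.ndarray:
    """Transform any table with the stored (train-only) statistics."""
    missing_cols = [f for f in pp.features if f not in table.columns]
    if missing_cols:
        raise ValidationError(f"table lacks selected features: {missing_cols}")
    raw = table[pp.features].to_numpy(dtype=float)
    mat = _assemble_matrix(raw, pp.features, pp.medians, pp.indicator_features)
    return (mat - pp.means) / pp.sds


# ---------------------------------------------------------------------------
# Training-set denoising
# ---------------------------------------------------------------------------

def denoise_training(
    X_train: np.ndarray,
    labels=None,
    min_cluster_size: int = 50,
    max_rows: int = 20_000,
    seed: int = 0,
) -> np.ndarray:
    """Indices of training rows retained after HDBSCAN noise removal.

    Hierarchical density-based clustering runs in the standardized feature
    space; rows labelled noise (-1) are dropped from *training only*. For very
    large training sets the clusterer is fitted on a seeded subsample and
    noise status of the remaining rows is inferred by approximate membership
    (nearest retained/noise vote via the fitted medoids is unnecessary — the
    subsample decides only its own rows; unsampled rows are retained).
    """
    if not np.all(np.isfinite(X_train)):
        raise ValidationError("training matrix must be finite")
    n = X_train.shape[0]
    if n > max_rows:
        rng = np.random.default_rng(seed)
        sub = np.sort(rng.choice(n, size=max_rows, replace=False))
        lab = HDBSCAN(min_cluster_size=min_cluster_size, copy=True).fit_predict(X_train[sub])
        noise = set(sub[lab == -1].tolist())
        retained = np.array([i for i in range(n) if i not in noise], dtype=np.int64)
    else:
        lab = HDBSCAN(min_cluster_size=min_cluster_size, copy=True).fit_predict(X_train)
        retained = np.flatnonzero(lab != -1)
    if retained.size == 0:
        raise ValidationError("all training points flagged as noise; parameters unusable")
    return retained


# ---------------------------------------------------------------------------
# Model zoo and evaluation
# ---------------------------------------------------------------------------

def default_model_zoo(seed: int = 0) -> dict:
    """The ten candidate classifiers (name → unfitted estimator)."""
    return {
        "mlp": MLPClassifier(hidden_layer_sizes=(64, 32), early_stopping=True,
                             max_iter=300, random_state=seed),
        "random_forest": RandomForestClassifier(n_estimators=200, random_state=seed, n_jobs=1),
        "gradient_boosting": XGBClassifier(
            n_estimators=200, tree_method="hist", random_state=seed,
            n_jobs=1, verbosity=0,
        ),
        "svc": SVC(kernel="rbf", cache_size=500, random_state=seed),
        "lda": LinearDiscriminantAnalysis(),
        "knn": KNeighborsClassifier(n_neighbors=15),
        "logistic_regression": LogisticRegression(max_iter=1000, random_state=seed),
        "gaussian_nb": GaussianNB(),
        "extra_trees": ExtraTreesClassifier(n_estimators=200, random_state=seed, n_jobs=1),
        "qda": QuadraticDiscriminantAnalysis(reg_param=1e-3),
    }


_SCORING = {"accuracy": "accuracy", "macro_f1": "f1_macro",
            "balanced_accuracy": "balanced_accuracy"}


def evaluate_models(
    X: np.ndarray,
    y: np.ndarray,
    zoo: dict | None = None,
    seed: int = 0,
    n_splits: int = 10,
    n_repeats: int = 5,
) -> CVReport:
    """Repeated stratified k-fold bake-off; winner by mean macro-F1.

    ``y`` must be integer-encoded labels. A fold that loses a class raises
    from sklearn after one re-seeded retry.
    """
    zoo = zoo or default_model_zoo(seed)
    metrics = {}
    for name, est in zoo.items():
        for attempt_seed in (seed, seed + 104729):
            cv = RepeatedStratifiedKFold(
                n_splits=n_splits, n_repeats=n_repeats, random_state=attempt_seed
            )
            try:
                res = cross_validate(clone(est), X, y, cv=cv, scoring=_SCORING,
                                     n_jobs=1, error_score="raise")
                break
            except ValueError:
                if attempt_seed != seed:
                    raise
        metrics[name] = {
            m: (float(np.mean(res[f"test_{m}"])), float(np.std(res[f"test_{m}"])))
            for m in _SCORING
        }
    chosen = max(metrics, key=lambda k: metrics[k]["macro_f1"][0])
    return CVReport(metrics=metrics, chosen=chosen, n_splits=n_splits, n_repeats=n_repeats)


# ---------------------------------------------------------------------------
# Final model bundle
# ---------------------------------------------------------------------------

@dataclass
class ClassModelBundle:
    """Fitted preprocessor + classifier + label codec + training metadata."""

    preprocessor: Preprocessor
    selected_features: list
    label_encoder: LabelEncoder
    model: object
    cv_report: CVReport | None
    metadata: dict


def train_final(
    train: pd.DataFrame,
    selected_features: list,
    seed: int = 0,
    cv_report: CVReport | None = None,
    model=None,
    preprocessor: Preprocessor | None = None,
    retained_idx: np.ndarray | None = None,
) -> ClassModelBundle:
    """Fit the winning model on the (optionally denoised) training table."""
    unknown = [f for f in selected_features if f not in FEATURE_NAMES]
    if unknown:
        raise ValidationError(f"selected features outside the canonical set: {unknown}")
    pp = preprocessor or fit_preprocessor(train, selected_features)
    X = apply_preprocessor(pp, train)
    le = LabelEncoder().fit(train["label"])
    y = le.transform(train["label"])
    if retained_idx is not None:
        X, y = X[retained_idx], y[retained_idx]
    if model is None:
        name = cv_report.chosen if cv_report else "mlp"
        model = default_model_zoo(seed)[name]
        model_name = name
    else:
        model_name = type(model).__name__
    model = clone(model).fit(X, y)
    config = {
        "selected_features": list(selected_features),
        "model": model_name,
        "seed": seed,
    }
    metadata = {
        **config,
        "n_train": int(X.shape[0]),
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True).encode()
        ).hexdigest()[:16],
    }
    return ClassModelBundle(pp, list(selected_features), le, model, cv_report, metadata)


def predict_events(bundle: ClassModelBundle, table: pd.DataFrame):
    """Per-event labels and class probabilities for a feature table."""
    X = apply_preprocessor(bundle.preprocessor, table)
    model = bundle.model
    if hasattr(model, "predict_proba"):
        proba = model.predict_proba(X)
    else:  # e.g. SVC without probability: one-hot the decision
        pred = model.predict(X)
        proba = np.zeros((X.shape[0], bundle.label_encoder.classes_.size))
        proba[np.arange(X.shape[0]), pred] = 1.0
    labels = bundle.label_encoder.inverse_transform(np.argmax(proba, axis=1))
    return labels, proba


def confusion_and_learning_curve(
    bundle: ClassModelBundle,
    test: pd.DataFrame,
    train: pd.DataFrame | None = None,
    sizes=(0.2, 0.4, 0.6, 0.8, 1.0),
    cv: int = 3,
    seed: int = 0,
):
    """Row-normalized confusion matrix on the test set (+ optional learning curve)."""
    if len(test) == 0:
        raise ValidationError("empty test set")
    labels_pred, _ = predict_events(bundle, test)
    classes = list(bundle.label_encoder.classes_)
    cm = confusion_matrix(test["label"], labels_pred, labels=classes, normalize="true")
    curve = None
    if train is not None:
        X = apply_preprocessor(bundle.preprocessor, train)
        y = bundle.label_encoder.transform(train["label"])
        ns, tr_scores, va_scores = learning_curve(
            clone(bundle.model), X, y, train_sizes=list(sizes), cv=cv,
            scoring="accuracy", random_state=seed, n_jobs=1, shuffle=True,
        )
        curve = pd.DataFrame({
            "n_train": ns,
            "train_score": tr_scores.mean(axis=1),
            "cv_score": va_scores.mean(axis=1),
        })
    return pd.DataFrame(cm, index=classes, columns=classes), curve


def embed_2d(X: np.ndarray, seed: int = 0) -> np.ndarray:
    """2-D manifold embedding (UMAP) with a fixed seed; plotting plumbing only."""
    if X.shape[0] < 10:
        raise ValidationError("need >= 10 points to embed")
    import umap  # deferred: numba-backed import is slow

    return umap.UMAP(n_components=2, random_state=seed).fit_transform(X)


# ---------------------------------------------------------------------------
# Bundle serialization
# ---------------------------------------------------------------------------

def save_bundle(bundle: ClassModelBundle, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "metadata.json").write_text(json.dumps(bundle.metadata, indent=1))
    joblib.dump(bundle, directory / "bundle.joblib")


def load_bundle(directory) -> ClassModelBundle:
    directory = Path(directory)
    bundle = joblib.load(directory / "bundle.joblib")
    meta = json.loads((directory / "metadata.json").read_text())
    if meta.get("config_hash") != bundle.metadata.get("config_hash"):
        raise ValidationError("bundle metadata/config-hash mismatch")
    return bundle
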