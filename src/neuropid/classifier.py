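"""Four-model supervised ensemble with calibrated decision thresholds.

The classifier stack scores a 560-feature vector with four models —

* ``random_forest`` — a decision-tree ensemble on all features,
* ``gradient_boosting`` — boosted trees on all features,
* ``linear_svm`` — a linear SVM whose margins are Platt-calibrated to
  probabilities (the thresholding contract needs probabilities),
* ``minimal_tree`` — a tree ensemble restricted to a small subset of the
  most discriminative features,

and a sequence is called positive when *at least one* model's probability
strictly exceeds that model's threshold.  Default thresholds are 0.8 for
the three tree/SVM models and a stringent 0.99 for gradient boosting.

Training evaluates each model by stratified k-fold cross-validation
(default 6 folds), averaging held-out metrics across folds, then refits
on all data.  All randomness flows from a single integer seed recorded
in the bundle; the feature-catalog version is recorded too and scoring
vectors from a different catalog is refused.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import clone
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import (
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .feature_extraction import CATALOG_VERSION, FEATURE_NAMES, FeatureVector

MODEL_NAMES = ("random_forest", "gradient_boosting", "linear_svm", "minimal_tree")

DEFAULT_THRESHOLDS: dict[str, float] = {
    "random_forest": 0.8,
    "gradient_boosting": 0.99,
    "linear_svm": 0.8,
    "minimal_tree": 0.8,
}

DEFAULT_K_MINIMAL = 20


class CatalogMismatchError(ValueError):
    """Feature vector was built under a different catalog version."""


@dataclass
class EvalMetrics:
    """Confusion counts and the derived classification quality measures."""

    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    precision: float
    recall: float
    mcc: float
    auc: float = float("nan")
    precision_undefined: bool = False


def confusion_metrics(tp: int, tn: int, fp: int, fn: int) -> EvalMetrics:
    """Accuracy, precision, recall and MCC from confusion counts.

    accuracy = (TP+TN)/(TP+FP+TN+FN); precision = TP/(TP+FP);
    recall = TP/(TP+FN); MCC = (TP*TN - FP*FN) /
    sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)), defined as 0 when any factor of
    the denominator is 0.  Undefined precision (TP+FP = 0) is reported
    as 0 with ``precision_undefined`` set.
    """
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("confusion counts sum to zero")
    accuracy = (tp + tn) / total
    precision_undefined = (tp + fp) == 0
    precision = 0.0 if precision_undefined else tp / (tp + fp)
    recall = 0.0 if (tp + fn) == 0 else tp / (tp + fn)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / np.sqrt(denom)
    return EvalMetrics(tp=tp, tn=tn, fp=fp, fn=fn, accuracy=accuracy,
                       precision=precision, recall=recall, mcc=float(mcc),
                       precision_undefined=precision_undefined)


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve, Mann–Whitney formulation.

    Equals the fraction of (positive, negative) pairs where the positive
    outscores the negative, ties counting one half.  Requires at least one
    label of each class.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("auc requires both a positive and a negative label")
    ranks = rankdata(scores)  # mid-ranks handle ties as 1/2
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def _default_models(seed: int, params: Mapping[str, dict] | None = None):
    """Fresh unfitted estimators for the four slots.

    ``params`` overrides constructor keywords per model name.  Gradient
    boosting subsamples features per split (``max_features='sqrt'``) —
    with 560 mostly sparse descriptors this loses little accuracy and
    keeps training fast.
    """
    params = params or {}
    models = {
        "random_forest": RandomForestClassifier(
            n_estimators=200, random_state=seed, n_jobs=1,
            class_weight="balanced",
            **params.get("random_forest", {}),
        ),
        "gradient_boosting": GradientBoostingClassifier(
            n_estimators=150, max_depth=3, max_features="sqrt",
            random_state=seed,
            **params.get("gradient_boosting", {}),
        ),
        "linear_svm": Pipeline([
            ("scale", StandardScaler()),
            ("clf", CalibratedClassifierCV(
                LinearSVC(C=1.0, max_iter=20000, random_state=seed,
                          class_weight="balanced"),
                method="sigmoid", cv=3,
            )),
        ]),
        "minimal_tree": ExtraTreesClassifier(
            n_estimators=200, random_state=seed, n_jobs=1,
            class_weight="balanced",
            **params.get("minimal_tree", {}),
        ),
    }
    return models


@dataclass
class CVResult:
    """Fold-averaged held-out metrics for one model (counts summed)."""

    model: str
    auc: float
    accuracy: float
    precision: float
    recall: float
    mcc: float
    tp: int
    tn: int
    fp: int
    fn: int


@dataclass
class ModelBundle:
    """Four trained classifiers plus everything needed to score safely."""

    models: dict
    thresholds: dict[str, float]
    minimal_feature_names: tuple[str, ...]
    catalog_version: str
    training_seed: int
    folds: int

    def __post_init__(self):
        for name, t in self.thresholds.items():
            if not (0.0 < t < 1.0):
                raise ValueError(f"threshold for {name} must be in (0,1)")
        self._minimal_idx = np.array(
            [FEATURE_NAMES.index(n) for n in self.minimal_feature_names]
        )

    # -- scoring -----------------------------------------------------------

    def predict_matrix(self, X: pd.DataFrame | np.ndarray,
                       catalog_version: str | None = None) -> pd.DataFrame:
        """Probabilities for each row under all four models."""
        if isinstance(X, pd.DataFrame):
            version = X.attrs.get("catalog_version", catalog_version)
            values = X.to_numpy()
        else:
            version = catalog_version
            values = np.asarray(X)
        if version is not None and version != self.catalog_version:
            raise CatalogMismatchError(
                f"bundle was trained under catalog {self.catalog_version!r}, "
                f"got vectors from {version!r}"
            )
        probs = {}
        for name in MODEL_NAMES:
            cols = values[:, self._minimal_idx] if name == "minimal_tree" else values
            probs[name] = self.models[name].predict_proba(cols)[:, 1]
        return pd.DataFrame(probs)

    def predict(self, fv: FeatureVector) -> dict[str, float]:
        """Four probabilities for one feature vector."""
        if fv.catalog_version != self.catalog_version:
            raise CatalogMismatchError(
                f"bundle was trained under catalog {self.catalog_version!r}, "
                f"got a vector from {fv.catalog_version!r}"
            )
        row = self.predict_matrix(fv.values[None, :],
                                  catalog_version=fv.catalog_version)
        return {name: float(row[name].iloc[0]) for name in MODEL_NAMES}

    # -- persistence -------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Persist as a directory: joblib models + auditable manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        joblib.dump(self.models, directory / "models.joblib")
        manifest = {
            "catalog_version": self.catalog_version,
            "thresholds": self.thresholds,
            "training_seed": self.training_seed,
            "folds": self.folds,
            "minimal_feature_names": list(self.minimal_feature_names),
            "model_names": list(MODEL_NAMES),
        }
        (directory / "manifest.json").write_text(
            json.dumps(manifest, indent=2) + "\n"
        )

    @classmethod
    def load(cls, directory: str | Path) -> "ModelBundle":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        models = joblib.load(directory / "models.joblib")
        return cls(
            models=models,
            thresholds=manifest["thresholds"],
            minimal_feature_names=tuple(manifest["minimal_feature_names"]),
            catalog_version=manifest["catalog_version"],
            training_seed=manifest["training_seed"],
            folds=manifest["folds"],
        )


def call_positive(
    probs: Mapping[str, float],
    thresholds: Mapping[str, float] | None = None,
) -> tuple[dict[str, bool], bool]:
    """Per-model calls (probability strictly above threshold) and their OR."""
    thresholds = thresholds or DEFAULT_THRESHOLDS
    calls = {name: probs[name] > thresholds[name] for name in MODEL_NAMES}
    return calls, any(calls.values())


def select_minimal_features(
    pos: pd.DataFrame | np.ndarray,
    neg: pd.DataFrame | np.ndarray,
    k: int = DEFAULT_K_MINIMAL,
    seed: int = 0,
    feature_names: Sequence[str] = FEATURE_NAMES,
) -> tuple[str, ...]:
    """Top-k features by extra-trees impurity importance, deterministic."""
    if k > len(feature_names):
        raise ValueError(f"k={k} exceeds catalog size {len(feature_names)}")
    X = np.vstack([np.asarray(pos), np.asarray(neg)])
    y = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    et = ExtraTreesClassifier(n_estimators=200, random_state=seed, n_jobs=1)
    et.fit(X, y)
    order = np.argsort(et.feature_importances_)[::-1][:k]
    order = np.sort(order)  # stable catalog order within the subset
    return tuple(feature_names[i] for i in order)


def train(
    pos: pd.DataFrame,
    neg: pd.DataFrame,
    seed: int,
    folds: int = 6,
    k_minimal: int = DEFAULT_K_MINIMAL,
    thresholds: Mapping[str, float] | None = None,
    model_params: Mapping[str, dict] | None = None,
) -> tuple[ModelBundle, dict[str, CVResult]]:
    """Cross-validate and fit the four-model ensemble.

    ``pos`` and ``neg`` are feature matrices from
    :func:`neuropid.feature_extraction.extract_matrix` (identical column
    order).  Held-out metrics are computed per fold at a 0.5 probability
    cut (AUC is threshold-free) and averaged; confusion counts are summed
    across folds.  The returned bundle is refit on all data.
    """
    for df in (pos, neg):
        if isinstance(df, pd.DataFrame):
            version = df.attrs.get("catalog_version", CATALOG_VERSION)
            if version != CATALOG_VERSION:
                raise CatalogMismatchError(version)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both positive and negative sets must be nonempty")
    X = np.vstack([np.asarray(pos), np.asarray(neg)])
    y = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    if min(len(pos), len(neg)) < folds:
        raise ValueError(
            f"need at least {folds} examples per class for {folds}-fold CV"
        )

    templates = _default_models(seed, model_params)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))

    fold_stats: dict[str, list] = {name: [] for name in MODEL_NAMES}
    for train_idx, test_idx in splits:
        Xtr, Xte, ytr, yte = X[train_idx], X[test_idx], y[train_idx], y[test_idx]
        minimal_names = select_minimal_features(
            Xtr[ytr == 1], Xtr[ytr == 0], k=k_minimal, seed=seed)
        mi = np.array([FEATURE_NAMES.index(n) for n in minimal_names])
        for name in MODEL_NAMES:
            model = clone(templates[name])
            if name == "minimal_tree":
                model.fit(Xtr[:, mi], ytr)
                p = model.predict_proba(Xte[:, mi])[:, 1]
            else:
                model.fit(Xtr, ytr)
                p = model.predict_proba(Xte)[:, 1]
            pred = p > 0.5
            tp = int(np.sum(pred & (yte == 1)))
            tn = int(np.sum(~pred & (yte == 0)))
            fp = int(np.sum(pred & (yte == 0)))
            fn = int(np.sum(~pred & (yte == 1)))
            m = confusion_metrics(tp, tn, fp, fn)
            m.auc = auc(p, yte.astype(int))
            fold_stats[name].append(m)

    results = {}
    for name, ms in fold_stats.items():
        results[name] = CVResult(
            model=name,
            auc=float(np.mean([m.auc for m in ms])),
            accuracy=float(np.mean([m.accuracy for m in ms])),
            precision=float(np.mean([m.precision for m in ms])),
            recall=float(np.mean([m.recall for m in ms])),
            mcc=float(np.mean([m.mcc for m in ms])),
            tp=sum(m.tp for m in ms), tn=sum(m.tn for m in ms),
            fp=sum(m.fp for m in ms), fn=sum(m.fn for m in ms),
        )

    # final fit on all data
    minimal_names = select_minimal_features(
        X[y == 1], X[y == 0], k=k_minimal, seed=seed)
    mi = np.array([FEATURE_NAMES.index(n) for n in minimal_names])
    models = {}
    for name in MODEL_NAMES:
        model = clone(templates[name])
        if name == "minimal_tree":
            model.fit(X[:, mi], y)
        else:
            model.fit(X, y)
        models[name] = model

    bundle = ModelBundle(
        models=models,
        thresholds=dict(thresholds or DEFAULT_THRESHOLDS),
        minimal_feature_names=minimal_names,
        catalog_version=CATALOG_VERSION,
        training_seed=seed,
        folds=folds,
    )
    return bundle, results
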