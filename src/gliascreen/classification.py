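"""Cell-type classification: balanced training sets, random forest, CV,
feature importance and 2-D embedding.

The seven classes (neuron, microglia, astrocyte, other, condensed, necrotic,
debris) are learned from per-object features by a seeded random forest
("Random Trees", 100 trees, sqrt features per split by default).  Training
sets are balanced per class — and optionally between LPS strata — with
pool-limited classes flagged rather than silently upsampled.  Validation is
stratified k-fold cross-validation reported as a row-stochastic confusion
matrix with per-class recall and precision.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.metrics import confusion_matrix
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .simulate import CLASSES


class ClassificationError(ValueError):
    pass


@dataclass
class TrainingSet:
    features: pd.DataFrame          # feature columns only
    labels: np.ndarray              # class names, aligned with rows
    lps: np.ndarray | None = None   # optional LPS-stratum tags
    imbalanced_classes: list = field(default_factory=list)

    @property
    def per_class_counts(self) -> dict[str, int]:
        return pd.Series(self.labels).value_counts().to_dict()


@dataclass
class ClassifierModel:
    estimator: object
    feature_names: list[str]
    classes: list[str]
    seed: int
    hyperparams: dict = field(default_factory=dict)

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path) -> "ClassifierModel":
        with open(path, "rb") as fh:
            return pickle.load(fh)


@dataclass
class ConfusionSummary:
    matrix: pd.DataFrame            # actual x predicted, raw counts

    def normalized(self) -> pd.DataFrame:
        m = self.matrix.to_numpy(dtype=float)
        rs = m.sum(axis=1, keepdims=True)
        rs[rs == 0] = 1.0
        return pd.DataFrame(m / rs, index=self.matrix.index, columns=self.matrix.columns)

    @property
    def recall(self) -> pd.Series:
        m = self.matrix.to_numpy(dtype=float)
        denom = m.sum(axis=1)
        denom[denom == 0] = np.nan
        return pd.Series(np.diag(m) / denom, index=self.matrix.index)

    @property
    def precision(self) -> pd.Series:
        m = self.matrix.to_numpy(dtype=float)
        denom = m.sum(axis=0)
        denom[denom == 0] = np.nan
        return pd.Series(np.diag(m) / denom, index=self.matrix.columns)


def assemble_training_set(pool: pd.DataFrame, labels, per_class: int = 400,
                          feature_cols: list[str] | None = None,
                          lps=None, balance_lps: bool = False,
                          classes: tuple = CLASSES, seed: int = 0) -> TrainingSet:
    """Seeded sampling without replacement of ``per_class`` objects per class.

    Pool-limited classes contribute everything they have and are flagged.
    With ``balance_lps`` the sample is additionally split as evenly as the
    pool allows between LPS strata within each class.
    """
    labels = np.asarray(labels, dtype=object)
    if len(labels) != len(pool):
        raise ClassificationError("labels length does not match pool")
    if feature_cols is None:
        feature_cols = list(pool.columns)
    lps = None if lps is None else np.asarray(lps)
    rng = np.random.default_rng(seed)
    take_idx: list[np.ndarray] = []
    take_labels: list[np.ndarray] = []
    flagged = []
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        if idx.size == 0:
            raise ClassificationError(f"class {cls!r} absent from pool")
        if idx.size < per_class:
            chosen = idx
            flagged.append(cls)
        elif balance_lps and lps is not None:
            chosen_parts = []
            strata = [np.flatnonzero((labels == cls) & (lps == v)) for v in (False, True)]
            want = [per_class // 2, per_class - per_class // 2]
            # redistribute shortfalls between strata
            short = sum(max(0, w - s.size) for w, s in zip(want, strata))
            for i in range(2):
                if strata[i].size >= want[i] + short:
                    want[i] += short
                    short = 0
            for w, s in zip(want, strata):
                k = min(w, s.size)
                chosen_parts.append(rng.choice(s, size=k, replace=False))
            chosen = np.concatenate(chosen_parts)
            if chosen.size < per_class:
                flagged.append(cls)
        else:
            chosen = rng.choice(idx, size=per_class, replace=False)
        take_idx.append(chosen)
        take_labels.append(labels[chosen])
    sel = np.concatenate(take_idx)
    return TrainingSet(
        features=pool.iloc[sel][feature_cols].reset_index(drop=True),
        labels=np.concatenate(take_labels),
        lps=None if lps is None else lps[sel],
        imbalanced_classes=flagged,
    )


def train_classifier(ts: TrainingSet, seed: int = 0, model: str = "random_forest",
                     **hyperparams) -> ClassifierModel:
    """Fit the cell-type classifier (random forest by default, SVM optional)."""
    y = np.asarray(ts.labels, dtype=object)
    if len(np.unique(y)) < 2:
        raise ClassificationError("need at least two classes to train")
    X = ts.features.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ClassificationError("non-finite feature values")
    if model == "random_forest":
        params = dict(n_estimators=100, max_features="sqrt")
        params.update(hyperparams)
        est = RandomForestClassifier(random_state=seed, **params)
    elif model == "svm":
        params = dict(kernel="rbf", C=1.0, probability=True)
        params.update(hyperparams)
        est = SVC(random_state=seed, **params)
    else:
        raise ClassificationError(f"unknown model {model!r}")
    est.fit(X, y.astype(str))
    return ClassifierModel(estimator=est, feature_names=list(ts.features.columns),
                           classes=list(est.classes_), seed=seed,
                           hyperparams={"model": model, **params})


def classify_objects(model: ClassifierModel, ft: pd.DataFrame,
                     return_scores: bool = False):
    """Predict a class per row; errors if the feature columns mismatch."""
    missing = [c for c in model.feature_names if c not in ft.columns]
    if missing:
        raise ClassificationError(f"feature columns missing: {missing}")
    if len(ft) == 0:
        labels = np.array([], dtype=object)
        return (labels, pd.DataFrame(columns=model.classes)) if return_scores else labels
    X = ft[model.feature_names].to_numpy(dtype=float)
    labels = model.estimator.predict(X).astype(object)
    if return_scores:
        scores = pd.DataFrame(model.estimator.predict_proba(X),
                              columns=model.estimator.classes_, index=ft.index)
        return labels, scores
    return labels


def cross_validate(ts: TrainingSet, k: int = 5, seed: int = 0,
                   model: str = "random_forest", **hyperparams) -> ConfusionSummary:
    """Stratified k-fold cross-validation; out-of-fold predictions only."""
    if k < 2:
        raise ClassificationError("k must be >= 2")
    y = np.asarray(ts.labels, dtype=object).astype(str)
    counts = pd.Series(y).value_counts()
    low = counts[counts < k]
    if len(low):
        raise ClassificationError(
            f"classes with fewer than k={k} members: {list(low.index)}")
    X = ts.features.to_numpy(dtype=float)
    pred = np.empty_like(y)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for tr, te in skf.split(X, y):
        fold = TrainingSet(features=ts.features.iloc[tr], labels=y[tr])
        m = train_classifier(fold, seed=seed, model=model, **hyperparams)
        pred[te] = m.estimator.predict(X[te])
    present = [c for c in CLASSES if c in set(y)] or sorted(set(y))
    cm = confusion_matrix(y, pred, labels=present)
    return ConfusionSummary(matrix=pd.DataFrame(cm, index=present, columns=present))


def rank_feature_importance(model: ClassifierModel) -> pd.Series:
    """Impurity-based importances, descending; nonnegative, summing to 1."""
    est = model.estimator
    if not hasattr(est, "feature_importances_"):
        raise ClassificationError("model is unfitted or has no feature importances")
    imp = pd.Series(est.feature_importances_, index=model.feature_names)
    return imp.sort_values(ascending=False)


def embed_features(ft: pd.DataFrame, n_neighbors: int = 15,
                   min_dist: float = 0.1, seed: int = 0) -> np.ndarray:
    """Standardize features and embed to 2-D with UMAP; seeded."""
    import umap  # deferred: slow import

    X = ft.to_numpy(dtype=float)
    if len(X) < n_neighbors:
        raise ClassificationError(
            f"need at least n_neighbors={n_neighbors} rows, got {len(X)}")
    X = StandardScaler().fit_transform(X)
    reducer = umap.UMAP(n_neighbors=n_neighbors, min_dist=min_dist,
                        n_components=2, random_state=seed)
    return reducer.fit_transform(X)
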