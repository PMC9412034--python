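"""SVM training/evaluation, lead-subset search, feature ranking and PCA.

The classification task is binary chamber-of-origin (LVOT vs RVOT,
encoded LVOT=1, RVOT=0).  Three evaluation scenarios are supported:

* Sc1 — train on simulated-style (optionally mixup-augmented) beats;
* Sc2 — train on a (small, noisy) clinical-like set only;
* Sc3 — train on the hybrid concatenation of both.

Held-out test sets are scored with balanced accuracy (mean of per-class
recalls), robust to the ~3:1 right-sided class imbalance of clinical
populations; within-training cross-validation uses plain accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.decomposition import PCA
from sklearn.ensemble import ExtraTreesClassifier
from sklearn.metrics import accuracy_score, balanced_accuracy_score, confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, LinearSVC
from sklearn.utils.validation import check_is_fitted

from .preprocess import BeatPreprocessor
from .synthetic_ecg import Dataset

__all__ = [
    "CHAMBER_CODES",
    "encode_chamber",
    "SVMBeatClassifier",
    "balanced_accuracy",
    "CVResult",
    "cross_validate_accuracy",
    "LeadSearchResult",
    "exhaustive_lead_search",
    "FeatureRanking",
    "rank_features_extratrees",
    "pca_cumulative_variance",
    "ScenarioSpec",
    "EvaluationResult",
    "run_scenario",
]

#: Chamber label encoding used throughout: RVOT = 0, LVOT = 1.
CHAMBER_CODES: dict[str, int] = {"RVOT": 0, "LVOT": 1}


def encode_chamber(y) -> np.ndarray:
    """Map chamber labels (strings or SOOLabel-bearing values) to {0, 1}."""
    out = []
    for v in y:
        label = getattr(v, "label", v)
        name = getattr(label, "chamber", label)
        if name not in CHAMBER_CODES:
            raise ValueError(f"unknown chamber label {name!r}")
        out.append(CHAMBER_CODES[name])
    return np.asarray(out, dtype=int)


class SVMBeatClassifier(ClassifierMixin, BaseEstimator):
    """RBF-kernel SVM with optional feature standardization.

    ``gamma="scale"`` is the kernel-width rule 1 / (n_features x mean
    feature variance); per-sample weights (the mixup lambdas) are honored in
    the hinge loss.
    """

    def __init__(self, C: float = 1.0, gamma="scale", kernel: str = "rbf",
                 scale: bool = True, class_weight=None, random_state: int = 0):
        self.C = C
        self.gamma = gamma
        self.kernel = kernel
        self.scale = scale
        self.class_weight = class_weight
        self.random_state = random_state

    def _build(self):
        if self.C <= 0:
            raise ValueError("C must be > 0")
        svc = SVC(C=self.C, gamma=self.gamma, kernel=self.kernel,
                  class_weight=self.class_weight,
                  random_state=self.random_state, cache_size=500)
        steps = ([("scaler", StandardScaler()), ("svc", svc)]
                 if self.scale else [("svc", svc)])
        return Pipeline(steps)

    def fit(self, X, y, sample_weight=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one row per label")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training labels contain a single class")
        self.model_ = self._build()
        self.model_.fit(X, y, svc__sample_weight=sample_weight)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict(np.asarray(X, dtype=float))

    def decision_function(self, X):
        check_is_fitted(self, "model_")
        return self.model_.decision_function(np.asarray(X, dtype=float))


def balanced_accuracy(y_true, y_pred) -> float:
    """Unweighted mean of per-class recalls, in [0, 1]."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) == 0:
        raise ValueError("empty input")
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred lengths differ")
    return float(balanced_accuracy_score(y_true, y_pred))


@dataclass
class CVResult:
    mean_accuracy: float
    fold_accuracies: list[float]
    folds: int
    seed: int


def cross_validate_accuracy(
    X, y,
    model: BaseEstimator | None = None,
    folds: int = 5,
    seed: int = 0,
    sample_weight=None,
) -> CVResult:
    """Stratified k-fold CV; every sample is tested exactly once.

    Returns plain (unbalanced) fold accuracies and their mean.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples; needs >= {folds}"
        )
    if model is None:
        model = SVMBeatClassifier(random_state=seed)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for train_idx, test_idx in skf.split(X, y):
        m = clone(model)
        if sample_weight is not None:
            m.fit(X[train_idx], y[train_idx],
                  sample_weight=np.asarray(sample_weight)[train_idx])
        else:
            m.fit(X[train_idx], y[train_idx])
        accs.append(float(accuracy_score(y[test_idx], m.predict(X[test_idx]))))
    return CVResult(mean_accuracy=float(np.mean(accs)), fold_accuracies=accs,
                    folds=folds, seed=seed)


@dataclass
class LeadSearchResult:
    """Exhaustive lead-subset search bookkeeping.

    ``masks`` has one boolean row per non-empty subset (2^12 - 1 rows for 12
    leads); ``accuracies`` maps each test-set name to the per-subset
    balanced accuracies.
    """

    lead_names: tuple[str, ...]
    masks: np.ndarray
    accuracies: dict[str, np.ndarray]

    @property
    def n_subsets(self) -> int:
        return self.masks.shape[0]

    def lead_distribution(self, lead, test_name: str) -> np.ndarray:
        """Accuracies of every subset containing ``lead``."""
        idx = (self.lead_names.index(lead) if isinstance(lead, str) else lead)
        return self.accuracies[test_name][self.masks[:, idx]]

    def best_subsets(self, test_name: str, k: int = 24):
        order = np.argsort(self.accuracies[test_name])[::-1][:k]
        return [(tuple(np.array(self.lead_names)[self.masks[i]]),
                 float(self.accuracies[test_name][i])) for i in order]


def exhaustive_lead_search(
    train_raw: np.ndarray,
    y_train,
    test_sets: Mapping[str, tuple[np.ndarray, Sequence]],
    lead_names: Sequence[str] | None = None,
    fast: bool = False,
    C: float = 1.0,
    seed: int = 0,
) -> LeadSearchResult:
    """Train one SVM per non-empty lead subset of the raw bin representation.

    ``train_raw`` and each test matrix have shape ``(n_beats, n_leads,
    n_bins)``; subset feature vectors are the concatenated bins of the
    selected leads.  ``fast=True`` swaps the RBF SVM for a linear one, which
    keeps the full 4,095-subset sweep tractable.
    """
    train_raw = np.asarray(train_raw, dtype=float)
    if train_raw.ndim != 3:
        raise ValueError("train_raw must have shape (n, n_leads, n_bins)")
    n, n_leads, _ = train_raw.shape
    if lead_names is None:
        lead_names = tuple(f"L{i}" for i in range(n_leads))
    y_train = np.asarray(y_train)

    n_subsets = 2 ** n_leads - 1
    masks = np.zeros((n_subsets, n_leads), dtype=bool)
    accs = {name: np.zeros(n_subsets) for name in test_sets}
    for m in range(1, n_subsets + 1):
        row = m - 1
        mask = np.array([(m >> b) & 1 == 1 for b in range(n_leads)])
        masks[row] = mask
        Xtr = train_raw[:, mask, :].reshape(n, -1)
        if fast:
            model = LinearSVC(C=C, random_state=seed)
        else:
            model = SVC(C=C, kernel="rbf", gamma="scale", random_state=seed)
        model.fit(Xtr, y_train)
        for name, (Xte_raw, yte) in test_sets.items():
            Xte = np.asarray(Xte_raw, dtype=float)[:, mask, :].reshape(
                len(Xte_raw), -1)
            accs[name][row] = balanced_accuracy(yte, model.predict(Xte))
    return LeadSearchResult(lead_names=tuple(lead_names), masks=masks,
                            accuracies=accs)


@dataclass
class FeatureRanking:
    """Features ordered by decreasing mean impurity-decrease importance."""

    names: list[str]
    importances: np.ndarray
    dispersions: np.ndarray

    def top(self, k: int) -> list[str]:
        return self.names[:k]


def rank_features_extratrees(
    X, y,
    n_trees: int = 200,
    seed: int = 0,
    feature_names: Sequence[str] | None = None,
) -> FeatureRanking:
    """Extra-trees impurity-decrease feature ranking.

    Trees are fit on the whole training set (no bootstrap) with random split
    thresholds; importances are the forest means, dispersions the per-tree
    standard deviations.  A constant design matrix yields all-zero
    importances with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes to rank features")
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(X.shape[1])]
    forest = ExtraTreesClassifier(
        n_estimators=n_trees, bootstrap=False, criterion="gini",
        random_state=seed)
    forest.fit(X, y)
    per_tree = np.array([t.feature_importances_ for t in forest.estimators_])
    importances = np.nan_to_num(forest.feature_importances_)
    if importances.sum() == 0:
        warnings.warn("constant features: all importances are zero",
                      stacklevel=2)
    dispersions = per_tree.std(axis=0)
    order = np.argsort(importances)[::-1]
    return FeatureRanking(
        names=[feature_names[i] for i in order],
        importances=importances[order],
        dispersions=dispersions[order],
    )


def pca_cumulative_variance(X) -> np.ndarray:
    """Cumulative explained-variance curve of a full PCA of ``X``."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("PCA variance analysis needs at least 2 rows")
    pca = PCA(svd_solver="full")
    pca.fit(X)
    return np.cumsum(pca.explained_variance_ratio_)


@dataclass(frozen=True)
class ScenarioSpec:
    """One train/test composition: dataset keys plus a representation."""

    scenario_id: str
    train: tuple[str, ...]
    test: tuple[str, ...]
    representation: str = "raw10"  # raw10 | features | top10
    top_k: int = 10

    def __post_init__(self) -> None:
        if self.representation not in ("raw10", "features", "top10"):
            raise ValueError("representation must be raw10|features|top10")
        overlap = set(self.train) & set(self.test)
        if overlap:
            raise ValueError(f"train/test sets overlap: {sorted(overlap)}")


@dataclass
class EvaluationResult:
    scenario_id: str
    representation: str
    train: tuple[str, ...]
    test: tuple[str, ...]
    n_train: int
    cv_accuracy: float
    cv_fold_accuracies: list[float]
    test_balanced_accuracy: dict[str, float]
    confusion: dict[str, list[list[int]]]  # rows/cols ordered [RVOT, LVOT]
    seed: int
    selected_features: list[str] | None = None

    def to_dict(self) -> dict:
        return {
            "scenario_id": self.scenario_id,
            "representation": self.representation,
            "train": list(self.train),
            "test": list(self.test),
            "n_train": self.n_train,
            "cv_accuracy": self.cv_accuracy,
            "cv_fold_accuracies": self.cv_fold_accuracies,
            "test_balanced_accuracy": self.test_balanced_accuracy,
            "confusion": self.confusion,
            "seed": self.seed,
            "selected_features": self.selected_features,
        }


def _design(dataset: Dataset, representation: str, columns=None,
            window_ms: float = 200.0, n_bins: int = 10,
            use_true_fiducials: bool = True):
    """Design matrix + encoded labels + weights for one dataset."""
    from .features import extract_feature_matrix  # deferred: heavier import

    records = dataset.records
    y = encode_chamber(records)
    w = np.array([float(getattr(r, "sample_weight", 1.0)) for r in records])
    if representation == "raw10":
        pre = BeatPreprocessor(window_ms=window_ms, n_bins=n_bins,
                               use_true_fiducials=use_true_fiducials,
                               output="raw10")
        X = pre.fit_transform(dataset)
        names = list(pre.get_feature_names_out())
    else:
        frame = extract_feature_matrix(dataset, window_ms=window_ms,
                                       use_true_fiducials=use_true_fiducials,
                                       with_labels=False)
        if columns is not None:
            frame = frame[columns]
        names = list(frame.columns)
        X = frame.to_numpy(dtype=float)
    return X, y, w, names


def run_scenario(
    spec: ScenarioSpec,
    datasets: Mapping[str, Dataset],
    seed: int = 0,
    model: SVMBeatClassifier | None = None,
    folds: int = 5,
    window_ms: float = 200.0,
    n_bins: int = 10,
    use_true_fiducials: bool = True,
) -> EvaluationResult:
    """Train and evaluate one scenario composition.

    Training datasets are concatenated (augmented beats keep their lambda
    sample weights); cross-validation is pooled and stratified over the
    concatenation, and every held-out test set is scored with balanced
    accuracy plus 2x2 confusion counts (rows/cols ordered RVOT=0, LVOT=1).
    For the ``top10`` representation the features are ranked with
    extra-trees on the training set and the top ``spec.top_k`` retained.
    """
    missing = [k for k in (*spec.train, *spec.test) if k not in datasets]
    if missing:
        raise KeyError(f"unknown dataset keys: {missing}")

    base_repr = "features" if spec.representation == "top10" else spec.representation
    parts = [
        _design(datasets[k], base_repr, window_ms=window_ms, n_bins=n_bins,
                use_true_fiducials=use_true_fiducials)
        for k in spec.train
    ]
    X = np.vstack([p[0] for p in parts])
    y = np.concatenate([p[1] for p in parts])
    w = np.concatenate([p[2] for p in parts])
    names = parts[0][3]

    selected = None
    if spec.representation == "top10":
        ranking = rank_features_extratrees(X, y, seed=seed,
                                           feature_names=names)
        selected = ranking.top(spec.top_k)
        cols = [names.index(c) for c in selected]
        X = X[:, cols]

    if model is None:
        # raw10 values already share the normalized [-1, 1] scale; its
        # near-constant edge bins make standardization noise-amplifying.
        model = SVMBeatClassifier(random_state=seed,
                                  scale=(base_repr != "raw10"))
    cv = cross_validate_accuracy(X, y, model=model, folds=folds, seed=seed,
                                 sample_weight=w)
    final = clone(model)
    final.fit(X, y, sample_weight=w)

    test_ba: dict[str, float] = {}
    confusion: dict[str, list[list[int]]] = {}
    for k in spec.test:
        Xte, yte, _, te_names = _design(
            datasets[k], base_repr, window_ms=window_ms, n_bins=n_bins,
            use_true_fiducials=use_true_fiducials)
        if selected is not None:
            cols = [te_names.index(c) for c in selected]
            Xte = Xte[:, cols]
        pred = final.predict(Xte)
        test_ba[k] = balanced_accuracy(yte, pred)
        confusion[k] = confusion_matrix(yte, pred, labels=[0, 1]).tolist()

    return EvaluationResult(
        scenario_id=spec.scenario_id,
        representation=spec.representation,
        train=spec.train,
        test=spec.test,
        n_train=len(y),
        cv_accuracy=cv.mean_accuracy,
        cv_fold_accuracies=cv.fold_accuracies,
        test_balanced_accuracy=test_ba,
        confusion=confusion,
        seed=seed,
        selected_features=selected,
    )
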