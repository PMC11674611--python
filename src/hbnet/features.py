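"""Hybrid network features and the cross-validated evaluation protocol.

A hybrid network H = concat(G, C) glues the c x c causal matrix and the
c x d coupling matrix of one window column-wise into a c x (c+d) matrix
(62 x 80 for a 62-region atlas with 18 fNIRS channels). Row-major
vectorisation of H (or of G or C alone) gives the feature vector of
that window; stacking windows gives a feature set.

Evaluation replicates a standard protocol: stratified 5-fold
cross-validation repeated 5 times with reseeded fold assignments,
linear-kernel SVM (C = 1) and 10-nearest-neighbour classifiers,
accuracy averaged over folds per repetition and summarised as
mean +/- sd over all folds. Features are z-scored with statistics
fitted on the training folds only. Fold assignment defaults to the
window-sample level (matching the reference protocol); trial-level
folds are available because 1.5 s window overlap leaks information
between sample-level folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import GroupKFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .containers import CausalMatrix, CouplingMatrix, FeatureSet, HybridNetwork
from .errors import AlignmentError, DataError, ProtocolError

__all__ = ["hybrid", "vectorize", "build_feature_set", "evaluate", "EvalResult"]


def hybrid(gs: CausalMatrix, cs: CouplingMatrix) -> HybridNetwork:
    """Concatenate a window's causal and coupling matrices column-wise."""
    if gs.window != cs.window:
        raise AlignmentError(
            f"causal window {gs.window} and coupling window {cs.window} differ"
        )
    if gs.g.shape[0] != cs.cs.shape[0]:
        raise AlignmentError(
            f"row counts differ: causal {gs.g.shape[0]} vs coupling {cs.cs.shape[0]}"
        )
    return HybridNetwork(h=np.concatenate([gs.g, cs.cs], axis=1), window=gs.window)


def vectorize(h: HybridNetwork | np.ndarray) -> np.ndarray:
    """Row-major flattening of a network matrix; stable feature ordering."""
    m = h.h if isinstance(h, HybridNetwork) else np.asarray(h, dtype=float)
    if not np.all(np.isfinite(m)):
        raise DataError("network matrix contains NaN or inf")
    return m.reshape(-1, order="C").copy()


def build_feature_set(
    matrices: list[np.ndarray],
    labels: list[int],
    feature_kind: str,
    subject: str = "sub-01",
    groups: list[int] | None = None,
) -> FeatureSet:
    """Stack vectorised window networks into a feature set.

    ``groups`` (one trial id per window) enables trial-level folding.
    """
    X = np.stack([vectorize(m) for m in matrices])
    fs = FeatureSet(
        matrix=X, labels=np.asarray(labels, dtype=int), feature_kind=feature_kind, subject=subject
    )
    fs.groups = np.asarray(groups, dtype=int) if groups is not None else None
    return fs


@dataclass
class EvalResult:
    accuracy_mean: float
    accuracy_sd: float
    per_class: dict[int, float]
    confusion: np.ndarray  # row-normalised, rows = true class
    fold_accuracies: list[float] = field(default_factory=list)
    classifier: str = ""
    feature_kind: str = ""

    def to_dict(self) -> dict:
        return {
            "accuracy_mean": self.accuracy_mean,
            "accuracy_sd": self.accuracy_sd,
            "per_class": {str(k): v for k, v in self.per_class.items()},
            "confusion": self.confusion.tolist(),
            "fold_accuracies": self.fold_accuracies,
            "classifier": self.classifier,
            "feature_kind": self.feature_kind,
        }


def _make_classifier(name: str):
    if name == "svm_linear":
        return make_pipeline(StandardScaler(), SVC(kernel="linear", C=1.0))
    if name == "knn10":
        return make_pipeline(StandardScaler(), KNeighborsClassifier(n_neighbors=10))
    raise ValueError(f"unknown classifier {name!r} (use svm_linear or knn10)")


def evaluate(
    fs: FeatureSet,
    classifier: str = "svm_linear",
    k_folds: int = 5,
    repeats: int = 5,
    seed: int = 0,
    fold_unit: str = "sample",
) -> EvalResult:
    """Repeated stratified k-fold cross-validation of one feature set.

    Returns overall accuracy (mean +/- sd over all folds of all
    repetitions), per-class accuracy, and the row-normalised confusion
    matrix aggregated over every held-out prediction.
    """
    X, y = fs.matrix, fs.labels
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ProtocolError("need at least two classes")
    if counts.min() < k_folds:
        raise ProtocolError(
            f"class {classes[np.argmin(counts)]} has {counts.min()} samples < {k_folds} folds"
        )
    groups = getattr(fs, "groups", None)
    accs: list[float] = []
    conf = np.zeros((classes.size, classes.size))
    rng = np.random.default_rng(seed)
    for _ in range(repeats):
        rep_seed = int(rng.integers(2**31))
        if fold_unit == "trial" and groups is not None:
            # shuffle groups deterministically, then contiguous group folds
            splitter = GroupKFold(n_splits=k_folds)
            perm = np.random.default_rng(rep_seed).permutation(len(np.unique(groups)))
            gmap = {g: perm[i] for i, g in enumerate(np.unique(groups))}
            folds = splitter.split(X, y, np.asarray([gmap[g] for g in groups]))
        else:
            splitter = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=rep_seed)
            folds = splitter.split(X, y)
        for train, test in folds:
            clf = _make_classifier(classifier)
            clf.fit(X[train], y[train])
            pred = clf.predict(X[test])
            accs.append(float(np.mean(pred == y[test])))
            conf += _sk_confusion(y[test], pred, labels=classes)
    row_sums = conf.sum(axis=1, keepdims=True)
    conf_norm = np.divide(conf, row_sums, out=np.zeros_like(conf), where=row_sums > 0)
    per_class = {int(cl): float(conf_norm[i, i]) for i, cl in enumerate(classes)}
    return EvalResult(
        accuracy_mean=float(np.mean(accs)),
        accuracy_sd=float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
        per_class=per_class,
        confusion=conf_norm,
        fold_accuracies=accs,
        classifier=classifier,
        feature_kind=fs.feature_kind,
    )
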