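"""Cluster-pairing ensemble SVMs and the plain-SVM baseline.

Diagnostic groups such as ASD are heterogeneous: a single hyperplane can be
a poor fit when each class is itself a mixture of subtypes.  The
cluster-pairing ensemble first splits each class into ``c`` subgroups by
unsupervised clustering — either multi-kernel similarity learning
(``strategy="simlr"``) or Ward's hierarchical clustering
(``strategy="hwc"``) — then trains one linear SVM per (class-A subgroup,
class-B subgroup) pairing, giving up to c^2 classifiers whose majority vote
labels new subjects.  Each member classifier's within-pairing leave-one-out
accuracy is recorded as a diagnostic.
"""

from __future__ import annotations

import warnings
from itertools import product

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.svm import SVC
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .embedding import ward_cluster
from .simlr import SIMLR


def make_svm(C: float = 1.0, class_weight=None) -> SVC:
    """Shared linear-SVM factory for the baseline and ensemble members."""
    return SVC(kernel="linear", C=C, class_weight=class_weight)


def split_within_class(features: np.ndarray, c: int, strategy: str = "simlr",
                       seed: int = 0, simlr_params: dict | None = None) -> np.ndarray:
    """Cluster one class's subjects into (at most) c subgroups.

    If the class holds fewer subjects than requested subgroups, the subgroup
    count is reduced (with a warning).  ``c = 1`` returns a single subgroup.
    """
    features = np.asarray(features, dtype=float)
    n = features.shape[0]
    if n < 2:
        raise ValueError("cannot split a class with fewer than 2 subjects")
    c_eff = min(c, n)
    if strategy == "simlr":
        # the spectral latent needs c < n
        c_eff = min(c_eff, n - 1)
    if c_eff < c:
        warnings.warn(
            f"subgroup count reduced from {c} to {c_eff} for a class of size {n}",
            RuntimeWarning, stacklevel=2,
        )
    if c_eff <= 1:
        return np.zeros(n, dtype=int)
    if strategy == "simlr":
        model = SIMLR(n_clusters=c_eff, random_state=seed,
                      **(simlr_params or {}))
        return model.fit_predict(features)
    if strategy == "hwc":
        return ward_cluster(features, c_eff)
    raise ValueError(f"unknown split strategy {strategy!r}")


def build_pairings(asd_subgroups: list[np.ndarray],
                   nc_subgroups: list[np.ndarray]) -> list[np.ndarray]:
    """Cartesian pairings of subgroup index sets; empty subgroups dropped."""
    a = [np.asarray(g, dtype=int) for g in asd_subgroups if len(g)]
    b = [np.asarray(g, dtype=int) for g in nc_subgroups if len(g)]
    if not a or not b:
        raise ValueError("need at least one non-empty subgroup per class")
    return [np.concatenate([ga, gb]) for ga, gb in product(a, b)]


def _loo_accuracy(clf_proto, X: np.ndarray, y: np.ndarray) -> float:
    """Leave-one-out accuracy; a single-class training split predicts its class."""
    n = len(y)
    correct = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        y_tr = y[mask]
        if len(np.unique(y_tr)) < 2:
            pred = y_tr[0]
        else:
            pred = clone(clf_proto).fit(X[mask], y_tr).predict(X[i : i + 1])[0]
        correct += pred == y[i]
    return correct / n


class ClusterPairingSVC(BaseEstimator, ClassifierMixin):
    """Ensemble of linear SVMs over paired within-class subgroups.

    Parameters
    ----------
    n_subgroups : int, default 4
        Number of subgroups c per class; up to c^2 pairings are formed.
    strategy : {"simlr", "hwc"}
        Within-class clustering used to form the subgroups.
    C : float
        SVM regularization (shared by every member).
    class_weight : None or "balanced", default "balanced"
        Passed to every member SVM; pairings of unequal subgroup sizes are
        otherwise dominated by the larger class.
    compute_loo : bool
        Record each member's within-pairing leave-one-out accuracy.

    Attributes
    ----------
    classes_ : ndarray of the two class labels (sorted).
    pairings_ : list of index arrays into the training set, one per member.
    estimators_ : the trained member SVMs.
    loo_scores_ : per-member LOO accuracy (NaN when not computed).
    subgroup_labels_ : dict mapping class label -> subgroup assignment.
    """

    def __init__(self, n_subgroups: int = 4, *, strategy: str = "simlr",
                 C: float = 1.0, class_weight="balanced", compute_loo: bool = True,
                 simlr_params: dict | None = None, random_state: int | None = 0):
        self.n_subgroups = n_subgroups
        self.strategy = strategy
        self.C = C
        self.class_weight = class_weight
        self.compute_loo = compute_loo
        self.simlr_params = simlr_params
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("ClusterPairingSVC is a binary classifier")
        seed = self.random_state if self.random_state is not None else 0
        subgroups: dict = {}
        per_class_groups: list[list[np.ndarray]] = []
        for offset, cls in enumerate(self.classes_):
            idx = np.flatnonzero(y == cls)
            if self.n_subgroups <= 1 or len(idx) <= 2:
                assign = np.zeros(len(idx), dtype=int)
            else:
                assign = split_within_class(
                    X[idx], self.n_subgroups, strategy=self.strategy,
                    seed=seed + offset, simlr_params=self.simlr_params,
                )
            subgroups[cls] = assign
            per_class_groups.append(
                [idx[assign == g] for g in range(assign.max() + 1)]
            )
        self.subgroup_labels_ = subgroups
        pairings = build_pairings(per_class_groups[0], per_class_groups[1])

        proto = make_svm(C=self.C, class_weight=self.class_weight)
        self.pairings_ = []
        self.estimators_ = []
        self.loo_scores_ = []
        for pairing in pairings:
            y_p = y[pairing]
            if len(np.unique(y_p)) < 2:
                warnings.warn("skipping a single-class pairing", RuntimeWarning,
                              stacklevel=2)
                continue
            clf = clone(proto).fit(X[pairing], y_p)
            self.pairings_.append(pairing)
            self.estimators_.append(clf)
            self.loo_scores_.append(
                _loo_accuracy(proto, X[pairing], y_p) if self.compute_loo
                else float("nan")
            )
        if not self.estimators_:
            raise ValueError("no valid pairing contained both classes")
        return self

    def decision_function(self, X):
        """Summed signed decision values across the ensemble members."""
        check_is_fitted(self, "estimators_")
        X = check_array(X, dtype=float)
        return np.sum([clf.decision_function(X) for clf in self.estimators_], axis=0)

    def predict(self, X):
        """Majority vote; exact ties go to the sign of the summed margins,
        and a summed margin of exactly zero to ``classes_[1]``."""
        check_is_fitted(self, "estimators_")
        X = check_array(X, dtype=float)
        votes = np.stack([clf.predict(X) for clf in self.estimators_])  # members x n
        n = X.shape[0]
        counts = np.stack(
            [(votes == cls).sum(axis=0) for cls in self.classes_]
        )  # 2 x n
        pred = np.where(counts[0] > counts[1], self.classes_[0], self.classes_[1])
        tie = counts[0] == counts[1]
        if tie.any():
            margins = self.decision_function(X[tie])
            # decision_function > 0 points at classes_[1]; exact 0 -> classes_[1]
            pred[tie] = np.where(margins < 0, self.classes_[0], self.classes_[1])
        return pred


def svm_baseline(train_X, train_y, test_X, test_y=None, *, C: float = 1.0,
                 class_weight="balanced"):
    """Single linear-SVM baseline; returns held-out accuracy (or predictions).

    Trained through the same SVM factory as the ensemble members, so a
    pairing ensemble with c = 1 reproduces it exactly.
    """
    train_X, train_y = check_X_y(train_X, train_y, dtype=float)
    if len(np.unique(train_y)) < 2:
        raise ValueError("baseline SVM needs both classes in the training set")
    clf = make_svm(C=C, class_weight=class_weight).fit(train_X, train_y)
    pred = clf.predict(check_array(test_X, dtype=float))
    if test_y is None:
        return pred
    return float(np.mean(pred == np.asarray(test_y)))
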