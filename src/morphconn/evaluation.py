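"""Clustering purity and the repeated k-fold evaluation harness.

The *performance rate* of a clustering against binary diagnostic labels is
cluster purity: each cluster is mapped to its majority true label and the
rate is the fraction of subjects whose label matches their cluster's
majority, ``1 - misclassified / n``.  The harness shuffles and splits the
cohort into k folds, evaluates the chosen method per fold — clustering
methods cluster the training portion into c groups and score purity there;
supervised methods train on the training folds and score held-out accuracy
— and averages over folds, then over a number of independent repeats.
Everything is driven by a single integer seed and is bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import adjusted_rand_score
from sklearn.model_selection import KFold

from .embedding import ward_cluster
from .ensemble import ClusterPairingSVC, svm_baseline
from .simlr import SIMLR

CLUSTERING_METHODS = ("simlr", "ward")
SUPERVISED_METHODS = ("svm", "simlr_pair_svm", "hwc_pair_svm")


def performance_rate(assignments: np.ndarray, true_labels: np.ndarray) -> float:
    """Majority-mapping cluster purity in [0, 1]."""
    assignments = np.asarray(assignments)
    true_labels = np.asarray(true_labels)
    if assignments.shape != true_labels.shape:
        raise ValueError("assignments and labels must have equal length")
    if "unknown" in set(np.asarray(true_labels, dtype=str)):
        raise ValueError("performance rate needs known binary labels")
    classes = np.unique(true_labels)
    if len(classes) > 2:
        raise ValueError("performance rate is defined for binary labels")
    n = len(true_labels)
    misclassified = 0
    for cluster in np.unique(assignments):
        members = true_labels[assignments == cluster]
        majority = max((np.sum(members == cls) for cls in classes))
        misclassified += len(members) - majority
    return 1.0 - misclassified / n


@dataclass
class CVResult:
    mean_rate: float
    per_repeat: list[float]
    per_fold: list[list[float]]
    method: str
    k_folds: int
    ari_per_repeat: list[float] = field(default_factory=list)

    @property
    def mean_ari(self) -> float:
        return float(np.mean(self.ari_per_repeat)) if self.ari_per_repeat else float("nan")


def _eval_clustering_fold(method, features, labels, train_idx, test_idx, c,
                          seed, method_params, score_heldout):
    X_tr = features[train_idx]
    y_tr = labels[train_idx]
    if method == "simlr":
        model = SIMLR(n_clusters=c, random_state=seed, **(method_params or {}))
        assign = model.fit_predict(X_tr)
    else:
        assign = ward_cluster(X_tr, c)
    rate = performance_rate(assign, y_tr)
    ari = adjusted_rand_score(y_tr, assign)
    if score_heldout and len(test_idx):
        # out-of-sample rule: nearest training-cluster centroid in feature
        # space, scored with the training cluster's majority label
        centroids, majority = [], []
        classes = np.unique(y_tr)
        for cluster in np.unique(assign):
            mask = assign == cluster
            centroids.append(X_tr[mask].mean(axis=0))
            counts = [np.sum(y_tr[mask] == cls) for cls in classes]
            majority.append(classes[int(np.argmax(counts))])
        centroids = np.vstack(centroids)
        X_te = features[test_idx]
        d2 = ((X_te[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=-1)
        pred = np.asarray(majority)[np.argmin(d2, axis=1)]
        heldout_rate = float(np.mean(pred == labels[test_idx]))
        return rate, ari, heldout_rate
    return rate, ari, None


def _eval_supervised_fold(method, features, labels, train_idx, test_idx,
                          c, seed, method_params):
    y_tr = labels[train_idx]
    if len(np.unique(y_tr)) < 2:
        warnings.warn("skipping a fold whose training split has one class",
                      RuntimeWarning, stacklevel=2)
        return None
    X_tr, X_te = features[train_idx], features[test_idx]
    if method == "svm":
        return svm_baseline(X_tr, y_tr, X_te, labels[test_idx],
                            **(method_params or {}))
    strategy = "simlr" if method == "simlr_pair_svm" else "hwc"
    clf = ClusterPairingSVC(n_subgroups=c, strategy=strategy,
                            random_state=seed, compute_loo=False,
                            **(method_params or {}))
    clf.fit(X_tr, y_tr)
    return float(np.mean(clf.predict(X_te) == labels[test_idx]))


def cv_evaluate(features: np.ndarray, labels: np.ndarray, method: str = "simlr",
                k_folds: int = 5, repeats: int = 20, seed: int = 0,
                n_clusters: int = 4, method_params: dict | None = None,
                score_heldout: bool = False) -> CVResult:
    """Repeated k-fold evaluation of a clustering or supervised method.

    ``method`` is one of ``simlr`` / ``ward`` (unsupervised: purity of the
    clustered training portion; with ``score_heldout`` the held-out fold is
    additionally scored by nearest-centroid transfer and the held-out rate
    is reported instead) or ``svm`` / ``simlr_pair_svm`` / ``hwc_pair_svm``
    (supervised held-out accuracy).
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    n = features.shape[0]
    if n < k_folds:
        raise ValueError(f"n={n} is smaller than k_folds={k_folds}")
    if method not in CLUSTERING_METHODS + SUPERVISED_METHODS:
        raise ValueError(f"unknown method {method!r}")

    rng = np.random.default_rng(seed)
    per_repeat, per_fold_all, ari_per_repeat = [], [], []
    for _ in range(repeats):
        repeat_seed = int(rng.integers(0, 2**31 - 1))
        kf = KFold(n_splits=k_folds, shuffle=True, random_state=repeat_seed)
        fold_rates, fold_aris = [], []
        for fold_i, (train_idx, test_idx) in enumerate(kf.split(features)):
            fold_seed = (repeat_seed + fold_i) % (2**31 - 1)
            if method in CLUSTERING_METHODS:
                rate, ari, heldout = _eval_clustering_fold(
                    method, features, labels, train_idx, test_idx,
                    n_clusters, fold_seed, method_params, score_heldout)
                fold_rates.append(heldout if score_heldout else rate)
                fold_aris.append(ari)
            else:
                acc = _eval_supervised_fold(
                    method, features, labels, train_idx, test_idx,
                    n_clusters, fold_seed, method_params)
                if acc is not None:
                    fold_rates.append(acc)
        per_fold_all.append(fold_rates)
        per_repeat.append(float(np.mean(fold_rates)))
        if fold_aris:
            ari_per_repeat.append(float(np.mean(fold_aris)))
    return CVResult(mean_rate=float(np.mean(per_repeat)), per_repeat=per_repeat,
                    per_fold=per_fold_all, method=method, k_folds=k_folds,
                    ari_per_repeat=ari_per_repeat)


def permutation_null_rate(features: np.ndarray, labels: np.ndarray,
                          method: str = "simlr", k_folds: int = 5,
                          repeats: int = 20, seed: int = 0,
                          n_clusters: int = 4,
                          method_params: dict | None = None) -> CVResult:
    """The same harness with labels permuted once per repeat.

    This is the proper chance level of the purity statistic: with c clusters
    of finite size, majority mapping sits above the majority-class
    proportion even for random labels, and the permutation null reproduces
    that finite-cluster bias.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed + 1)
    per_repeat = []
    for r in range(repeats):
        perm = rng.permutation(len(labels))
        res = cv_evaluate(features, labels[perm], method=method,
                          k_folds=k_folds, repeats=1,
                          seed=int(rng.integers(0, 2**31 - 1)),
                          n_clusters=n_clusters, method_params=method_params)
        per_repeat.append(res.mean_rate)
    return CVResult(mean_rate=float(np.mean(per_repeat)), per_repeat=per_repeat,
                    per_fold=[], method=f"{method}(permuted)", k_folds=k_folds)
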