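"""Low-order and high-order morphological brain networks.

A *low-order* network (LON) for one cortical attribute connects ROIs *i* and
*j* with the absolute difference of their mean attribute values,
``X[i, j] = |x_i - x_j|``.  Stacking one such view per attribute gives the
subject's brain tensor.  The *high-order* network (HON) goes one level up:
for every ROI pair (i, j) collect its edge weights across the ``n_v`` views
into an edge vector ``y_ij``, then connect two ROI *pairs* by the Pearson
correlation of their edge vectors, ``H[(i,j), (p,q)] = corr(y_ij, y_pq)``.
The HON is a P x P matrix over the P = n_r (n_r - 1) / 2 ROI pairs and
captures how the morphological relationship of one pair of regions co-varies
with that of another across attributes.

Feature vectors are the strict upper triangles (row-major, i < j; the
diagonal is zero by construction and excluded): views concatenated
view-by-view for the LON (length ``n_v * P``) and the upper triangle of H for
the HON (length ``P (P - 1) / 2``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import AttributeTable, Cohort


def roi_pairs(n_r: int) -> list[tuple[int, int]]:
    """Ordered ROI pairs (i, j), i < j, lexicographic, 0-based."""
    return [(i, j) for i in range(n_r) for j in range(i + 1, n_r)]


def n_pairs(n_r: int) -> int:
    return n_r * (n_r - 1) // 2


@dataclass
class BrainTensor:
    """Stack of n_v symmetric, zero-diagonal LON views for one subject."""

    views: np.ndarray  # n_v x n_r x n_r
    subject_id: str = ""
    attribute_names: list[str] | None = None

    @property
    def n_v(self) -> int:
        return self.views.shape[0]

    @property
    def n_r(self) -> int:
        return self.views.shape[1]

    def edge_vectors(self) -> np.ndarray:
        """P x n_v matrix whose rows are the edge vectors y_ij."""
        iu, ju = np.triu_indices(self.n_r, k=1)
        return self.views[:, iu, ju].T


@dataclass
class HONMatrix:
    """P x P high-order network with zero diagonal and entries in [-1, 1]."""

    H: np.ndarray
    pair_index: list[tuple[int, int]]

    @property
    def P(self) -> int:
        return self.H.shape[0]


@dataclass
class FeatureVector:
    h: np.ndarray
    kind: str  # "LON_concat" or "HON_upper"
    index_map: list  # position -> (view, (i, j)) or ((i, j), (p, q))


def build_lon_view(x: np.ndarray) -> np.ndarray:
    """Absolute-difference network of one attribute's ROI mean vector."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("attribute vector must be 1-D")
    if not np.all(np.isfinite(x)):
        bad = int(np.flatnonzero(~np.isfinite(x))[0])
        raise ValueError(f"non-finite attribute value at ROI index {bad}")
    return np.abs(x[:, None] - x[None, :])


def build_tensor(subject: AttributeTable) -> BrainTensor:
    """One LON view per cortical attribute, stacked into the subject tensor."""
    views = np.stack([build_lon_view(subject.values[:, k]) for k in range(subject.n_v)])
    return BrainTensor(
        views=views,
        subject_id=subject.subject_id,
        attribute_names=list(subject.attribute_names),
    )


def lon_index_map(n_r: int, n_v: int) -> list[tuple[int, tuple[int, int]]]:
    """position -> (view, (i, j)) for the concatenated LON feature vector."""
    pairs = roi_pairs(n_r)
    return [(k, p) for k in range(n_v) for p in pairs]


def extract_lon_features(t: BrainTensor) -> FeatureVector:
    """Strict upper triangles of all views, concatenated view-by-view."""
    iu, ju = np.triu_indices(t.n_r, k=1)
    h = np.concatenate([t.views[k][iu, ju] for k in range(t.n_v)])
    return FeatureVector(h=h, kind="LON_concat", index_map=lon_index_map(t.n_r, t.n_v))


def build_hon(t: BrainTensor, degenerate_policy: str = "zero") -> HONMatrix:
    """Pearson correlation between edge vectors of every two ROI pairs.

    An edge vector with zero variance across views has no defined
    correlation; under ``degenerate_policy="zero"`` its row and column are
    set to 0 (with a warning), under ``"error"`` the pair is reported and
    construction aborts.  The diagonal is forced to 0.
    """
    if t.n_v < 2:
        raise ValueError("HON needs at least 2 views")
    Y = t.edge_vectors()  # P x n_v
    pairs = roi_pairs(t.n_r)
    sd = Y.std(axis=1)
    degenerate = sd == 0.0
    if degenerate.any():
        which = [pairs[a] for a in np.flatnonzero(degenerate)]
        if degenerate_policy == "error":
            raise ValueError(f"zero-variance edge vector(s) for ROI pairs {which}")
        warnings.warn(
            f"zero-variance edge vector(s) for ROI pairs {which}; "
            "their correlations are set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    Yc = Y - Y.mean(axis=1, keepdims=True)
    denom = np.where(degenerate, 1.0, sd * np.sqrt(Y.shape[1]))
    Z = Yc / denom[:, None]
    H = Z @ Z.T
    H[degenerate, :] = 0.0
    H[:, degenerate] = 0.0
    np.clip(H, -1.0, 1.0, out=H)
    H = (H + H.T) / 2.0
    np.fill_diagonal(H, 0.0)
    return HONMatrix(H=H, pair_index=pairs)


def hon_index_map(n_r: int) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """position -> ((i, j), (p, q)) for the HON upper-triangle features."""
    pairs = roi_pairs(n_r)
    P = len(pairs)
    return [(pairs[a], pairs[b]) for a in range(P) for b in range(a + 1, P)]


def extract_hon_features(hon: HONMatrix) -> FeatureVector:
    """Strict upper triangle of the HON matrix, row-major."""
    P = hon.P
    iu, ju = np.triu_indices(P, k=1)
    n_r = max(j for _, j in hon.pair_index) + 1
    return FeatureVector(h=hon.H[iu, ju], kind="HON_upper", index_map=hon_index_map(n_r))


def cohort_features(
    cohort: Cohort, order: str = "high", degenerate_policy: str = "zero"
) -> tuple[np.ndarray, list]:
    """Feature matrix (subjects x features) for a whole cohort.

    ``order="low"`` concatenates all LON views (CON features); ``"high"``
    uses the HON upper triangle.  Returns the matrix and the shared index
    map resolving feature positions back to ROI pairs/views.
    """
    rows = []
    index_map: list = []
    for s in cohort:
        t = build_tensor(s)
        if order == "low":
            fv = extract_lon_features(t)
        elif order == "high":
            fv = extract_hon_features(build_hon(t, degenerate_policy=degenerate_policy))
        else:
            raise ValueError("order must be 'low' or 'high'")
        rows.append(fv.h)
        index_map = fv.index_map
    return np.vstack(rows), index_map


def describe_feature(index_entry, roi_names: list[str], attribute_names: list[str] | None = None) -> str:
    """Human-readable description of one feature-map entry."""
    first = index_entry[0]
    if isinstance(first, (int, np.integer)):  # LON: (view, (i, j))
        k, (i, j) = index_entry
        attr = attribute_names[k] if attribute_names else f"view{k}"
        return f"({roi_names[i]}, {roi_names[j]}) @ {attr}"
    (i, j), (p, q) = index_entry
    return (
        f"(({roi_names[i]}, {roi_names[j]}), ({roi_names[p]}, {roi_names[q]}))"
    )
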