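"""Shared data structures, validation, pairwise distances and stratified selection.

Every selector in this package consumes either a feature matrix ``X`` of
shape ``(s, d)`` (binary or real valued) or a precomputed symmetric pairwise
distance matrix ``D`` of shape ``(s, s)``, and returns an ordered list of
selected sample indices.  This module holds the pieces they all share:
input validation, distance-matrix construction for built-in and user-defined
metrics, medoid finding, and the label-stratified wrapper that runs any
selector independently within each class under proportional quotas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform

__all__ = [
    "BaseSubsetSelector",
    "SelectionResult",
    "validate_feature_matrix",
    "validate_distance_matrix",
    "is_binary",
    "compute_pairwise_distances",
    "medoid",
    "stratified_quotas",
    "stratified_select",
]

_SYMMETRY_TOL = 1e-8
_MATRIX_SYMMETRY_TOL = 1e-10


@dataclass
class SelectionResult:
    """Ordered selection of sample indices with provenance.

    Attributes
    ----------
    indices : list of int
        Selected sample indices (0-based) in selection order.
    method : str
        Identifier of the selector that produced this result.
    params : dict
        Parameters of the run, including the seed for stochastic selectors.
    """

    indices: list[int]
    method: str = ""
    params: dict = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.indices)

    def __post_init__(self) -> None:
        idx = [int(i) for i in self.indices]
        if len(set(idx)) != len(idx):
            raise ValueError("selection contains duplicate indices")
        self.indices = idx

    def __iter__(self):
        return iter(self.indices)

    def __len__(self) -> int:
        return len(self.indices)


def validate_feature_matrix(X, *, name: str = "X") -> np.ndarray:
    """Return ``X`` as a validated 2-D float array (s >= 1, d >= 1, finite)."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    if X.ndim != 2:
        raise ValueError(f"{name} must be 2-dimensional, got ndim={X.ndim}")
    if X.shape[0] < 1 or X.shape[1] < 1:
        raise ValueError(f"{name} must have at least one sample and one feature")
    if not np.all(np.isfinite(X)):
        raise ValueError(f"{name} contains non-finite entries")
    return X


def is_binary(X) -> bool:
    """True iff every entry of ``X`` is 0 or 1."""
    X = np.asarray(X, dtype=float)
    return bool(np.all((X == 0) | (X == 1)))


def validate_distance_matrix(D, *, name: str = "D") -> np.ndarray:
    """Validate symmetry (1e-10), zero diagonal, nonnegativity and finiteness."""
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError(f"{name} must be square, got shape {D.shape}")
    if not np.all(np.isfinite(D)):
        raise ValueError(f"{name} contains non-finite entries")
    if np.any(D < 0):
        raise ValueError(f"{name} contains negative distances")
    if not np.allclose(D, D.T, atol=_MATRIX_SYMMETRY_TOL, rtol=0.0):
        raise ValueError(f"{name} is not symmetric within {_MATRIX_SYMMETRY_TOL}")
    if np.any(np.diagonal(D) != 0):
        raise ValueError(f"{name} diagonal must be exactly zero")
    return D


def _binary_counters(x: np.ndarray, y: np.ndarray):
    """Pairwise fingerprint counters (a, b, c, d) for two binary vectors."""
    a = int(np.sum((x == 1) & (y == 1)))
    b = int(np.sum((x == 1) & (y == 0)))
    c = int(np.sum((x == 0) & (y == 1)))
    d = int(np.sum((x == 0) & (y == 0)))
    return a, b, c, d


def tanimoto_distance(x, y) -> float:
    """1 − Jaccard–Tanimoto similarity a/(a+b+c) of two binary vectors."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    a, b, c, _ = _binary_counters(x, y)
    if a + b + c == 0:  # two all-zero vectors are identical
        return 0.0
    return 1.0 - a / (a + b + c)


def modified_tanimoto_distance(x, y) -> float:
    """1 − modified Tanimoto similarity (see :mod:`divsel.similarity`)."""
    from .similarity import modified_tanimoto

    return 1.0 - modified_tanimoto(x, y)


def _resolve_metric(metric):
    """Map a metric identifier to a (scipy-name, kwargs) pair or callable."""
    if callable(metric):
        return metric
    if not isinstance(metric, str):
        raise TypeError("metric must be an identifier string or a callable")
    m = metric.lower()
    if m == "euclidean":
        return ("euclidean", {})
    if m.startswith("minkowski"):
        p = 2.0
        if ":" in m or "-" in m.replace("minkowski", "", 1)[:1]:
            tail = m.split(":", 1)[1] if ":" in m else m.split("-", 1)[1]
            p = float(tail)
        if p < 1:
            raise ValueError("minkowski exponent p must be >= 1")
        return ("minkowski", {"p": p})
    if m in ("tanimoto", "tanimoto-distance", "jt"):
        return tanimoto_distance
    if m in ("mt", "modified-tanimoto", "modified-tanimoto-distance"):
        return modified_tanimoto_distance
    raise ValueError(
        f"unknown metric {metric!r}; valid identifiers: euclidean, "
        "minkowski[:p], tanimoto-distance, modified-tanimoto-distance"
    )


def compute_pairwise_distances(X, metric="euclidean") -> np.ndarray:
    """Full pairwise distance matrix under a built-in or user-defined metric.

    Parameters
    ----------
    X : array-like of shape (s, d)
        Feature matrix.
    metric : str or callable
        ``"euclidean"``, ``"minkowski:p"``, ``"tanimoto-distance"``,
        ``"modified-tanimoto-distance"``, or any callable mapping two feature
        vectors to a nonnegative real.  User callables are checked for
        symmetry over the full matrix and for finite, nonnegative output.

    Returns
    -------
    ndarray of shape (s, s)
        Validated distance matrix; the diagonal is clamped to exactly 0.
    """
    X = validate_feature_matrix(X)
    resolved = _resolve_metric(metric)
    s = X.shape[0]
    if callable(resolved):
        D = np.zeros((s, s), dtype=float)
        for i in range(s):
            for j in range(s):
                if i == j:
                    continue
                D[i, j] = resolved(X[i], X[j])
        bad = np.argwhere(~np.isfinite(D))
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                f"metric returned a non-finite distance for pair ({i}, {j})"
            )
        asym = np.abs(D - D.T)
        if np.any(asym > _SYMMETRY_TOL):
            i, j = np.unravel_index(np.argmax(asym), asym.shape)
            raise ValueError(
                f"user metric is asymmetric: |D[{i},{j}] - D[{j},{i}]| = "
                f"{asym[i, j]:.3e} exceeds {_SYMMETRY_TOL}"
            )
        D = 0.5 * (D + D.T)  # kill round-off asymmetry below tolerance
        if np.any(D < 0):
            i, j = np.argwhere(D < 0)[0]
            raise ValueError(f"metric returned a negative distance for pair ({i}, {j})")
    else:
        name, kwargs = resolved
        D = squareform(pdist(X, metric=name, **kwargs))
    np.fill_diagonal(D, 0.0)
    return validate_distance_matrix(D)


def distances_to_points(X, indices, *, p: float = 2.0) -> np.ndarray:
    """Minkowski p-norm distances from every row of ``X`` to ``X[indices]``.

    Computed on demand from features (shape ``(s, len(indices))``) so
    sphere-exclusion selectors never need the full s×s matrix.
    """
    X = np.asarray(X, dtype=float)
    pts = np.atleast_2d(X[np.asarray(indices, dtype=int)])
    if p == 2.0:
        return cdist(X, pts, metric="euclidean")
    return cdist(X, pts, metric="minkowski", p=p)


def medoid(D) -> int:
    """Index minimizing the sum of distances to all other samples.

    Ties break to the lowest index (``np.argmin`` convention).
    """
    D = validate_distance_matrix(D)
    return int(np.argmin(D.sum(axis=1)))


def medoid_from_features(X, *, metric="euclidean") -> int:
    return medoid(compute_pairwise_distances(X, metric=metric))


def stratified_quotas(class_sizes: Sequence[int], n: int) -> list[int]:
    """Per-class quotas by largest-remainder (Hamilton) apportionment.

    When ``n >=`` number of classes every class receives at least 1: after
    Hamilton rounding, any class left at zero is raised to 1 and the seat is
    taken from the class currently holding the largest quota.  When
    ``n <`` number of classes a warning is issued and the ``n`` largest
    classes receive quota 1.  Quotas never exceed class sizes; excess is
    redistributed by largest remainder.

    Examples
    --------
    >>> stratified_quotas([98, 19, 10, 9, 7, 2], 9)
    [4, 1, 1, 1, 1, 1]
    """
    sizes = [int(c) for c in class_sizes]
    k = len(sizes)
    if any(c < 1 for c in sizes):
        raise ValueError("every class must contain at least one sample")
    total = sum(sizes)
    if not 1 <= n <= total:
        raise ValueError(f"n={n} must be in [1, {total}]")

    if n < k:
        warnings.warn(
            f"requested n={n} is smaller than the number of classes ({k}); "
            "only the largest classes receive a sample",
            UserWarning,
            stacklevel=2,
        )
        # rank by size descending, ties to the lower class index
        order = sorted(range(k), key=lambda i: (-sizes[i], i))
        quotas = [0] * k
        for i in order[:n]:
            quotas[i] = 1
        return quotas

    shares = [n * c / total for c in sizes]
    quotas = [int(np.floor(sh)) for sh in shares]
    remainders = [sh - q for sh, q in zip(shares, quotas)]
    missing = n - sum(quotas)
    for i in sorted(range(k), key=lambda i: (-remainders[i], i))[:missing]:
        quotas[i] += 1

    # guarantee >= 1 per class: pull seats from the largest holders
    for i in range(k):
        if quotas[i] == 0:
            donor = max(range(k), key=lambda j: (quotas[j], -j))
            quotas[donor] -= 1
            quotas[i] = 1

    # cap at class sizes, redistribute surplus by largest remainder among
    # classes with spare capacity
    while True:
        over = [i for i in range(k) if quotas[i] > sizes[i]]
        if not over:
            break
        surplus = 0
        for i in over:
            surplus += quotas[i] - sizes[i]
            quotas[i] = sizes[i]
        room = [i for i in range(k) if quotas[i] < sizes[i]]
        for i in sorted(room, key=lambda i: (-remainders[i], i))[:surplus]:
            quotas[i] += 1
        if not room:
            raise RuntimeError("cannot satisfy quotas within class sizes")

    assert sum(quotas) == n
    return quotas


def stratified_select(selector, X, labels, n: int) -> SelectionResult:
    """Run ``selector`` independently within each labeled class.

    Parameters
    ----------
    selector : estimator
        Any fitted-style selector from this package (clone-compatible);
        its ``n_select`` is overridden per class.
    X : array-like of shape (s, d) or (s, s)
        Feature matrix, or a precomputed distance matrix if the selector is
        configured with ``metric="precomputed"``.
    labels : array-like of int, length s
        Class identifiers.
    n : int
        Total number of samples to select across classes.

    Returns
    -------
    SelectionResult
        Global indices, grouped by class in label-sorted order; within each
        class the order is the selector's own selection order.
    """
    from sklearn.base import clone

    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if labels.shape[0] != X.shape[0]:
        raise ValueError("labels length must match the number of samples")
    classes, counts = np.unique(labels, return_counts=True)
    quotas = stratified_quotas(counts.tolist(), n)

    precomputed = getattr(selector, "metric", None) == "precomputed"
    all_indices: list[int] = []
    for cls, quota in zip(classes, quotas):
        if quota == 0:
            continue
        mask = labels == cls
        members = np.flatnonzero(mask)
        sub = X[np.ix_(members, members)] if precomputed else X[members]
        est = clone(selector)
        est.set_params(n_select=quota)
        est.fit(sub)
        all_indices.extend(int(members[i]) for i in est.indices_)

    return SelectionResult(
        indices=all_indices,
        method=f"stratified[{type(selector).__name__}]",
        params={"n": n, "quotas": [int(q) for q in quotas]},
    )


class BaseSubsetSelector:
    """Mixin giving every selector the scikit-learn estimator contract.

    Subclasses implement ``_select(X) -> list[int]`` and set ``_method``.
    ``fit(X, y=None)`` stores the chosen row indices in ``indices_`` (in
    selection order) and a provenance :class:`SelectionResult` in
    ``result_``; passing integer class labels as ``y`` switches to
    label-stratified selection with proportional per-class quotas.
    ``transform(X)`` returns the selected rows, so selectors compose with
    sklearn pipelines and ``fit_transform``.
    """

    _method = "base"

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if y is not None:
            result = stratified_select(self, X, y, self.n_select)
        else:
            indices = self._select(X)
            result = SelectionResult(
                indices=list(indices),
                method=self._method,
                params={k: v for k, v in self.get_params().items()},
            )
        self.indices_ = np.asarray(result.indices, dtype=int)
        self.result_ = result
        self.n_features_in_ = X.shape[1]
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)

    def transform(self, X):
        if not hasattr(self, "indices_"):
            raise RuntimeError("selector is not fitted")
        return np.asarray(X, dtype=float)[self.indices_]
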