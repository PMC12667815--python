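"""Distance-based diverse subset selectors.

Four classic pickers that maximize pairwise dissimilarity:

* :class:`MaxMinSelector` — greedy farthest-point picking; each new sample
  maximizes the minimum distance to the already-selected set.
* :class:`MaxSumSelector` — each new sample maximizes the *sum* of distances
  to the selected set, which drives picks toward the periphery.
* :class:`OptiSimSelector` — stochastic sphere exclusion: samples inside a
  radius ``r`` of any selected point are excluded, and each pick is the best
  of a random size-``k`` subsample of the survivors.
* :class:`DISESelector` — directed sphere exclusion: samples are visited in
  ascending distance from a reference point and accepted unless a previous
  selection's exclusion sphere already swallowed them.

MaxMin/MaxSum consume a full distance matrix (or build one from features
under any metric); OptiSim and DISE compute Minkowski ``p``-norm distances
on demand from features and never materialize the s×s matrix.  For the
sphere-exclusion pair the radius is tuned by bisection so the natural
stopping size matches the requested subset size.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .base import (
    BaseSubsetSelector,
    SelectionResult,
    compute_pairwise_distances,
    distances_to_points,
    medoid,
    validate_distance_matrix,
    validate_feature_matrix,
)

__all__ = [
    "MaxMinSelector",
    "MaxSumSelector",
    "OptiSimSelector",
    "DISESelector",
    "select_maxmin",
    "select_maxsum",
    "select_optisim",
    "select_dise",
]

_RADIUS_BISECTION_ITERS = 50


def _resolve_start(D: np.ndarray, start) -> list[int]:
    s = D.shape[0]
    if isinstance(start, str):
        if start != "medoid":
            raise ValueError(f"unknown start {start!r}; use 'medoid' or indices")
        return [medoid(D)]
    if np.isscalar(start):
        start = [start]
    idx = [int(i) for i in start]
    if len(set(idx)) != len(idx):
        raise ValueError("duplicate start indices")
    if any(not 0 <= i < s for i in idx):
        raise ValueError("start index out of range")
    return idx


def _greedy_distance_select(D: np.ndarray, n: int, start, criterion: str) -> list[int]:
    """Shared greedy loop; ``criterion`` is 'maxmin' or 'maxsum'."""
    D = validate_distance_matrix(D)
    s = D.shape[0]
    if not 1 <= n <= s:
        raise ValueError(f"n={n} must be in [1, {s}]")
    selected = _resolve_start(D, start)
    if len(selected) > n:
        raise ValueError("more start indices than the requested subset size")
    in_set = np.zeros(s, dtype=bool)
    in_set[selected] = True
    # running per-candidate score: min or sum of distances to the selected set
    if criterion == "maxmin":
        score = D[:, selected].min(axis=1)
    else:
        score = D[:, selected].sum(axis=1)
    while len(selected) < n:
        masked = np.where(in_set, -np.inf, score)
        pick = int(np.argmax(masked))  # argmax ties break to the lowest index
        selected.append(pick)
        in_set[pick] = True
        if criterion == "maxmin":
            score = np.minimum(score, D[:, pick])
        else:
            score = score + D[:, pick]
    return selected


class MaxMinSelector(BaseSubsetSelector, BaseEstimator):
    """Greedy MaxMin (farthest-point) diverse subset selection.

    Starting from the dataset medoid (or user-supplied indices), each
    iteration adds the unselected sample whose minimum distance to the
    selected set is largest; ties break to the lowest index.

    Parameters
    ----------
    n_select : int
        Target subset size ``n``.
    metric : str, callable or "precomputed"
        Distance metric used to build the pairwise matrix from features, or
        ``"precomputed"`` if ``fit`` receives a distance matrix directly.
    start : "medoid", int or list of int
        Initial selection.

    Attributes
    ----------
    indices_ : ndarray of int
        Selected indices in selection order.
    result_ : SelectionResult
    """

    _method = "maxmin"

    def __init__(self, n_select=2, metric="euclidean", start="medoid"):
        self.n_select = n_select
        self.metric = metric
        self.start = start

    def _distance_matrix(self, X):
        if isinstance(self.metric, str) and self.metric == "precomputed":
            return validate_distance_matrix(X)
        return compute_pairwise_distances(X, metric=self.metric)

    def _select(self, X):
        D = self._distance_matrix(X)
        return _greedy_distance_select(D, self.n_select, self.start, "maxmin")


class MaxSumSelector(MaxMinSelector):
    """Greedy MaxSum selection: maximize the sum of distances to the set.

    Same contract as :class:`MaxMinSelector` with the argmax criterion
    Σ_{j∈selected} D[i, j].
    """

    _method = "maxsum"

    def _select(self, X):
        D = self._distance_matrix(X)
        return _greedy_distance_select(D, self.n_select, self.start, "maxsum")


def _tune_radius(run, n: int, s: int, r_init, r_max: float):
    """Find a radius whose natural stopping size is >= n, largest possible.

    ``run(r)`` returns the full selection sequence at radius ``r``.  Size is
    (weakly) decreasing in ``r``, so bisection over [0, hi] keeps ``lo`` at a
    radius with size >= n; the final sequence is truncated to ``n``.
    """
    if r_init is not None:
        seq = run(float(r_init))
        if len(seq) >= n:
            return seq[:n], float(r_init)
        hi = float(r_init)
    else:
        hi = max(r_max, 1e-12)
        seq = run(hi)
        if len(seq) >= n:
            return seq[:n], hi
    lo = 0.0
    lo_seq = run(lo)
    for _ in range(_RADIUS_BISECTION_ITERS):
        mid = 0.5 * (lo + hi)
        seq = run(mid)
        if len(seq) >= n:
            lo, lo_seq = mid, seq
        else:
            hi = mid
    return lo_seq[:n], lo


def _relax_to_n(selected, excluded_dist, r, n):
    """Top up an undersized selection with samples nearest the sphere edges."""
    s = len(excluded_dist)
    remaining = [i for i in range(s) if i not in set(selected)]
    remaining.sort(key=lambda i: (abs(excluded_dist[i] - r), i))
    return selected + remaining[: n - len(selected)]


class OptiSimSelector(BaseSubsetSelector, BaseEstimator):
    """OptiSim: stochastic sphere-exclusion diverse subset selection.

    Starting from a reference sample (the medoid by default), all samples
    within radius ``r`` of any selected sample are permanently excluded from
    candidacy.  Each iteration draws a uniform random subsample of size ``k``
    (without replacement) from the surviving candidates and selects the one
    with the greatest minimum Minkowski ``p``-norm distance to the selected
    set, until no candidates remain.  The radius is tuned by bisection so the
    natural stopping size matches ``n_select``; if it overshoots, the
    selection order is truncated.

    Parameters
    ----------
    n_select : int
    r : float or None
        Exclusion radius.  ``None`` (default) tunes from scratch; a given
        value is used directly when it already yields >= ``n_select``
        samples and otherwise serves as the upper bracket for tuning.
    k : int
        Random subsample size per iteration.
    p : float
        Minkowski exponent, >= 1.
    ref : "medoid" or int
        Reference (first selected) sample.
    random_state : int or None
        Seed for the subsample draws; recorded in ``result_``.
    """

    _method = "optisim"

    def __init__(self, n_select=2, r=None, k=10, p=2.0, ref="medoid", random_state=None):
        self.n_select = n_select
        self.r = r
        self.k = k
        self.p = p
        self.ref = ref
        self.random_state = random_state

    def _reference(self, X):
        if isinstance(self.ref, str):
            if self.ref != "medoid":
                raise ValueError("ref must be 'medoid' or an integer index")
            return medoid(compute_pairwise_distances(X, metric=f"minkowski:{self.p}"))
        return int(self.ref)

    def _run(self, X, ref, r, rng):
        s = X.shape[0]
        selected = [ref]
        dist_to_sel = distances_to_points(X, [ref], p=self.p).ravel()
        alive = np.ones(s, dtype=bool)
        alive[ref] = False
        alive &= dist_to_sel > r
        while alive.any():
            cand = np.flatnonzero(alive)
            if len(cand) > self.k:
                cand = np.sort(rng.choice(cand, size=self.k, replace=False))
            best = cand[int(np.argmax(dist_to_sel[cand]))]
            selected.append(int(best))
            alive[best] = False
            d_new = distances_to_points(X, [best], p=self.p).ravel()
            dist_to_sel = np.minimum(dist_to_sel, d_new)
            alive &= d_new > r
        return selected, dist_to_sel

    def _select(self, X):
        X = validate_feature_matrix(X)
        s = X.shape[0]
        n = self.n_select
        if not 1 <= n <= s:
            raise ValueError(f"n={n} must be in [1, {s}]")
        if not 1 <= self.k:
            raise ValueError("k must be >= 1")
        ref = self._reference(X)
        if n == 1:
            return [ref]

        last = {}

        def run(r):
            rng = np.random.default_rng(self.random_state)
            seq, dist = self._run(X, ref, r, rng)
            last[r] = dist
            return seq

        d_ref = distances_to_points(X, [ref], p=self.p).ravel()
        r_max = 2.0 * float(d_ref.max())  # triangle-inequality bound on any pair
        seq, r_used = _tune_radius(run, n, s, self.r, r_max)
        if len(seq) < n:
            seq = _relax_to_n(seq, last[r_used], r_used, n)
        return seq


class DISESelector(BaseSubsetSelector, BaseEstimator):
    """Directed Sphere Exclusion (DISE) diverse subset selection.

    Samples are sorted in ascending Minkowski ``p``-norm distance from a
    reference sample (ties to the lower index).  Walking the sorted list, a
    sample is selected iff no earlier selection's exclusion sphere of radius
    ``r`` covers it; each selection excludes everything within ``r`` of it.
    Deterministic given parameters; ``r`` is tuned as in OptiSim.
    """

    _method = "dise"

    def __init__(self, n_select=2, r=None, p=2.0, ref="medoid"):
        self.n_select = n_select
        self.r = r
        self.p = p
        self.ref = ref

    def _run(self, X, order, r):
        s = X.shape[0]
        excluded = np.zeros(s, dtype=bool)
        selected = []
        dist_to_sel = np.full(s, np.inf)
        for i in order:
            if excluded[i]:
                continue
            selected.append(int(i))
            d_new = distances_to_points(X, [i], p=self.p).ravel()
            dist_to_sel = np.minimum(dist_to_sel, d_new)
            excluded |= d_new <= r
        return selected, dist_to_sel

    def _select(self, X):
        X = validate_feature_matrix(X)
        s = X.shape[0]
        n = self.n_select
        if not 1 <= n <= s:
            raise ValueError(f"n={n} must be in [1, {s}]")
        if isinstance(self.ref, str):
            if self.ref != "medoid":
                raise ValueError("ref must be 'medoid' or an integer index")
            ref = medoid(compute_pairwise_distances(X, metric=f"minkowski:{self.p}"))
        else:
            ref = int(self.ref)
        d_ref = distances_to_points(X, [ref], p=self.p).ravel()
        order = np.argsort(d_ref, kind="stable")

        last = {}

        def run(r):
            seq, dist = self._run(X, order, r)
            last[r] = dist
            return seq

        seq, r_used = _tune_radius(run, n, s, self.r, 2.0 * float(d_ref.max()))
        if len(seq) < n:
            seq = _relax_to_n(seq, last[r_used], r_used, n)
        return seq


# ---------------------------------------------------------------------------
# thin functional wrappers

def select_maxmin(D, n, start="medoid") -> SelectionResult:
    """MaxMin selection on a precomputed distance matrix."""
    est = MaxMinSelector(n_select=n, metric="precomputed", start=start).fit(D)
    return est.result_


def select_maxsum(D, n, start="medoid") -> SelectionResult:
    """MaxSum selection on a precomputed distance matrix."""
    est = MaxSumSelector(n_select=n, metric="precomputed", start=start).fit(D)
    return est.result_


def select_optisim(X, n, r=None, k=10, p=2.0, ref="medoid", seed=None) -> SelectionResult:
    est = OptiSimSelector(
        n_select=n, r=r, k=k, p=p, ref=ref, random_state=seed
    ).fit(X)
    return est.result_


def select_dise(X, n, r=None, p=2.0, ref="medoid") -> SelectionResult:
    est = DISESelector(n_select=n, r=r, p=p, ref=ref).fit(X)
    return est.result_
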