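"""Similarity machinery: pairwise indices, n-ary (iSIM/eSIM) counters,
similarity→distance conversion, and the NSimilarity greedy selector.

Binary similarity indices are defined over the classic contingency counters
of two fingerprints: ``a`` (both bits on), ``d`` (both off), ``b + c``
(mismatches) and ``p = a + b + c + d``.  Every registered index is expressed
as a function ``f(a, d, bc, p)``, which lets the same registry serve three
settings:

* **pairwise** — counters of a single vector pair;
* **iSIM** — counters aggregated over *all* pairs of a set from the column
  sums ``k_j`` alone (``a = Σ k_j(k_j−1)/2`` etc.), giving the exact mean
  pairwise value for indices linear in the counters (Russell–Rao,
  Sokal–Michener) and a near-equivalent otherwise, at O(s·d) cost;
* **eSIM** — each column is classified as 1-similarity, 0-similarity or
  dissimilarity by comparing its on-bit majority margin ``Δ_j = |2k_j − s|``
  with a coincidence threshold, and weighted counters replace (a, d, b+c).

iSIM requires binary input; eSIM extends to real-valued data by min-max
scaling each column to [0, 1] first (``preprocess=True``).
"""

from __future__ import annotations

import math
from typing import Callable

import numpy as np
from sklearn.base import BaseEstimator

from .base import (
    BaseSubsetSelector,
    SelectionResult,
    is_binary,
    validate_feature_matrix,
)

__all__ = [
    "SIMILARITY_INDICES",
    "list_indices",
    "pairwise_similarity",
    "pairwise_similarity_matrix",
    "modified_tanimoto",
    "isim_average",
    "esim_nary",
    "similarity_to_distance",
    "NSimilaritySelector",
    "select_nsimilarity",
]


# ---------------------------------------------------------------------------
# index registry
#
# Each index is a function of a counter record with fields
#   a, d, dis : raw counts of 1-similarity, 0-similarity and dissimilarity
#               columns (for a vector pair: both-on, both-off, mismatch);
#   w_a, w_d, w_dis : their weighted analogues (equal to the raw counts in
#               the pairwise and iSIM settings, fractional under eSIM
#               weighting);
#   p : total number of columns (comparisons).
# Weighted counters enter numerators, raw counts enter denominators — the
# structure of the extended (n-ary) similarity family — which reduces to the
# classic pairwise formulas when every weight is 1.  A zero denominator
# returns 1 for a fully coincident comparison (no dissimilarity columns,
# e.g. two identical all-zero vectors) and 0 otherwise.


def _guard(num: float, den: float, dis: float) -> float:
    if den == 0:
        return 1.0 if dis == 0 else 0.0
    return num / den


def _austin_colwell(c):
    if c["p"] == 0:
        return 1.0 if c["dis"] == 0 else 0.0
    return (2.0 / math.pi) * math.asin(math.sqrt((c["w_a"] + c["w_d"]) / c["p"]))


def _bub(c):
    num = math.sqrt(c["w_a"] * c["w_d"]) + c["w_a"]
    den = math.sqrt(c["a"] * c["d"]) + c["a"] + c["dis"]
    return _guard(num, den, c["dis"])


def _ct1(c):
    if c["p"] == 0:
        return 1.0 if c["dis"] == 0 else 0.0
    return math.log(1 + c["w_a"] + c["w_d"]) / math.log(1 + c["p"])


def _ct2(c):
    if c["p"] == 0:
        return 1.0 if c["dis"] == 0 else 0.0
    return (math.log(1 + c["p"]) - math.log(1 + c["w_dis"])) / math.log(1 + c["p"])


def _ct3(c):
    if c["p"] == 0:
        return 1.0 if c["dis"] == 0 else 0.0
    return math.log(1 + c["w_a"]) / math.log(1 + c["p"])


def _ct4(c):
    return _guard(
        math.log(1 + c["w_a"]),
        math.log(1 + c["a"] + c["dis"]),
        c["dis"],
    )


SIMILARITY_INDICES: dict[str, Callable] = {
    "austin_colwell": _austin_colwell,
    "baroni_urbani_buser": _bub,
    "consonni_todeschini": _ct1,
    "consonni_todeschini_2": _ct2,
    "consonni_todeschini_3": _ct3,
    "consonni_todeschini_4": _ct4,
    "faith": lambda c: _guard(c["w_a"] + 0.5 * c["w_d"], c["p"], c["dis"]),
    "gleason": lambda c: _guard(2 * c["w_a"], 2 * c["a"] + c["dis"], c["dis"]),
    "jaccard": lambda c: _guard(3 * c["w_a"], 3 * c["a"] + c["dis"], c["dis"]),
    "jaccard_0variant": lambda c: _guard(3 * c["w_d"], 3 * c["d"] + c["dis"], c["dis"]),
    "jaccard_tanimoto": lambda c: _guard(c["w_a"], c["a"] + c["dis"], c["dis"]),
    "rogers_tanimoto": lambda c: _guard(
        c["w_a"] + c["w_d"], c["p"] + c["dis"], c["dis"]
    ),
    "russell_rao": lambda c: _guard(c["w_a"], c["p"], c["dis"]),
    "sokal_michener": lambda c: _guard(c["w_a"] + c["w_d"], c["p"], c["dis"]),
    "sokal_sneath": lambda c: _guard(c["w_a"], c["a"] + 2 * c["dis"], c["dis"]),
    "sokal_sneath_2": lambda c: _guard(
        2 * (c["w_a"] + c["w_d"]), c["p"] + c["a"] + c["d"], c["dis"]
    ),
}

_ALIASES = {
    "jt": "jaccard_tanimoto",
    "ac": "austin_colwell",
    "bub": "baroni_urbani_buser",
    "ct": "consonni_todeschini",
    "ct1": "consonni_todeschini",
    "ct2": "consonni_todeschini_2",
    "ct3": "consonni_todeschini_3",
    "ct4": "consonni_todeschini_4",
    "fai": "faith",
    "gle": "gleason",
    "ja": "jaccard",
    "ja0": "jaccard_0variant",
    "rt": "rogers_tanimoto",
    "rr": "russell_rao",
    "sm": "sokal_michener",
    "ss": "sokal_sneath",
    "ss2": "sokal_sneath_2",
}


def list_indices() -> list[str]:
    """Identifiers of all registered similarity indices."""
    return sorted(SIMILARITY_INDICES)


def _index_fn(index: str) -> Callable:
    key = index.lower()
    key = _ALIASES.get(key, key)
    if key not in SIMILARITY_INDICES:
        raise ValueError(
            f"unknown similarity index {index!r}; valid: {list_indices()}"
        )
    return SIMILARITY_INDICES[key]


def _require_binary(X: np.ndarray, context: str) -> None:
    if not is_binary(X):
        raise ValueError(f"{context} requires binary (0/1) features")


# ---------------------------------------------------------------------------
# pairwise

def pairwise_similarity(x, y, index: str = "jaccard_tanimoto") -> float:
    """Similarity of two binary vectors under a registered index."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    _require_binary(np.stack([x, y]), "pairwise similarity")
    a = float(np.sum((x == 1) & (y == 1)))
    d = float(np.sum((x == 0) & (y == 0)))
    bc = float(np.sum(x != y))
    c = {"a": a, "d": d, "dis": bc, "w_a": a, "w_d": d, "w_dis": bc,
         "p": float(x.size)}
    return float(_index_fn(index)(c))


def pairwise_similarity_matrix(X, index: str = "jaccard_tanimoto") -> np.ndarray:
    """Full s×s matrix of pairwise similarities (diagonal = identity value)."""
    X = validate_feature_matrix(X)
    s = X.shape[0]
    S = np.empty((s, s))
    for i in range(s):
        for j in range(i, s):
            S[i, j] = S[j, i] = pairwise_similarity(X[i], X[j], index)
    return S


def modified_tanimoto(x, y) -> float:
    """Modified Tanimoto similarity for binary fingerprints.

    Blends the on-bit Tanimoto T1 = a/(a+b+c) and the off-bit analogue
    T0 = d/(d+b+c) with weights depending on the mean on-bit fraction
    p̄ of the two vectors: MT = ((2−p̄)/3)·T1 + ((1+p̄)/3)·T0.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    _require_binary(np.stack([x, y]), "modified Tanimoto")
    a = float(np.sum((x == 1) & (y == 1)))
    d = float(np.sum((x == 0) & (y == 0)))
    bc = float(np.sum(x != y))
    t1 = _guard(a, a + bc, bc)
    t0 = _guard(d, d + bc, bc)
    p_bar = 0.5 * (x.mean() + y.mean())
    return ((2.0 - p_bar) / 3.0) * t1 + ((1.0 + p_bar) / 3.0) * t0


# ---------------------------------------------------------------------------
# iSIM: aggregated pair counters from column sums

def _isim_counters(X: np.ndarray) -> dict:
    s = X.shape[0]
    k = X.sum(axis=0)
    a = float(np.sum(k * (k - 1) / 2.0))
    d0 = float(np.sum((s - k) * (s - k - 1) / 2.0))
    bc = float(np.sum(k * (s - k)))
    p = X.shape[1] * s * (s - 1) / 2.0
    return {"a": a, "d": d0, "dis": bc, "w_a": a, "w_d": d0, "w_dis": bc,
            "p": p}


def isim_average(X, index: str = "jaccard_tanimoto") -> float:
    """Instant (iSIM) set similarity from column sums; binary input only.

    Exactly the mean pairwise similarity for counter-linear indices
    (Russell–Rao, Sokal–Michener); a close surrogate for the rest.
    """
    X = validate_feature_matrix(X)
    if X.shape[0] < 2:
        raise ValueError("iSIM requires at least two samples")
    if not is_binary(X):
        raise ValueError(
            "iSIM relies on binary feature representations and does not "
            "apply to non-binary features"
        )
    return float(_index_fn(index)(_isim_counters(X)))


# ---------------------------------------------------------------------------
# eSIM: weighted column classification

def _minmax_scale_columns(X: np.ndarray) -> np.ndarray:
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    rng = hi - lo
    out = np.empty_like(X, dtype=float)
    const = rng == 0
    # constant columns map to 1: fully coincident (margin Δ = s)
    out[:, const] = 1.0
    nz = ~const
    out[:, nz] = (X[:, nz] - lo[nz]) / rng[nz]
    return out


def _esim_counters(
    X: np.ndarray, coincidence_threshold: float, weight_scheme: str
) -> dict:
    s = X.shape[0]
    k = X.sum(axis=0)
    margin = 2.0 * k - s  # >0: on-majority, <0: off-majority
    delta = np.abs(margin)
    one_sim = margin > coincidence_threshold
    zero_sim = -margin > coincidence_threshold
    dis = ~(one_sim | zero_sim)
    if weight_scheme == "fraction":
        w_sim = delta / s
        w_dis = 1.0 - (delta - s % 2) / s
    elif weight_scheme == "none":
        w_sim = np.ones_like(delta)
        w_dis = np.ones_like(delta)
    else:
        raise ValueError("weight_scheme must be 'fraction' or 'none'")
    return {
        "a": float(np.count_nonzero(one_sim)),
        "d": float(np.count_nonzero(zero_sim)),
        "dis": float(np.count_nonzero(dis)),
        "w_a": float(np.sum(w_sim[one_sim])),
        "w_d": float(np.sum(w_sim[zero_sim])),
        "w_dis": float(np.sum(w_dis[dis])),
        "p": float(X.shape[1]),
    }


def esim_nary(
    X,
    index: str = "jaccard_tanimoto",
    coincidence_threshold: float = 0.0,
    weight_scheme: str = "fraction",
    preprocess: bool = False,
) -> float:
    """Extended (eSIM) n-ary set similarity.

    Each column with sum ``k_j`` is a 1-similarity column if
    ``2k_j − s > threshold``, a 0-similarity column if
    ``s − 2k_j > threshold`` and a dissimilarity column otherwise.  Weighted
    column counters (weight w(Δ_j) of the majority margin Δ_j = |2k_j − s|)
    enter the index numerators in place of (a, d, b+c), while the raw
    column counts enter the denominators; at ``s = 2`` all weights are 1
    and every index reduces exactly to its pairwise formula.

    ``preprocess=True`` min-max scales each column to [0, 1] first, which
    extends the method to real-valued features (constant columns count as
    fully coincident).
    """
    X = validate_feature_matrix(X)
    if X.shape[0] < 2:
        raise ValueError("eSIM requires at least two samples")
    if preprocess:
        X = _minmax_scale_columns(X)
    elif not is_binary(X):
        raise ValueError(
            "eSIM requires binary features; pass preprocess=True for "
            "real-valued data"
        )
    counters = _esim_counters(X, coincidence_threshold, weight_scheme)
    return float(_index_fn(index)(counters))


def _nary_similarity(X, index, engine, coincidence_threshold, weight_scheme, preprocess):
    if engine == "isim":
        return isim_average(X, index)
    if engine == "esim":
        return esim_nary(
            X, index,
            coincidence_threshold=coincidence_threshold,
            weight_scheme=weight_scheme,
            preprocess=preprocess,
        )
    raise ValueError("engine must be 'esim' or 'isim'")


# ---------------------------------------------------------------------------
# similarity -> distance

def similarity_to_distance(S, method: str = "reverse"):
    """Convert similarity values (in [0, 1]) to distances.

    Methods: ``reverse`` (1−s), ``squared-root`` (√(1−s)), ``reciprocal``
    (1/s − 1, errors on s = 0).  A converted matrix gets a zero diagonal.
    """
    arr = np.asarray(S, dtype=float)
    scalar = arr.ndim == 0
    if np.any(arr < 0) or (method != "reciprocal" and np.any(arr > 1)):
        raise ValueError("similarity values must lie in [0, 1]")
    if method == "reverse":
        out = 1.0 - arr
    elif method in ("squared-root", "sqrt"):
        out = np.sqrt(1.0 - arr)
    elif method == "reciprocal":
        if np.any(arr == 0):
            raise ValueError(
                "reciprocal conversion is undefined at similarity 0; use "
                "'reverse' or 'squared-root' instead"
            )
        out = 1.0 / arr - 1.0
    else:
        raise ValueError("method must be 'reverse', 'squared-root' or 'reciprocal'")
    if not scalar and out.ndim == 2 and out.shape[0] == out.shape[1]:
        np.fill_diagonal(out, 0.0)
    return float(out) if scalar else out


# ---------------------------------------------------------------------------
# NSimilarity greedy selector

class NSimilaritySelector(BaseSubsetSelector, BaseEstimator):
    """Greedy diverse selection minimizing n-ary set similarity.

    Starting from a user-defined sample (by default the most outlying one —
    the sample whose removal leaves the most self-similar remainder), each
    step evaluates, for every unselected candidate, the n-ary similarity of
    the selected set plus that candidate, and adds the minimizer (ties to
    the lowest index) until ``n_select`` samples are chosen.

    Parameters
    ----------
    n_select : int
    index : str
        Any of the 16 registered similarity indices.
    start : "outlier" or int
    engine : "esim" or "isim"
        Which n-ary counter construction scores candidate sets.
    preprocess : bool
        Min-max scale real-valued columns first (eSIM engine only).
    coincidence_threshold, weight_scheme :
        Passed through to the eSIM counters.
    """

    _method = "nsimilarity"

    def __init__(
        self,
        n_select=2,
        index="jaccard_tanimoto",
        start="outlier",
        engine="esim",
        preprocess=False,
        coincidence_threshold=0.0,
        weight_scheme="fraction",
    ):
        self.n_select = n_select
        self.index = index
        self.start = start
        self.engine = engine
        self.preprocess = preprocess
        self.coincidence_threshold = coincidence_threshold
        self.weight_scheme = weight_scheme

    def _set_similarity(self, Xw):
        # Xw is already scaled (or binary); evaluate counters directly so the
        # normalization frame stays that of the full matrix, not the subset.
        if self.engine == "isim":
            if not is_binary(Xw):
                raise ValueError(
                    "the iSIM engine relies on binary feature representations"
                )
            return float(_index_fn(self.index)(_isim_counters(Xw)))
        if self.engine != "esim":
            raise ValueError("engine must be 'esim' or 'isim'")
        counters = _esim_counters(
            Xw, self.coincidence_threshold, self.weight_scheme
        )
        return float(_index_fn(self.index)(counters))

    def _most_outlying(self, Xw) -> int:
        s = Xw.shape[0]
        if s == 2:
            return 0
        best, best_val = 0, -np.inf
        for i in range(s):
            rest = np.delete(Xw, i, axis=0)
            val = self._set_similarity(rest)
            if val > best_val + 1e-15:
                best, best_val = i, val
        return best

    def _select(self, X):
        X = validate_feature_matrix(X)
        s = X.shape[0]
        n = self.n_select
        if not 2 <= n <= s:
            raise ValueError(f"n={n} must be in [2, {s}]")
        if self.preprocess:
            # scale the FULL matrix once; candidate subsets are never rescaled
            Xw = _minmax_scale_columns(X)
        elif not is_binary(X):
            raise ValueError(
                "similarity selection requires binary features; pass "
                "preprocess=True for real-valued data"
            )
        else:
            Xw = X
        if isinstance(self.start, str):
            if self.start != "outlier":
                raise ValueError("start must be 'outlier' or an integer index")
            start = self._most_outlying(Xw)
        else:
            start = int(self.start)
        selected = [start]
        remaining = [i for i in range(s) if i != start]
        while len(selected) < n:
            best, best_val = None, np.inf
            for c in remaining:
                val = self._set_similarity(Xw[selected + [c]])
                if val < best_val - 1e-15:
                    best, best_val = c, val
            selected.append(best)
            remaining.remove(best)
        return selected


def select_nsimilarity(
    X, n, index="jaccard_tanimoto", start="outlier", preprocess=False,
    engine="esim",
) -> SelectionResult:
    """Functional wrapper over :class:`NSimilaritySelector`."""
    est = NSimilaritySelector(
        n_select=n, index=index, start=start, preprocess=preprocess,
        engine=engine,
    ).fit(X)
    return est.result_
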