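"""Diversity measures for (selected) subsets of a feature matrix.

Absolute measures depend only on the selected rows: log-determinant,
Shannon entropy, explicit diversity index (EDI), Gini coefficient and the
Wasserstein Distance to the Uniform Distribution (WDUD).  Hypersphere
overlap is relative: it needs the full matrix too, since the subset is
normalized to the full data's per-feature range.

Direction conventions: higher log-determinant, entropy and EDI mean more
diverse; lower WDUD, Gini and hypersphere overlap mean more diverse.
Entropy, EDI and Gini are restricted to binary features; log-determinant,
WDUD and overlap accept binary or real input.
"""

from __future__ import annotations

from dataclasses import dataclass
import hashlib

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .base import is_binary, validate_feature_matrix

__all__ = [
    "DiversityReport",
    "logdet_diversity",
    "shannon_entropy",
    "explicit_diversity_index",
    "gini_coefficient",
    "wdud",
    "hypersphere_overlap",
    "compute_diversity",
    "MEASURES",
]

_HIGHER = "higher_is_diverse"
_LOWER = "lower_is_diverse"

MEASURES = {
    "logdet": _HIGHER,
    "shannon": _HIGHER,
    "edi": _HIGHER,
    "gini": _LOWER,
    "wdud": _LOWER,
    "overlap": _LOWER,
}


@dataclass
class DiversityReport:
    measure: str
    value: float
    direction: str
    inputs_hash: str


def _hash_arrays(*arrays) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a, dtype=float).tobytes())
    return h.hexdigest()[:16]


def logdet_diversity(Xsel) -> float:
    """log det(X·Xᵀ + I) of the selected rows; larger spans score higher.

    The identity regularization keeps the Gram matrix positive definite for
    degenerate and n > d subsets alike, so the value is always >= 0.
    """
    X = validate_feature_matrix(Xsel, name="Xsel")
    n, d = X.shape
    # Sylvester: det(XXᵀ + I_n) == det(XᵀX + I_d); factor the smaller one
    if d < n:
        G = X.T @ X + np.eye(d)
    else:
        G = X @ X.T + np.eye(n)
    sign, logdet = np.linalg.slogdet(G)
    if sign <= 0:
        raise RuntimeError("Gram + I must be positive definite")
    return float(max(logdet, 0.0))


def shannon_entropy(Xsel) -> float:
    """Sum over columns of the binary entropy of the on-bit fraction (bits)."""
    X = validate_feature_matrix(Xsel, name="Xsel")
    if not is_binary(X):
        raise ValueError("Shannon entropy requires binary features")
    p = X.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -p * np.log2(p) - (1 - p) * np.log2(1 - p)
    h = np.where((p == 0) | (p == 1), 0.0, h)
    return float(h.sum())


def _mean_nearest_neighbor_tanimoto(X: np.ndarray) -> float:
    from .similarity import pairwise_similarity_matrix

    S = pairwise_similarity_matrix(X, "jaccard_tanimoto")
    np.fill_diagonal(S, -np.inf)
    return float(S.max(axis=1).mean())


def explicit_diversity_index(Xsel, cs: int = 1) -> float:
    """Explicit diversity index of a binary fingerprint set, scaled to (0, 100).

    SDI = (1 − NAT) / (0.8047 − 0.065·ln n), with NAT the mean
    nearest-neighbor Tanimoto similarity; CR = −log10(n / cs³);
    EDI = (SDI + CR)/√2, reported as 100·(tanh(EDI/3) + 1)/2.
    """
    X = validate_feature_matrix(Xsel, name="Xsel")
    if not is_binary(X):
        raise ValueError("explicit diversity index requires binary features")
    n = X.shape[0]
    if n < 2:
        raise ValueError("EDI needs at least two samples (NAT is undefined)")
    if cs < 1:
        raise ValueError("cs must be >= 1")
    nat = _mean_nearest_neighbor_tanimoto(X)
    sdi = (1.0 - nat) / (0.8047 - 0.065 * np.log(n))
    cr = -np.log10(n / cs**3)
    edi = (sdi + cr) / np.sqrt(2.0)
    return float(100.0 * (np.tanh(edi / 3.0) + 1.0) / 2.0)


def gini_coefficient(Xsel) -> float:
    """Gini coefficient of the column on-bit counts; 0 = perfectly even usage."""
    X = validate_feature_matrix(Xsel, name="Xsel")
    if not is_binary(X):
        raise ValueError("Gini coefficient requires binary features")
    counts = np.sort(X.sum(axis=0))
    d = counts.size
    total = counts.sum()
    if total == 0:
        raise ValueError("Gini is undefined for an all-zero matrix")
    ranks = np.arange(1, d + 1)
    return float(2.0 * np.sum(ranks * counts) / (d * total) - (d + 1) / d)


def _wdud_single(values: np.ndarray) -> float:
    """Exact ∫₀¹ |F(t) − t| dt for one min-max normalized feature."""
    lo, hi = values.min(), values.max()
    if hi == lo:
        # degenerate range: point mass at 0.5 -> two triangles of area 1/8
        return 0.25
    v = np.sort((values - lo) / (hi - lo))
    n = v.size
    knots = np.concatenate(([0.0], v, [1.0]))
    total = 0.0
    for seg in range(knots.size - 1):
        left, right = knots[seg], knots[seg + 1]
        if right <= left:
            continue
        c = min(seg, n) / n  # F value on this open interval
        # ∫ |c − t| dt with a possible sign change at t = c
        if c <= left:
            total += 0.5 * ((right - c) ** 2 - (left - c) ** 2)
        elif c >= right:
            total += 0.5 * ((c - left) ** 2 - (c - right) ** 2)
        else:
            total += 0.5 * ((c - left) ** 2 + (right - c) ** 2)
    return total


def wdud(Xsel) -> float:
    """Mean per-feature Wasserstein distance to the uniform distribution.

    Each feature is min-max normalized to [0, 1]; the distance between its
    empirical CDF and the uniform CDF is integrated exactly piecewise.
    Lower values mean a more uniformly spread subset; range [0, 0.5].
    """
    X = validate_feature_matrix(Xsel, name="Xsel")
    return float(np.mean([_wdud_single(X[:, j]) for j in range(X.shape[1])]))


def _match_rows(X: np.ndarray, Xsel: np.ndarray) -> None:
    for i, row in enumerate(Xsel):
        if not np.any(np.all(np.isclose(X, row, atol=1e-12), axis=1)):
            raise ValueError(f"selected row {i} is not a row of the full matrix")


def hypersphere_overlap(X, Xsel, r: float | None = None) -> float:
    """Hypersphere overlap of a subset, relative to the full matrix.

    Features are min-max normalized per column using the *full* matrix.
    Each selected point carries a sphere of radius ``r`` (default: half the
    mean nearest-neighbor distance of the full normalized data).  The score
    is the pairwise sphere-overlap term Σ_{i<j, d_ij<2r} (1 − d_ij/(2r))
    plus an edge penalty Σ_i Σ_j max(0, 1 − e_ij/r) for spheres spilling
    over the unit-box boundary, where ``e_ij`` is the distance of point
    ``i`` to the nearer wall of dimension ``j``.  Lower = better spread.
    """
    X = validate_feature_matrix(X)
    Xs = validate_feature_matrix(Xsel, name="Xsel")
    if X.shape[1] != Xs.shape[1]:
        raise ValueError("X and Xsel must share the feature dimension")
    _match_rows(X, Xs)
    lo, hi = X.min(axis=0), X.max(axis=0)
    rng = np.where(hi > lo, hi - lo, 1.0)
    Xn = (X - lo) / rng
    Xsn = (Xs - lo) / rng
    if r is None:
        if X.shape[0] < 2:
            raise ValueError("cannot infer a radius from a single sample")
        D = squareform(pdist(Xn))
        np.fill_diagonal(D, np.inf)
        r = 0.5 * float(D.min(axis=1).mean())
    if r <= 0:
        raise ValueError("radius must be positive")
    pair = 0.0
    if Xsn.shape[0] >= 2:
        dists = pdist(Xsn)
        close = dists < 2 * r
        pair = float(np.sum(1.0 - dists[close] / (2 * r)))
    edge_dist = np.minimum(Xsn, 1.0 - Xsn)
    edge = float(np.sum(np.maximum(0.0, 1.0 - edge_dist / r)))
    return pair + edge


def compute_diversity(measure: str, Xsel, X=None, cs: int = 1, r=None) -> DiversityReport:
    """Dispatch a named measure and wrap the result in a DiversityReport."""
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; valid: {sorted(MEASURES)}")
    if measure == "logdet":
        value = logdet_diversity(Xsel)
    elif measure == "shannon":
        value = shannon_entropy(Xsel)
    elif measure == "edi":
        value = explicit_diversity_index(Xsel, cs=cs)
    elif measure == "gini":
        value = gini_coefficient(Xsel)
    elif measure == "wdud":
        value = wdud(Xsel)
    else:
        if X is None:
            raise ValueError("hypersphere overlap needs the full matrix X")
        value = hypersphere_overlap(X, Xsel, r=r)
    arrays = (Xsel,) if X is None else (Xsel, X)
    return DiversityReport(
        measure=measure,
        value=float(value),
        direction=MEASURES[measure],
        inputs_hash=_hash_arrays(*arrays),
    )
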