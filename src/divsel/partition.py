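"""Partition-based selection: bin the feature space, then sample per cell.

Four binning schemes are supported, the cross of {equisized, equifrequent}
× {independent, dependent}:

* ``equisized_independent`` — per-dimension edges uniform over the observed
  range, each dimension binned independently.
* ``equifrequent_independent`` — per-dimension edges at empirical quantiles,
  so bins hold approximately equal counts.
* ``equisized_dependent`` / ``equifrequent_dependent`` — dimensions are
  processed in column order; within each parent cell of the already-binned
  dimensions, the next dimension's edges are recomputed from only the
  samples in that cell, so feature order affects the outcome.

Selection then visits non-empty cells round-robin in ascending occupancy
(rare regions are guaranteed representation first) and takes each cell's
most central unselected sample — or a seeded uniform draw when
``random_in_cell`` is set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .base import (
    BaseSubsetSelector,
    SelectionResult,
    validate_feature_matrix,
)

__all__ = ["BinGrid", "partition", "GridPartitionSelector", "select_partition"]

SCHEMES = (
    "equisized_independent",
    "equisized_dependent",
    "equifrequent_independent",
    "equifrequent_dependent",
)


@dataclass
class BinGrid:
    """Assignment of samples to multi-dimensional grid cells.

    ``assignment[i]`` is the tuple of per-dimension bin indices of sample
    ``i``; ``cells`` maps each non-empty cell id to the sample indices it
    holds.
    """

    scheme: str
    nbins_per_dim: int
    assignment: list[tuple]

    @property
    def cells(self) -> dict:
        out: dict[tuple, list[int]] = {}
        for i, cell in enumerate(self.assignment):
            out.setdefault(cell, []).append(i)
        return out


def _digitize(values: np.ndarray, edges: np.ndarray, nbins: int) -> np.ndarray:
    """Bin index per value; the last interval is right-closed."""
    idx = np.searchsorted(edges[1:-1], values, side="right")
    return np.clip(idx, 0, nbins - 1)


def _edges(values: np.ndarray, nbins: int, equifrequent: bool) -> np.ndarray:
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:  # constant dimension: single degenerate bin
        return np.array([lo, hi])
    if equifrequent:
        qs = np.linspace(0.0, 1.0, nbins + 1)
        edges = np.quantile(values, qs)
        edges[0], edges[-1] = lo, hi
        return edges
    return np.linspace(lo, hi, nbins + 1)


def partition(X, scheme: str = "equisized_independent", nbins_per_dim: int = 2) -> BinGrid:
    """Partition the feature space and assign every sample to one cell.

    Parameters
    ----------
    X : array-like of shape (s, d)
    scheme : str
        One of ``equisized_independent``, ``equisized_dependent``,
        ``equifrequent_independent``, ``equifrequent_dependent``.
    nbins_per_dim : int
        Number of bins along each dimension (>= 1).  Constant dimensions
        collapse to a single degenerate bin.
    """
    X = validate_feature_matrix(X)
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; valid: {SCHEMES}")
    if nbins_per_dim < 1:
        raise ValueError("nbins_per_dim must be >= 1")
    s, d = X.shape
    if nbins_per_dim**d > 10**6:
        warnings.warn(
            f"grid has {nbins_per_dim}**{d} cells; consider fewer bins or dims",
            UserWarning,
            stacklevel=2,
        )
    equifrequent = scheme.startswith("equifrequent")
    dependent = scheme.endswith("dependent") and not scheme.endswith("independent")

    assignment = np.zeros((s, d), dtype=int)
    if not dependent:
        for j in range(d):
            col = X[:, j]
            edges = _edges(col, nbins_per_dim, equifrequent)
            nb = len(edges) - 1
            assignment[:, j] = _digitize(col, edges, nb)
    else:
        # recurse over parent cells of the previously processed dimensions
        groups = {(): np.arange(s)}
        for j in range(d):
            new_groups: dict[tuple, np.ndarray] = {}
            for parent, members in groups.items():
                col = X[members, j]
                edges = _edges(col, nbins_per_dim, equifrequent)
                nb = len(edges) - 1
                bins = _digitize(col, edges, nb)
                assignment[members, j] = bins
                for b in np.unique(bins):
                    new_groups[parent + (int(b),)] = members[bins == b]
            groups = new_groups
    return BinGrid(
        scheme=scheme,
        nbins_per_dim=nbins_per_dim,
        assignment=[tuple(int(b) for b in row) for row in assignment],
    )


class GridPartitionSelector(BaseSubsetSelector, BaseEstimator):
    """Diverse selection by feature-space partitioning.

    The space is binned with the configured scheme, and non-empty cells are
    visited round-robin in ascending occupancy (ties broken by lexicographic
    cell id); every visit takes the cell's most central unselected sample
    (the cell medoid under euclidean distance, ties to the lowest index),
    or a seeded uniform draw with ``random_in_cell=True``.  Passes repeat
    until ``n_select`` samples are collected, so every non-empty cell is
    covered before any cell contributes twice.

    Parameters
    ----------
    n_select : int
    scheme : str
        Binning scheme (see :func:`partition`).
    nbins_per_dim : int or None
        ``None`` defaults to ``ceil(n_select ** (1/d))`` so the grid has at
        least about ``n_select`` cells.
    random_in_cell : bool
        Uniform seeded within-cell choice instead of the cell medoid.
    random_state : int or None
    """

    _method = "grid_partition"

    def __init__(
        self,
        n_select=2,
        scheme="equisized_independent",
        nbins_per_dim=None,
        random_in_cell=False,
        random_state=None,
    ):
        self.n_select = n_select
        self.scheme = scheme
        self.nbins_per_dim = nbins_per_dim
        self.random_in_cell = random_in_cell
        self.random_state = random_state

    def _select(self, X):
        X = validate_feature_matrix(X)
        s, d = X.shape
        n = self.n_select
        if not 1 <= n <= s:
            raise ValueError(f"n={n} must be in [1, {s}]")
        nbins = self.nbins_per_dim
        if nbins is None:
            nbins = int(np.ceil(n ** (1.0 / d)))
        grid = partition(X, scheme=self.scheme, nbins_per_dim=nbins)
        cells = grid.cells
        # ascending occupancy, ties by lexicographic cell id
        order = sorted(cells, key=lambda c: (len(cells[c]), c))
        rng = np.random.default_rng(self.random_state)

        remaining = {c: list(cells[c]) for c in order}
        selected: list[int] = []
        while len(selected) < n:
            progressed = False
            for c in order:
                if len(selected) >= n:
                    break
                members = remaining[c]
                if not members:
                    continue
                if self.random_in_cell:
                    pick = int(rng.choice(members))
                else:
                    pts = X[members]
                    # cell medoid: min sum of euclidean distances within cell
                    diff = pts[:, None, :] - pts[None, :, :]
                    sums = np.sqrt((diff**2).sum(axis=2)).sum(axis=1)
                    pick = members[int(np.argmin(sums))]
                members.remove(pick)
                selected.append(pick)
                progressed = True
            if not progressed:
                raise RuntimeError("ran out of samples before reaching n")
        return selected


def select_partition(
    X, n, scheme="equisized_independent", nbins_per_dim=None, seed=None,
    random_in_cell=False,
) -> SelectionResult:
    """Functional wrapper over :class:`GridPartitionSelector`."""
    est = GridPartitionSelector(
        n_select=n,
        scheme=scheme,
        nbins_per_dim=nbins_per_dim,
        random_in_cell=random_in_cell,
        random_state=seed,
    ).fit(X)
    return est.result_
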