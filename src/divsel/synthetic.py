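"""Synthetic datasets exercising every selector and diversity measure.

Four generator families, all seeded and bit-reproducible:

* isotropic Gaussian blobs (labeled clusters, for the 2-D demonstrations);
* random binary fingerprints (Bernoulli bits, for the binary-only methods);
* a biased, class-imbalanced cluster dataset whose default class sizes
  [98, 19, 10, 9, 7, 2] mirror a curated set of 145 organic compounds
  (98 alkanes, 19 alcohols, 10 aldehydes, 9 ketones, 7 benzene derivatives,
  2 cycloalkanes);
* Boltzmann-weighted samples of a two-dimensional four-well potential
  energy surface, at a configurable bias sharpness ``k`` — the strongly
  biased sample (large ``k``) concentrates around the deep minima and all
  but misses the shallow well, while a mild bias covers the surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from sklearn.datasets import make_blobs

__all__ = [
    "gaussian_blobs",
    "random_fingerprints",
    "biased_class_dataset",
    "four_well_potential",
    "four_well_minima",
    "FourWellParams",
    "mc_boltzmann_sample",
    "BIASED_CLASS_SIZES",
    "redundant_and_diverse_points",
    "redundant_and_diverse_fingerprints",
]

BIASED_CLASS_SIZES = (98, 19, 10, 9, 7, 2)

# tilt coefficients making the four wells unequal in depth, one shallow
_TILT = (0.08, 0.16)


def gaussian_blobs(n_samples=100, centers=2, spread=1.0, seed=0):
    """Isotropic Gaussian clusters with integer labels.

    ``centers`` may be a count or an explicit array of center coordinates;
    ``spread`` is the per-cluster standard deviation.
    """
    X, y = make_blobs(
        n_samples=n_samples,
        centers=centers,
        cluster_std=spread,
        random_state=seed,
    )
    return X, y.astype(int)


def random_fingerprints(n, d, on_density=0.3, seed=0) -> np.ndarray:
    """n×d binary matrix of independent Bernoulli(on_density) bits."""
    if not 0.0 < on_density < 1.0:
        raise ValueError("on_density must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    return (rng.random((n, d)) < on_density).astype(float)


def biased_class_dataset(
    class_sizes=BIASED_CLASS_SIZES, class_separation=10.0, spread=1.0, seed=0
):
    """Class-imbalanced Gaussian clusters (default sizes sum to 145).

    Cluster centers sit on a circle of radius ``class_separation``; with the
    default separation ten times the spread the classes are well separated,
    so distance-based selection can demonstrate full class coverage where
    uniform random selection misses the rare classes.
    """
    sizes = [int(c) for c in class_sizes]
    if len(sizes) < 2:
        raise ValueError("need at least two classes")
    k = len(sizes)
    angles = 2 * np.pi * np.arange(k) / k
    centers = class_separation * np.column_stack([np.cos(angles), np.sin(angles)])
    rng = np.random.default_rng(seed)
    X = np.vstack(
        [centers[i] + spread * rng.standard_normal((sizes[i], 2)) for i in range(k)]
    )
    y = np.repeat(np.arange(k), sizes)
    return X, y


def four_well_potential(q1, q2):
    """Two-dimensional four-well potential energy surface.

    V(q1, q2) = (q1² − 1)² + (q2² − 1)² + t1·q1 + t2·q2 with small tilts
    (t1, t2) = (0.08, 0.16): four local minima near (±1, ±1) of unequal
    depth, the deepest near (−1, −1) and a shallow one near (+1, +1), all
    inside [−3, 3]².
    """
    q1 = np.asarray(q1, dtype=float)
    q2 = np.asarray(q2, dtype=float)
    t1, t2 = _TILT
    return (q1**2 - 1) ** 2 + (q2**2 - 1) ** 2 + t1 * q1 + t2 * q2


def four_well_minima():
    """Coordinates and energies of the four local minima, deepest first."""
    found = []
    for s1 in (-1.0, 1.0):
        for s2 in (-1.0, 1.0):
            res = minimize(
                lambda q: float(four_well_potential(q[0], q[1])),
                x0=[s1, s2],
                method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-12},
            )
            found.append((res.x.copy(), float(res.fun)))
    found.sort(key=lambda t: t[1])
    coords = np.array([c for c, _ in found])
    energies = np.array([e for _, e in found])
    return coords, energies


@dataclass
class FourWellParams:
    """Monte-Carlo Boltzmann sampling parameters for the four-well surface.

    ``k`` is the dimensionless bias sharpness in the weight
    exp(−1.5·k·(V − V_D)), with V_D the deepest minimum's energy; ``pool``
    uniform candidate points are drawn over ``q_range``² and ``output`` of
    them kept with probability proportional to their Boltzmann weight.
    Desk-scale defaults (pool 10⁵, output 10³) stand in for the full-scale
    10⁷ / 10⁴ demonstration.
    """

    k: float = 2.0
    pool: int = 100_000
    output: int = 1_000
    q_range: tuple = (-3.0, 3.0)
    seed: int = 0

    def __post_init__(self):
        if self.k <= 0:
            raise ValueError("bias k must be > 0")
        if self.output > self.pool:
            raise ValueError("output size cannot exceed the pool size")
        lo, hi = self.q_range
        coords, _ = four_well_minima()
        if coords.min() < lo or coords.max() > hi:
            raise ValueError("q_range must contain all four minima")


def mc_boltzmann_sample(params: FourWellParams) -> np.ndarray:
    """Boltzmann-weighted point cloud on the four-well surface.

    Draws ``pool`` uniform points in ``q_range``², weights each by
    w = exp(−1.5·k·(V − V_D)) ∈ (0, 1], and returns exactly ``output``
    distinct points sampled without replacement with probability
    proportional to w (importance-weighted selection; w = 1 only at the
    deepest minimum).
    """
    rng = np.random.default_rng(params.seed)
    lo, hi = params.q_range
    pts = rng.uniform(lo, hi, size=(params.pool, 2))
    _, energies = four_well_minima()
    v_d = energies[0]
    w = np.exp(-1.5 * params.k * (four_well_potential(pts[:, 0], pts[:, 1]) - v_d))
    if np.count_nonzero(w) < params.output:
        raise ValueError("pool too small for the requested output size")
    idx = rng.choice(params.pool, size=params.output, replace=False, p=w / w.sum())
    return pts[idx]


def redundant_and_diverse_points(n=20, seed=0, clump_fraction=0.9, clump_std=0.02):
    """Paired same-size subsets of the unit box for diversity-direction checks.

    The *redundant* set mimics a poor selection: a dense clump at the box
    center plus a few stragglers that set the observed range.  The *diverse*
    set covers the box near-uniformly.  Every direction-convention measure
    should rank the diverse set as more diverse.

    Returns ``(redundant, diverse)``, each of shape (n, 2).
    """
    rng = np.random.default_rng(seed)
    nc = int(clump_fraction * n)
    clump = 0.5 + clump_std * rng.standard_normal((nc, 2))
    stragglers = rng.uniform(0.0, 1.0, (n - nc, 2))
    redundant = np.vstack([clump, stragglers])
    diverse = rng.uniform(0.0, 1.0, (n, 2))
    return redundant, diverse


def redundant_and_diverse_fingerprints(n=20, d=32, seed=0, mutation_rate=0.05):
    """Paired binary sets: prototype-mutated (redundant) vs independent bits.

    The redundant set copies one prototype fingerprint with a small per-bit
    mutation rate, so bit usage is lopsided and neighbors are near-identical;
    the diverse set draws every bit independently at density 0.5.
    """
    rng = np.random.default_rng(seed)
    proto = (rng.random(d) < 0.5).astype(float)
    flips = rng.random((n, d)) < mutation_rate
    redundant = np.where(flips, 1.0 - proto, proto)
    diverse = (rng.random((n, d)) < 0.5).astype(float)
    return redundant, diverse
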