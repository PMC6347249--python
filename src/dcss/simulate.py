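"""Synthetic expression matrices with known structure.

Three generators back the test and example surface:

* ``toy_matrix`` — the 2 x 3 worked example where per-column thresholds
  and leverage-based selection disagree (two collinear high-count
  columns, one independent low-count column);
* ``simulate_counts`` — a planted-cluster Poisson count matrix emulating
  the gross traits of single-cell count data: non-negative sparse
  counts, a small block of structured ("informative") features that are
  highly expressed in exactly one cluster each, and a large background
  of low-rate noise features, giving a power-law-like decay of sorted
  leverage scores;
* ``power_law_profile`` — an exact power-law leverage profile for
  validating the closed-form selection-size prediction and the log-log
  fit.

All randomness flows through an explicit integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .matrix import ExpressionMatrix
from .leverage import LeverageProfile

__all__ = ["SyntheticSpec", "toy_matrix", "simulate_counts", "power_law_profile"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-cluster Poisson simulator.

    Defaults are the desk-scale study conditions used throughout the
    tests: 200 cells, 3 clusters, 30 informative features against 500
    noise features, Poisson mean 50 for a feature in its "on" cluster
    and 0.5 elsewhere.
    """

    n_cells: int = 200
    n_informative_features: int = 30
    n_noise_features: int = 500
    n_clusters: int = 3
    cluster_mean_scale: float = 50.0
    noise_rate: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.n_informative_features < 1:
            raise ValueError("need at least one cell and one informative feature")
        if self.n_noise_features < 0:
            raise ValueError("n_noise_features must be >= 0")
        if not 1 <= self.n_clusters <= self.n_cells:
            raise ValueError("n_clusters must be in 1..n_cells")
        if self.cluster_mean_scale < 0 or self.noise_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.seed is None:
            raise ValueError("seed is mandatory")


def toy_matrix() -> ExpressionMatrix:
    """The 2 x 3 worked example: rows (40, 20, 10) and (20, 10, 15).

    Column 1 is exactly twice column 2, so count/variance/dispersion
    thresholds keep a rank-1 pair {1, 2} while rank-2 leverage selection
    keeps the rank-2 pair {1, 3} (1-based).
    """
    return ExpressionMatrix(
        np.array([[40.0, 20.0, 10.0], [20.0, 10.0, 15.0]]),
        cell_ids=["cell_a", "cell_b"],
        feature_ids=["f1", "f2", "f3"],
    )


def simulate_counts(
    spec: SyntheticSpec,
) -> tuple[ExpressionMatrix, np.ndarray, np.ndarray]:
    """Planted-cluster Poisson counts.

    Cells are assigned round-robin to clusters (cell i -> cluster
    i mod n_clusters) so cluster sizes are exactly reproducible.  The
    informative features are split evenly across clusters; feature block
    c is Poisson(cluster_mean_scale) in cells of cluster c and
    Poisson(noise_rate) elsewhere.  Noise features are
    Poisson(noise_rate) everywhere.

    Returns (matrix, planted cell labels, informative column indices).
    Informative columns come first (indices 0..n_informative-1).
    """
    rng = np.random.default_rng(spec.seed)
    n, c = spec.n_cells, spec.n_clusters
    labels = np.arange(n) % c
    blocks = np.array_split(np.arange(spec.n_informative_features), c)
    lam = np.full((n, spec.n_informative_features), spec.noise_rate)
    for cl, cols in enumerate(blocks):
        lam[np.ix_(labels == cl, cols)] = spec.cluster_mean_scale
    informative = rng.poisson(lam)
    noise = rng.poisson(
        spec.noise_rate, size=(n, spec.n_noise_features)
    )
    values = sp.csr_matrix(
        np.hstack([informative, noise]).astype(float)
    )
    d = values.shape[1]
    A = ExpressionMatrix(
        values,
        cell_ids=[f"cell_{i}" for i in range(n)],
        feature_ids=[f"feature_{j}" for j in range(d)],
    )
    return A, labels, np.arange(spec.n_informative_features)


def power_law_profile(d: int, a: float, k: int) -> tuple[LeverageProfile, bool]:
    """An exact power-law leverage profile: tau at sorted rank i (1-based)
    proportional to i^(-a), rescaled so the scores sum to k.

    When the rescale would push the top score past 1 (leverage scores are
    bounded by 1), leading scores are clipped to 1 and the tail is
    renormalized; the returned flag reports whether clipping occurred, in
    which case the profile is power-law only in its tail.
    """
    if a <= 1:
        raise ValueError("power-law exponent must exceed 1")
    if not 1 <= k <= d:
        raise ValueError("need 1 <= k <= d")
    raw = np.arange(1, d + 1, dtype=float) ** (-a)
    tau = raw * (k / raw.sum())
    clipped = False
    # clip leading scores at the 1.0 ceiling, redistribute onto the tail
    for n_clip in range(d):
        if tau[n_clip] <= 1.0 + 1e-12:
            break
        clipped = True
        tail = raw[n_clip + 1 :]
        tau[n_clip] = 1.0
        remaining = k - (n_clip + 1)
        if remaining <= 0 or tail.sum() == 0:
            tau[n_clip + 1 :] = 0.0
            break
        tau[n_clip + 1 :] = tail * (remaining / tail.sum())
    tau = np.minimum(tau, 1.0)
    tau *= k / tau.sum()
    return (
        LeverageProfile(scores=tau, k=k, order=np.arange(d)),
        clipped,
    )
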