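"""Clustering-concordance evaluation for feature selections.

The evaluation protocol treats each cell as a probability mass function
over features (its count vector normalized to sum to one), measures
pairwise Jensen-Shannon distances between cells, spectral-clusters the
resulting similarity matrix, and scores a selection by the adjusted Rand
index between clusters from the selected submatrix and clusters from the
complete matrix, averaged over repeated k-means initializations.  The
complete-data clustering plays the role of ground truth: real data has
no labeled truth, so concordance with the full profile is the operative
quality measure for a feature filter.

Distances use the base-2 Jensen-Shannon distance (square root of the
base-2 JS divergence), which is a metric bounded by 1, so the similarity
S = 1 - D_JS is non-negative.  The spectral step is the classic
symmetric-normalized-Laplacian recipe: embed cells in the leading
eigenvector space of Deg^{-1/2} S Deg^{-1/2} and run k-means there.

The ARI is computed from the pair-counting contingency-table formula
directly; scikit-learn's implementation serves as an independent
cross-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.special import comb
from sklearn.cluster import KMeans

from .matrix import ExpressionMatrix

__all__ = [
    "CellPMFMatrix",
    "ClusterAssignment",
    "ComparisonReport",
    "rows_to_pmf",
    "js_distance_matrix",
    "spectral_cluster",
    "adjusted_rand_index",
    "concordance_experiment",
]

_LN2 = np.log(2.0)


@dataclass(frozen=True)
class CellPMFMatrix:
    """Cells as probability mass functions over features (rows sum to 1)."""

    values: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        rs = self.values.sum(axis=1)
        if self.values.size and not np.allclose(rs, 1.0, atol=1e-10):
            raise ValueError("rows of a PMF matrix must sum to 1")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class ClusterAssignment:
    labels: np.ndarray
    n_clusters: int
    seed: int

    def __post_init__(self) -> None:
        if self.labels.min() < 0 or self.labels.max() >= self.n_clusters:
            raise ValueError("labels out of range for n_clusters")


@dataclass(frozen=True)
class ComparisonReport:
    """Mean/sd ARI of each thresholded workflow against the complete-data
    workflow, over T k-means restarts sharing seeds with the reference."""

    n_clusters: int
    T: int
    seed: int
    mean_ari: dict[str, float]
    sd_ari: dict[str, float]
    per_restart_ari: dict[str, list[float]]
    n_cells_dropped: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_clusters": self.n_clusters,
            "T": self.T,
            "seed": self.seed,
            "mean_ari": self.mean_ari,
            "sd_ari": self.sd_ari,
            "n_cells_dropped": self.n_cells_dropped,
        }


def rows_to_pmf(A: ExpressionMatrix) -> CellPMFMatrix:
    """Normalize each cell's count vector to sum to one.

    A cell with zero total count has no probability mass function; such
    rows raise, naming the offending cells, so the caller can drop them
    explicitly (the concordance harness does this per selection).
    """
    dense = A.dense()
    rs = dense.sum(axis=1)
    zero = np.nonzero(rs <= 0)[0]
    if zero.size:
        names = ", ".join(str(A.cell_ids[i]) for i in zero[:10])
        raise ValueError(
            f"{zero.size} cell(s) have zero total count and no PMF: {names}"
        )
    return CellPMFMatrix(values=dense / rs[:, None], cell_ids=A.cell_ids)


def js_distance_matrix(P: CellPMFMatrix) -> np.ndarray:
    """Pairwise base-2 Jensen-Shannon distances between cells.

    D_JS(p, q) = sqrt( (1/2) KL(p || m) + (1/2) KL(q || m) ),
    m = (p + q)/2, logs base 2, so D_JS is a metric with values in
    [0, 1]: 0 for identical PMFs, 1 for disjoint supports.  Computed via
    scipy's natural-log JS distance rescaled by 1/sqrt(ln 2).
    """
    dist = pdist(P.values, metric="jensenshannon") / np.sqrt(_LN2)
    D = squareform(np.clip(dist, 0.0, 1.0))
    return D


def spectral_cluster(
    D: np.ndarray,
    n_clusters: int,
    seed: int,
    k_embed: int | None = None,
    renormalize_rows: bool = False,
) -> ClusterAssignment:
    """Spectral clustering of a distance matrix via the normalized Laplacian.

    Converts distances to similarities S = 1 - D, forms the
    symmetric-normalized operator Deg^{-1/2} S Deg^{-1/2}, embeds each
    cell in the k_embed leading eigenvectors (default k_embed =
    n_clusters), and k-means clusters the embedding with seeded k-means++
    and 10 internal restarts.  Set ``renormalize_rows`` to project the
    embedding onto the unit sphere before k-means.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be square and symmetric")
    if n_clusters < 1 or n_clusters > n:
        raise ValueError("n_clusters out of range")
    if k_embed is None:
        k_embed = n_clusters
    S = 1.0 - D
    deg = S.sum(axis=1)
    if np.any(deg <= 0):
        raise ValueError("similarity graph has a zero-degree cell")
    d_isqrt = 1.0 / np.sqrt(deg)
    M = (S * d_isqrt[:, None]) * d_isqrt[None, :]
    # leading eigenvectors of the normalized similarity = smallest of L_sym
    eigvals, eigvecs = np.linalg.eigh((M + M.T) / 2.0)
    embed = eigvecs[:, ::-1][:, :k_embed]
    if renormalize_rows:
        norms = np.linalg.norm(embed, axis=1)
        embed = embed / np.where(norms > 0, norms, 1.0)[:, None]
    km = KMeans(
        n_clusters=n_clusters, n_init=10, random_state=int(seed) % (2**31)
    ).fit(embed)
    return ClusterAssignment(
        labels=km.labels_.astype(int), n_clusters=n_clusters, seed=seed
    )


def adjusted_rand_index(labels1, labels2) -> float:
    """Chance-corrected pair-counting agreement of two partitions.

    From the contingency table N with row sums a_i and column sums b_j
    over n items:

        index    = sum_ij C(N_ij, 2)
        expected = sum_i C(a_i,2) * sum_j C(b_j,2) / C(n,2)
        maximum  = (sum_i C(a_i,2) + sum_j C(b_j,2)) / 2
        ARI      = (index - expected) / (maximum - expected)

    Returns 1 for identical partitions (up to label names), ~0 for
    independent labelings; symmetric in its arguments.  Both partitions
    trivial (each a single block, or all singletons) gives 1 by
    convention.
    """
    x = np.asarray(labels1)
    y = np.asarray(labels2)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("labelings must be 1-d and of equal length")
    n = x.shape[0]
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    table = np.zeros((xi.max() + 1, yi.max() + 1), dtype=np.int64)
    np.add.at(table, (xi, yi), 1)
    index = comb(table, 2).sum()
    a = comb(table.sum(axis=1), 2).sum()
    b = comb(table.sum(axis=0), 2).sum()
    expected = a * b / comb(n, 2)
    maximum = (a + b) / 2.0
    if maximum == expected:  # both partitions trivial
        return 1.0
    return float((index - expected) / (maximum - expected))


def concordance_experiment(
    A: ExpressionMatrix,
    selections: dict[str, np.ndarray],
    n_clusters: int,
    T: int = 10,
    seed: int = 0,
    k_embed: int | None = None,
) -> ComparisonReport:
    """Full-vs-submatrix clustering concordance for a set of selections.

    For the complete matrix and each selection: rows_to_pmf -> JS
    distances -> spectral clustering, repeated with seeds seed..seed+T-1.
    Each thresholded workflow at restart t is scored by ARI against the
    complete-data workflow at the same restart seed.  Cells whose counts
    become all-zero under a selection have no PMF there; they are dropped
    from BOTH labelings for that comparison and counted in the report.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    from .selection import extract_submatrix

    full_pmf = rows_to_pmf(A)
    D_full = js_distance_matrix(full_pmf)
    full_labels = [
        spectral_cluster(D_full, n_clusters, seed + t, k_embed).labels
        for t in range(T)
    ]

    per_restart: dict[str, list[float]] = {}
    dropped: dict[str, int] = {}
    for name, idx in selections.items():
        sub = extract_submatrix(A, idx)
        keep = np.nonzero(sub.row_sums() > 0)[0]
        dropped[name] = A.n_cells - keep.shape[0]
        if keep.shape[0] < n_clusters:
            raise ValueError(
                f"selection {name!r} leaves {keep.shape[0]} usable cells, "
                f"fewer than n_clusters={n_clusters}"
            )
        sub_kept = ExpressionMatrix(
            sub.values[keep],
            cell_ids=sub.cell_ids[keep],
            feature_ids=sub.feature_ids,
            require_nonnegative=sub.require_nonnegative,
        )
        D_sub = js_distance_matrix(rows_to_pmf(sub_kept))
        aris = []
        for t in range(T):
            sub_labels = spectral_cluster(
                D_sub, n_clusters, seed + t, k_embed
            ).labels
            aris.append(
                adjusted_rand_index(full_labels[t][keep], sub_labels)
            )
        per_restart[name] = aris

    return ComparisonReport(
        n_clusters=n_clusters,
        T=T,
        seed=seed,
        mean_ari={m: float(np.mean(v)) for m, v in per_restart.items()},
        sd_ari={m: float(np.std(v)) for m, v in per_restart.items()},
        per_restart_ari=per_restart,
        n_cells_dropped=dropped,
    )
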