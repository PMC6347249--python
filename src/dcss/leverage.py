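"""Rank-k factorizations and rank-k subspace leverage scores.

The rank-k subspace leverage score of column a_i of A is the quadratic
form

    tau_i = a_i^T (A_k A_k^T)^+ a_i,

where A_k = U_k diag(sigma) V_k^T is the best rank-k approximation of A
and ^+ is the Moore-Penrose pseudoinverse.  Substituting the SVD factors
collapses the quadratic form:

    a_i^T (A_k A_k^T)^+ a_i
      = a_i^T U_k diag(sigma^-2) U_k^T a_i
      = || diag(sigma^-1) U_k^T a_i ||^2  =  || V_k[i, :] ||^2,

because A^T U_k diag(sigma^-1) = V_k for the top-k triplets.  The
production path therefore just takes squared row norms of V_k — O(dk)
after the factorization, and never forms an n x n pseudoinverse.  Two
independent test oracles guard this identity: the literal pseudoinverse
form above, and the minimum-norm least-squares form (tau_i is the squared
norm of the min-norm solution of A_k x ~ a_i).

Scores satisfy 0 <= tau_i <= 1 and sum to exactly k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .matrix import ExpressionMatrix

__all__ = [
    "RankKFactorization",
    "LeverageProfile",
    "rank_k_factorize",
    "leverage_scores",
    "leverage_scores_pinv_oracle",
    "leverage_scores_lsq_oracle",
    "leverage_scores_custom_subspace",
]

#: relative singular-value cutoff below which a direction is treated as
#: numerically absent (the input is then rank-deficient for the requested k)
RANK_TOL = 1e-10

_ORTHO_TOL = 1e-8


@dataclass(frozen=True)
class RankKFactorization:
    """Top-k singular triplets of a matrix: A_k = U_k diag(sigma) V_k^T."""

    k: int
    U: np.ndarray  # (n, k), orthonormal columns
    sigma: np.ndarray  # (k,), non-increasing, strictly positive
    V: np.ndarray  # (d, k), orthonormal columns

    def __post_init__(self) -> None:
        k = self.k
        if self.U.shape[1] != k or self.V.shape[1] != k or self.sigma.shape != (k,):
            raise ValueError("inconsistent factor shapes for rank k")
        if np.any(np.diff(self.sigma) > 0):
            raise ValueError("singular values must be non-increasing")
        if self.sigma[-1] <= 0:
            raise ValueError("singular values must be strictly positive")
        for M, name in ((self.U, "U"), (self.V, "V")):
            gram = M.T @ M
            if not np.allclose(gram, np.eye(k), atol=_ORTHO_TOL):
                raise ValueError(f"{name} columns are not orthonormal")

    def reconstruct(self) -> np.ndarray:
        """Dense A_k = U_k diag(sigma) V_k^T."""
        return (self.U * self.sigma) @ self.V.T


@dataclass(frozen=True)
class LeverageProfile:
    """Per-column scores tau plus the descending-score sort permutation pi.

    Ties in tau are broken by ascending column index (stable sort), so the
    permutation — and everything downstream that walks it — is
    deterministic.
    """

    scores: np.ndarray  # (d,) non-negative reals summing to k
    k: int
    order: np.ndarray  # (d,) permutation, scores[order] non-increasing

    def __post_init__(self) -> None:
        tau = self.scores
        if np.any(tau < -1e-12) or np.any(tau > 1 + 1e-8):
            raise ValueError("leverage scores must lie in [0, 1]")
        if abs(tau.sum() - self.k) > 1e-8 * max(1.0, self.k):
            raise ValueError(
                f"leverage scores sum to {tau.sum():.12g}, expected k={self.k}"
            )
        srt = np.sort(self.order)
        if not np.array_equal(srt, np.arange(tau.shape[0])):
            raise ValueError("order is not a permutation of 0..d-1")

    @property
    def d(self) -> int:
        return self.scores.shape[0]

    def sorted_scores(self) -> np.ndarray:
        return self.scores[self.order]


def _sorted_order(tau: np.ndarray) -> np.ndarray:
    # stable mergesort on -tau: descending score, ties by ascending index
    return np.argsort(-tau, kind="stable")


def _fix_signs(U: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip each singular-vector pair so the largest-|entry| of the right
    vector is positive.  Makes repeated factorizations bit-comparable."""
    for j in range(V.shape[1]):
        col = V[:, j]
        pivot = np.argmax(np.abs(col))
        if col[pivot] < 0:
            V[:, j] = -col
            U[:, j] = -U[:, j]
    return U, V


def rank_k_factorize(A: ExpressionMatrix, k: int) -> RankKFactorization:
    """Top-k SVD of an expression matrix with a fixed sign convention.

    Uses a dense LAPACK SVD for dense inputs and ARPACK (``svds`` with a
    deterministic start vector) for sparse inputs, so repeated runs give
    identical factors.

    Raises
    ------
    ValueError
        If k is out of range, or the matrix has numerical rank < k
        (sigma_k <= RANK_TOL * sigma_1); the message names the achievable
        rank.
    """
    n, d = A.shape
    if not 1 <= k <= min(n, d):
        raise ValueError(f"k={k} out of range for a {n} x {d} matrix")
    use_sparse = A.is_sparse and k < min(n, d) - 1
    if use_sparse:
        # deterministic start vector: ARPACK output is then reproducible
        v0 = np.full(min(n, d), 1.0 / np.sqrt(min(n, d)))
        U, s, Vt = spla.svds(
            A.values.astype(float), k=k, v0=v0, tol=0, maxiter=None
        )
        desc = np.argsort(-s, kind="stable")
        U, s, Vt = U[:, desc], s[desc], Vt[desc]
    else:
        U, s, Vt = np.linalg.svd(A.dense(), full_matrices=False)
        U, s, Vt = U[:, :k], s[:k], Vt[:k]
    if s[0] == 0 or s[k - 1] <= RANK_TOL * s[0]:
        achievable = int(np.sum(s > RANK_TOL * s[0])) if s[0] > 0 else 0
        raise ValueError(
            f"matrix has numerical rank {achievable} < requested k={k}"
        )
    U, V = _fix_signs(np.ascontiguousarray(U), np.ascontiguousarray(Vt.T))
    return RankKFactorization(k=k, U=U, sigma=s.copy(), V=V)


def leverage_scores(F: RankKFactorization) -> LeverageProfile:
    """Rank-k subspace leverage scores as squared row norms of V_k.

    Algebraically identical to the pseudoinverse quadratic form
    a_i^T (A_k A_k^T)^+ a_i (see module docstring); the identity is
    exercised against :func:`leverage_scores_pinv_oracle` in the tests.
    """
    tau = np.einsum("ij,ij->i", F.V, F.V)
    # clip tiny negative / >1 float noise before the invariant check
    tau = np.clip(tau, 0.0, 1.0)
    tau *= F.k / tau.sum()
    return LeverageProfile(scores=tau, k=F.k, order=_sorted_order(tau))


def leverage_scores_pinv_oracle(A: ExpressionMatrix, k: int) -> LeverageProfile:
    """Literal-definition oracle: tau_i = a_i^T (A_k A_k^T)^+ a_i.

    Forms A_k and the dense n x n pseudoinverse explicitly.  Test-only:
    O(n^2 d) and dense, intended for small matrices (d up to a few
    hundred).
    """
    F = rank_k_factorize(A, k)
    Ak = F.reconstruct()
    P = np.linalg.pinv(Ak @ Ak.T)
    dense = A.dense()
    tau = np.einsum("ni,nm,mi->i", dense, P, dense)
    tau = np.clip(tau, 0.0, None)
    return LeverageProfile(scores=tau, k=k, order=_sorted_order(tau))


def leverage_scores_lsq_oracle(A: ExpressionMatrix, k: int) -> LeverageProfile:
    """Optimization-form oracle: tau_i = ||x_hat||^2 with x_hat the
    minimum-norm least-squares solution of A_k x ~ a_i.

    Independent of the V-row-norm route: solves d small least-squares
    problems through the pseudoinverse of A_k itself.  Test-only.
    """
    F = rank_k_factorize(A, k)
    Ak_pinv = np.linalg.pinv(F.reconstruct())
    X = Ak_pinv @ A.dense()  # column i = min-norm solution for a_i
    tau = np.einsum("ji,ji->i", X, X)
    tau = np.clip(tau, 0.0, None)
    return LeverageProfile(scores=tau, k=k, order=_sorted_order(tau))


def leverage_scores_custom_subspace(
    A: ExpressionMatrix, component_indices: set[int] | list[int]
) -> LeverageProfile:
    """Leverage scores for an arbitrary set of singular components.

    The selection machinery is not tied to the leading-k subspace: scores
    can be computed for any subset of singular vectors (e.g. drop
    component 0 when it tracks batch or library size, keep component 1).
    Scores are squared row norms of V restricted to the named components
    and sum to the number of components.
    """
    comps = sorted(set(int(c) for c in component_indices))
    if not comps:
        raise ValueError("component_indices must be non-empty")
    if comps[0] < 0:
        raise ValueError("component indices must be non-negative")
    k_needed = comps[-1] + 1
    F = rank_k_factorize(A, k_needed)  # errors if beyond numerical rank
    Vsub = F.V[:, comps]
    tau = np.einsum("ij,ij->i", Vsub, Vsub)
    tau = np.clip(tau, 0.0, 1.0)
    tau *= len(comps) / tau.sum()
    return LeverageProfile(scores=tau, k=len(comps), order=_sorted_order(tau))
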