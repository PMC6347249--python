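"""Runtime verification of the selection guarantees.

The selected submatrix C of a DCSS run with parameters (k, epsilon)
satisfies, with P = U_k U_k^T the projector onto the leading rank-k left
subspace of A:

  * Loewner two-sided bound
        (1 - eps) A_k A_k^T  <=  P C C^T P  <=  A_k A_k^T
    (and the looser upper bound with 1 + eps), meaning the projected
    square of C approximates A_k A_k^T to relative accuracy eps in the
    positive-semidefinite order;
  * Frobenius bound   (1 - eps) ||A_k||_F^2 <= ||C||_F^2 <= ||A||_F^2;
  * a likelihood identity: under the degenerate Gaussian model
    a_i ~ N(0, A_k A_k^T) i.i.d. over columns, dropping the unselected
    columns changes the total log-likelihood by exactly
    eps_tilde/2 plus a normalization constant, so the data likelihood is
    preserved up to a factor < exp(eps/2).

All checks are algebraic reductions to k x k matrices: with G =
U_k^T C C^T U_k and D = diag(sigma^2), the projected n x n statement
P C C^T P - (1-eps) A_k A_k^T >= 0 holds iff G - (1-eps) D >= 0, because
both sides vanish off the k-dimensional subspace.

Also here: the power-law description of sorted leverage profiles
tau_{pi_i} = tau_{pi_0} * i^(-a), the closed-form predicted selection
size under that decay, and the sample-size bound for randomized
leverage-score column sampling that the deterministic walk undercuts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .matrix import ExpressionMatrix
from .leverage import RankKFactorization, LeverageProfile, leverage_scores
from .selection import DCSSSelection, extract_submatrix

__all__ = [
    "BoundReport",
    "PowerLawFit",
    "LikelihoodReport",
    "verify_spectral_bounds",
    "verify_frobenius_bound",
    "fit_power_law",
    "predicted_dcss_size",
    "random_sampling_size",
    "dcss_beats_sampling",
    "log_likelihood",
    "likelihood_identity_check",
    "eigenvalue_scan",
]


@dataclass(frozen=True)
class BoundReport:
    """Machine-checkable verdicts for the spectral and Frobenius bounds.

    Slacks are the most-negative eigenvalue of each difference matrix; a
    check passes when its slack >= -tol.  tol scales with sigma_1^2 so
    pass/fail is invariant to the overall scale of the data.
    """

    epsilon: float
    tol: float
    lower_slack: float  # eig min of G - (1-eps) D
    upper_slack: float  # eig min of D - G
    upper_slack_relaxed: float  # eig min of (1+eps) D - G
    loewner_lower_ok: bool
    loewner_upper_ok: bool
    two_sided_ok: bool
    frob_A: float  # ||A||_F^2
    frob_Ak: float  # ||A_k||_F^2
    frob_C: float  # ||C||_F^2
    frobenius_lower_ok: bool
    frobenius_upper_ok: bool

    @property
    def all_ok(self) -> bool:
        return (
            self.loewner_lower_ok
            and self.loewner_upper_ok
            and self.two_sided_ok
            and self.frobenius_lower_ok
            and self.frobenius_upper_ok
        )

    def to_dict(self) -> dict:
        return {
            "epsilon": self.epsilon,
            "tol": self.tol,
            "loewner": {
                "lower_slack": self.lower_slack,
                "upper_slack": self.upper_slack,
                "upper_slack_relaxed": self.upper_slack_relaxed,
                "lower_ok": self.loewner_lower_ok,
                "upper_ok": self.loewner_upper_ok,
                "two_sided_ok": self.two_sided_ok,
            },
            "frobenius": {
                "norm_sq_A": self.frob_A,
                "norm_sq_Ak": self.frob_Ak,
                "norm_sq_C": self.frob_C,
                "lower_ok": self.frobenius_lower_ok,
                "upper_ok": self.frobenius_upper_ok,
            },
            "all_ok": self.all_ok,
        }


@dataclass(frozen=True)
class PowerLawFit:
    """Log-log OLS fit of sorted scores: score = b * rank^(-a).

    ``exponent`` is the decay rate a, stored positive for decaying
    profiles (the fitted log-log slope is -a).
    """

    exponent: float
    prefactor: float
    n_top: int
    r_squared: float


@dataclass(frozen=True)
class LikelihoodReport:
    """Both sides of the likelihood identity, computed independently."""

    log_L_A: float
    log_L_C: float
    realized_error: float
    identity_residual: float
    identity_ok: bool


def _loewner_slacks(
    A: ExpressionMatrix, F: RankKFactorization, selection_indices: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """G = U_k^T C C^T U_k and D = diag(sigma^2) in the k-dim basis."""
    C = extract_submatrix(A, selection_indices)
    M = C.values.T @ F.U if not C.is_sparse else (C.values.T @ F.U)
    M = np.asarray(M)
    G = M.T @ M  # = U^T C C^T U, k x k symmetric PSD
    D = np.diag(F.sigma**2)
    return G, D


def verify_spectral_bounds(
    A: ExpressionMatrix,
    F: RankKFactorization,
    selection: DCSSSelection | np.ndarray,
    epsilon: float,
    tol: float | None = None,
) -> BoundReport:
    """Check the Loewner bounds and the Frobenius bound for a selection.

    Accepts a DCSSSelection or a bare index array (so deliberately
    corrupted selections can be audited — the report then flags the
    violated side).  ``tol`` defaults to 1e-8 * sigma_1^2.
    """
    idx = selection.theta if isinstance(selection, DCSSSelection) else np.asarray(selection)
    if tol is None:
        tol = 1e-8 * float(F.sigma[0] ** 2)
    G, D = _loewner_slacks(A, F, idx)
    lower = float(np.linalg.eigvalsh(G - (1 - epsilon) * D).min())
    upper = float(np.linalg.eigvalsh(D - G).min())
    relaxed = float(np.linalg.eigvalsh((1 + epsilon) * D - G).min())

    frob = _frobenius_parts(A, F, idx)
    return BoundReport(
        epsilon=float(epsilon),
        tol=float(tol),
        lower_slack=lower,
        upper_slack=upper,
        upper_slack_relaxed=relaxed,
        loewner_lower_ok=lower >= -tol,
        loewner_upper_ok=upper >= -tol,
        two_sided_ok=lower >= -tol and relaxed >= -tol,
        frob_A=frob[0],
        frob_Ak=frob[1],
        frob_C=frob[2],
        frobenius_lower_ok=frob[2] >= (1 - epsilon) * frob[1] * (1 - 1e-10),
        frobenius_upper_ok=frob[2] <= frob[0] * (1 + 1e-10),
    )


def _frobenius_parts(
    A: ExpressionMatrix, F: RankKFactorization, idx: np.ndarray
) -> tuple[float, float, float]:
    if A.is_sparse:
        frob_A = float(A.values.power(2).sum())
        frob_C = float(A.values[:, np.asarray(idx, dtype=int)].power(2).sum())
    else:
        frob_A = float((A.values**2).sum())
        frob_C = float((A.values[:, np.asarray(idx, dtype=int)] ** 2).sum())
    frob_Ak = float((F.sigma**2).sum())
    return frob_A, frob_Ak, frob_C


def verify_frobenius_bound(
    A: ExpressionMatrix,
    F: RankKFactorization,
    selection: DCSSSelection | np.ndarray,
    epsilon: float,
) -> dict:
    """(1 - eps) ||A_k||_F^2 <= ||C||_F^2 <= ||A||_F^2, relative tol 1e-10."""
    idx = selection.theta if isinstance(selection, DCSSSelection) else np.asarray(selection)
    frob_A, frob_Ak, frob_C = _frobenius_parts(A, F, idx)
    return {
        "norm_sq_A": frob_A,
        "norm_sq_Ak": frob_Ak,
        "norm_sq_C": frob_C,
        "lower_ok": frob_C >= (1 - epsilon) * frob_Ak * (1 - 1e-10),
        "upper_ok": frob_C <= frob_A * (1 + 1e-10),
    }


def fit_power_law(profile: LeverageProfile, n_top: int) -> PowerLawFit:
    """Fit score = b * rank^(-a) to the top-n_top sorted scores.

    Ordinary least squares of log(score) on log(rank) with 1-based ranks,
    restricted to strictly positive scores.  R^2 on the log-log scale is
    returned so the decay assumption can be judged, not just fitted.
    """
    if n_top < 3:
        raise ValueError("need n_top >= 3 for a meaningful fit")
    n_top = min(n_top, profile.d)
    y = profile.sorted_scores()[:n_top]
    if np.any(y <= 0):
        y = y[y > 0]
        if y.shape[0] < 3:
            raise ValueError("fewer than 3 strictly positive scores to fit")
    ranks = np.arange(1, y.shape[0] + 1, dtype=float)
    lx, ly = np.log(ranks), np.log(y)
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    ss_tot = float(((ly - ly.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - float((resid**2).sum()) / ss_tot
    return PowerLawFit(
        exponent=float(-slope),
        prefactor=float(np.exp(intercept)),
        n_top=int(y.shape[0]),
        r_squared=r2,
    )


def predicted_dcss_size(k: int, epsilon: float, a: float) -> tuple[int, float]:
    """Closed-form selection size under exact power-law decay with rate a.

        |Theta| = max( (2k/eps)^(1/(a-1)), (2k(a-1)/eps)^(1/(a-1)) - 1, k )

    Returns (ceil of the raw value, raw value).  Valid only for a > 1;
    as a grows the first two terms collapse and the floor k takes over.
    """
    if a <= 1:
        raise ValueError("power-law exponent must exceed 1")
    if epsilon <= 0 or k < 1:
        raise ValueError("need epsilon > 0 and k >= 1")
    e = 1.0 / (a - 1.0)
    raw = max((2 * k / epsilon) ** e, (2 * k * (a - 1) / epsilon) ** e - 1, float(k))
    return int(math.ceil(raw - 1e-12)), raw


def random_sampling_size(
    k: int, epsilon: float, delta: float, m: int = 0, gamma: float = 0.0
) -> float:
    """Columns needed by randomized leverage sampling for the same bound.

        t >= (2 / eps^2) (k + m*gamma) (1 + eps/3) ln(16 k / delta)

    m is the number of zero-leverage columns, gamma the smallest nonzero
    leverage score, delta the failure probability.
    """
    if not 0 < delta < 1:
        raise ValueError("delta must be in (0, 1)")
    if epsilon <= 0 or k < 1 or m < 0 or gamma < 0:
        raise ValueError("invalid parameters")
    return (
        (2.0 / epsilon**2)
        * (k + m * gamma)
        * (1 + epsilon / 3.0)
        * math.log(16.0 * k / delta)
    )


def dcss_beats_sampling(
    k: int, epsilon: float, a: float, delta: float, m: int = 0, gamma: float = 0.0
) -> bool:
    """True when the deterministic walk needs fewer columns than the
    random-sampling bound at the same (k, epsilon)."""
    _, raw = predicted_dcss_size(k, epsilon, a)
    return raw < random_sampling_size(k, epsilon, delta, m, gamma)


def log_likelihood(
    F: RankKFactorization,
    profile: LeverageProfile,
    column_subset: np.ndarray | None = None,
) -> float:
    """Total log-likelihood of a set of columns under the degenerate
    Gaussian model a_i ~ N(0, A_k A_k^T).

    In log space, with c columns considered:

        log L = -(k c / 2) log 2pi - c * sum_j log sigma_j
                - (1/2) sum_{i in subset} tau_i

    since the quadratic form of column i under (A_k A_k^T)^+ is exactly
    its leverage score.  With all columns, the exponent term is -k/2.
    """
    if column_subset is None:
        tau_sum = float(profile.scores.sum())
        c = profile.d
    else:
        idx = np.asarray(column_subset, dtype=int)
        tau_sum = float(profile.scores[idx].sum())
        c = idx.shape[0]
    k = F.k
    return (
        -0.5 * k * c * math.log(2 * math.pi)
        - c * float(np.log(F.sigma).sum())
        - 0.5 * tau_sum
    )


def likelihood_identity_check(
    F: RankKFactorization,
    profile: LeverageProfile,
    selection: DCSSSelection,
    tol: float = 1e-6,
) -> LikelihoodReport:
    """Verify log L(C) = log L(A) + eps_tilde/2 + normalization.

    Both sides are computed independently: the left from the selected
    columns' own likelihood, the right from the full-data likelihood plus
    the analytic correction

        eps_tilde/2 + (k (d - |Theta|) / 2) log 2pi
                    + (d - |Theta|) sum_j log sigma_j.
    """
    log_L_A = log_likelihood(F, profile)
    log_L_C = log_likelihood(F, profile, selection.theta)
    d, s = profile.d, selection.size
    correction = (
        0.5 * selection.realized_error
        + 0.5 * F.k * (d - s) * math.log(2 * math.pi)
        + (d - s) * float(np.log(F.sigma).sum())
    )
    residual = log_L_C - (log_L_A + correction)
    return LikelihoodReport(
        log_L_A=log_L_A,
        log_L_C=log_L_C,
        realized_error=selection.realized_error,
        identity_residual=float(residual),
        identity_ok=abs(residual) < tol,
    )


def eigenvalue_scan(A: ExpressionMatrix, k_max: int) -> dict:
    """Top-k_max eigenvalues of A A^T (squared singular values), for
    choosing the rank k by the elbow heuristic.

    No automatic elbow detection — the analyst reads the spectrum — but
    the index with the largest consecutive eigenvalue ratio is reported
    as a hint.
    """
    n, d = A.shape
    if not 1 <= k_max <= min(n, d):
        raise ValueError(f"k_max={k_max} out of range")
    if A.is_sparse and k_max < min(n, d) - 1:
        import scipy.sparse.linalg as spla

        v0 = np.full(min(n, d), 1.0 / np.sqrt(min(n, d)))
        s = np.sort(spla.svds(A.values.astype(float), k=k_max, v0=v0,
                              return_singular_vectors=False))[::-1]
    else:
        s = np.linalg.svd(A.dense(), compute_uv=False)[:k_max]
    eigs = s**2
    pos = eigs[eigs > 1e-12 * max(eigs[0], 1.0)]
    hint = 1
    if pos.shape[0] >= 2:
        ratios = pos[:-1] / pos[1:]
        hint = int(np.argmax(ratios)) + 1
    elif pos.shape[0] == 1 and eigs.shape[0] > pos.shape[0]:
        hint = 1  # single dominant direction
    return {
        "eigenvalues": eigs,
        "n_positive": int(pos.shape[0]),
        "elbow_hint": hint,
    }
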