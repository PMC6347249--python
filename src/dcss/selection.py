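"""Greedy deterministic column subset selection and baseline selectors.

The DCSS rule: sort columns by descending rank-k subspace leverage score
and keep adding them to the set Theta until the retained scores sum
strictly past k - epsilon.  Because the scores total exactly k, the
leftover mass eps_tilde = k - sum(selected tau) is the realized error and
satisfies eps_tilde < epsilon.  If fewer than k columns were needed, the
set is padded to size k (the submatrix must be able to carry rank k).

Baselines are the per-column thresholds common in scRNA-Seq quality
control: total count, empirical variance, and index of dispersion
(variance/mean).  Each scores a column in isolation, so none can see
collinearity — the toy-matrix tests show them picking two linearly
dependent columns where DCSS picks a rank-2 pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import ExpressionMatrix
from .leverage import LeverageProfile

__all__ = [
    "DCSSSelection",
    "BaselineSelection",
    "dcss_select",
    "extract_submatrix",
    "threshold_by_score",
    "random_leverage_sample",
    "selection_overlap",
]

BASELINE_METHODS = ("count", "variance", "dispersion")


@dataclass(frozen=True)
class DCSSSelection:
    """Outcome of the greedy leverage walk.

    ``theta`` lists the selected column indices in inclusion order
    (descending leverage).  ``threshold`` is the leverage score of the
    last column kept; ``realized_error`` is the leverage mass left
    outside the selection, k - sum(tau over theta).  ``forced_fill``
    flags selections padded up to size k after the stopping rule was
    already met.
    """

    theta: np.ndarray  # inclusion order
    threshold: float
    realized_error: float
    k: int
    epsilon: float
    forced_fill: bool

    @property
    def size(self) -> int:
        return self.theta.shape[0]

    def to_dict(self) -> dict:
        return {
            "method": "dcss",
            "k": self.k,
            "epsilon": self.epsilon,
            "n_selected": int(self.size),
            "threshold": float(self.threshold),
            "realized_error": float(self.realized_error),
            "forced_fill": bool(self.forced_fill),
            "index_base": 0,
            "indices": [int(i) for i in self.theta],
        }


@dataclass(frozen=True)
class BaselineSelection:
    """A per-column-score selection (count / variance / dispersion) or a
    randomized leverage sample."""

    method: str
    indices: np.ndarray  # unique, in inclusion order
    scores: np.ndarray  # the full per-column score vector used
    threshold: float  # smallest score among the selected
    draws: np.ndarray | None = field(default=None)  # multiplicity record
    # (random_leverage only: the raw with-replacement draws)

    @property
    def size(self) -> int:
        return self.indices.shape[0]

    def to_dict(self) -> dict:
        out = {
            "method": self.method,
            "n_selected": int(self.size),
            "threshold": float(self.threshold),
            "index_base": 0,
            "indices": [int(i) for i in self.indices],
        }
        if self.draws is not None:
            out["n_draws"] = int(self.draws.shape[0])
        return out


def dcss_select(profile: LeverageProfile, epsilon: float) -> DCSSSelection:
    """Run the greedy selection on a leverage profile.

    Walks the descending-score permutation accumulating scores and stops
    at the first prefix whose sum strictly exceeds k - epsilon; pads to
    |Theta| = k if the stopping rule fired earlier than that.  An epsilon
    >= k makes the rule trivially true at the first column — permitted,
    the pad then supplies the remaining k - 1 columns.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    tau_sorted = profile.sorted_scores()
    k = profile.k
    cumsum = np.cumsum(tau_sorted)
    target = k - epsilon
    # first prefix with strict inequality; strictness matters when the
    # cumulative sum lands exactly on k - epsilon
    hits = np.nonzero(cumsum > target)[0]
    if hits.size == 0:  # float shortfall: all columns still needed
        stop = profile.d
    else:
        stop = int(hits[0]) + 1
    forced_fill = stop < k
    n_keep = max(stop, k)
    theta = profile.order[:n_keep].copy()
    kept_mass = float(cumsum[n_keep - 1])
    return DCSSSelection(
        theta=theta,
        threshold=float(tau_sorted[n_keep - 1]),
        realized_error=float(k - kept_mass),
        k=k,
        epsilon=float(epsilon),
        forced_fill=forced_fill,
    )


def extract_submatrix(A: ExpressionMatrix, indices) -> ExpressionMatrix:
    """Column submatrix C = A[:, indices] in the given (inclusion) order.

    Cell ids are preserved, feature ids subset; sparse storage stays
    sparse.
    """
    idx = np.asarray(list(indices), dtype=int)
    if idx.size == 0:
        raise ValueError("cannot extract an empty column subset")
    if np.unique(idx).size != idx.size:
        raise ValueError("duplicate column indices in selection")
    if idx.min() < 0 or idx.max() >= A.n_features:
        raise ValueError("column index out of range")
    sub = A.values[:, idx]
    return ExpressionMatrix(
        sub,
        cell_ids=A.cell_ids,
        feature_ids=A.feature_ids[idx],
        rows_are_cells=A.rows_are_cells,
        require_nonnegative=A.require_nonnegative,
    )


def column_scores(A: ExpressionMatrix, method: str) -> np.ndarray:
    """Per-column score for a simple-thresholding baseline.

    count: column sum (same ordering as the column mean for fixed n, so
    mean-thresholding is subsumed).  variance: population variance
    (divide by n).  dispersion: variance / mean, with 0/0 defined as 0 so
    all-zero columns rank last.
    """
    if method == "count":
        return A.column_sums()
    dense = A.dense()
    var = dense.var(axis=0)  # population convention
    if method == "variance":
        return var
    if method == "dispersion":
        mean = dense.mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            disp = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), 0.0)
        return disp
    raise ValueError(f"unknown method {method!r}; expected {BASELINE_METHODS}")


def threshold_by_score(
    A: ExpressionMatrix, method: str, n_select: int
) -> BaselineSelection:
    """Keep the top ``n_select`` columns by a per-column score.

    Ties are broken by ascending column index (stable sort), mirroring
    the leverage permutation's tie rule.
    """
    if not 1 <= n_select <= A.n_features:
        raise ValueError(
            f"n_select={n_select} out of range for {A.n_features} columns"
        )
    scores = column_scores(A, method)
    order = np.argsort(-scores, kind="stable")
    idx = order[:n_select].copy()
    return BaselineSelection(
        method=method,
        indices=idx,
        scores=scores,
        threshold=float(scores[idx[-1]]),
    )


def random_leverage_sample(
    profile: LeverageProfile, t: int, seed: int
) -> BaselineSelection:
    """Sample t columns i.i.d. with probability tau_i / k, with replacement.

    The standard randomized counterpart of the deterministic walk.
    Duplicate draws are collapsed (first-draw order) for submatrix
    extraction; the raw draw sequence is kept in ``draws`` so callers that
    reweight repeated columns can recover multiplicities.
    """
    if t < 1:
        raise ValueError("t must be >= 1")
    total = profile.scores.sum()
    if total <= 0:
        raise ValueError("cannot sample from an all-zero leverage profile")
    p = profile.scores / total
    rng = np.random.default_rng(seed)
    draws = rng.choice(profile.d, size=t, replace=True, p=p)
    _, first = np.unique(draws, return_index=True)
    idx = draws[np.sort(first)]
    return BaselineSelection(
        method="random_leverage",
        indices=idx,
        scores=profile.scores,
        threshold=float(profile.scores[idx].min()),
        draws=draws,
    )


def selection_overlap(selections: dict[str, np.ndarray], d: int) -> dict:
    """Pairwise and joint overlap of selections over the same d columns.

    ``selections`` maps a method name to its index array.  Returns
    pairwise intersection/union sizes and Jaccard indices plus the
    intersection and union over all methods (the numbers a Venn diagram
    of the selected feature sets would display).
    """
    if len(selections) < 2:
        raise ValueError("need at least two selections to compare")
    sets = {}
    for name, idx in selections.items():
        arr = np.asarray(list(idx), dtype=int)
        if arr.size and (arr.min() < 0 or arr.max() >= d):
            raise ValueError(f"selection {name!r} has indices outside 0..{d - 1}")
        sets[name] = set(arr.tolist())
    names = list(sets)
    pairwise = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            inter = len(sets[a] & sets[b])
            union = len(sets[a] | sets[b])
            pairwise[f"{a}|{b}"] = {
                "intersection": inter,
                "union": union,
                "jaccard": inter / union if union else 1.0,
            }
    all_inter = set.intersection(*sets.values())
    all_union = set.union(*sets.values())
    return {
        "d": d,
        "sizes": {name: len(s) for name, s in sets.items()},
        "pairwise": pairwise,
        "common_to_all": len(all_inter),
        "union_of_all": len(all_union),
    }
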