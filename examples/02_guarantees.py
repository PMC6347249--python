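"""The selection guarantees, checked numerically at run time.

Runs the leverage walk on a random Poisson count matrix and verifies:
the Loewner bounds (the projected square of the submatrix approximates
A_k A_k^T to relative accuracy eps in the positive-semidefinite order),
the Frobenius-norm sandwich, and the likelihood identity under the
degenerate Gaussian reading of the scores.  A corrupted selection shows
the verifier catching a violation.
"""

import numpy as np

from dcss import (
    ExpressionMatrix,
    rank_k_factorize,
    leverage_scores,
    dcss_select,
    verify_spectral_bounds,
    likelihood_identity_check,
)

rng = np.random.default_rng(0)
A = ExpressionMatrix(rng.poisson(5, size=(25, 80)).astype(float))
k, eps = 4, 0.1

F = rank_k_factorize(A, k)
profile = leverage_scores(F)
sel = dcss_select(profile, eps)
print(f"selected {sel.size} of {A.n_features} columns "
      f"(k={k}, eps={eps}); realized error {sel.realized_error:.4f} < {eps}")

report = verify_spectral_bounds(A, F, sel, eps)
print(f"\nLoewner lower slack  {report.lower_slack:12.4f}  (>= -tol: "
      f"{report.loewner_lower_ok})")
print(f"Loewner upper slack  {report.upper_slack:12.4e}  (>= -tol: "
      f"{report.loewner_upper_ok})")
print(f"Frobenius: (1-eps)||A_k||^2 = {(1 - eps) * report.frob_Ak:.1f} "
      f"<= ||C||^2 = {report.frob_C:.1f} <= ||A||^2 = {report.frob_A:.1f}")

lik = likelihood_identity_check(F, profile, sel)
print(f"likelihood identity residual: {lik.identity_residual:.2e} "
      f"(log L(A) = {lik.log_L_A:.2f}, log L(C) = {lik.log_L_C:.2f})")

# corrupt the selection: swap the best column for the worst
bad = sel.theta.copy()
bad[0] = profile.order[-1]
bad_report = verify_spectral_bounds(A, F, np.unique(bad), eps)
print(f"\ncorrupted selection lower slack {bad_report.lower_slack:.4f} -> "
      f"lower bound ok: {bad_report.loewner_lower_ok}")
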