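"""Executable checks of the selection guarantees.

The heart is the randomized suite: across a grid of Poisson count
matrices and (k, epsilon) settings, every selection must pass the
Loewner lower/upper bounds, the relaxed two-sided bound, and the
Frobenius bound, and the likelihood identity must hold to 1e-6.  A
deliberately corrupted selection must fail the lower bound, proving the
verifier can detect violations.
"""

import itertools
import math

import numpy as np
import pytest

from dcss import (
    ExpressionMatrix,
    rank_k_factorize,
    leverage_scores,
    dcss_select,
    verify_spectral_bounds,
    verify_frobenius_bound,
    fit_power_law,
    predicted_dcss_size,
    random_sampling_size,
    dcss_beats_sampling,
    log_likelihood,
    likelihood_identity_check,
    eigenvalue_scan,
    power_law_profile,
)
from conftest import random_count_matrix


@pytest.fixture
def toy_run(toy):
    F = rank_k_factorize(toy, 2)
    prof = leverage_scores(F)
    sel = dcss_select(prof, 0.3)
    return toy, F, prof, sel


class TestSpectralBounds:
    def test_full_selection_is_exactly_tight(self, toy):
        F = rank_k_factorize(toy, 2)
        report = verify_spectral_bounds(toy, F, np.arange(3), epsilon=0.3)
        assert report.all_ok
        # with C = A, G = D exactly: upper slack is ~0, never negative
        assert abs(report.upper_slack) < report.tol

    def test_toy_selection_passes_all_bounds(self, toy_run):
        A, F, _, sel = toy_run
        report = verify_spectral_bounds(A, F, sel, epsilon=0.3)
        assert report.loewner_lower_ok
        assert report.loewner_upper_ok
        assert report.two_sided_ok
        assert report.frobenius_lower_ok and report.frobenius_upper_ok

    def test_corrupted_selection_fails_lower_bound(self, toy):
        # drop the tau = 1.0 column: the kept pair spans only part of the
        # leading subspace and the lower bound must be violated
        F = rank_k_factorize(toy, 2)
        report = verify_spectral_bounds(toy, F, np.array([0, 1]), epsilon=0.3)
        assert not report.loewner_lower_ok
        assert report.lower_slack < -report.tol

    def test_randomized_grid_always_passes(self, rng):
        """Theorem suite: 50 Poisson matrices x (k, eps) grid."""
        matrices = [
            random_count_matrix(
                rng, int(rng.integers(8, 31)), int(rng.integers(40, 101))
            )
            for _ in range(50)
        ]
        grid = list(itertools.product(range(2, 7), (0.05, 0.1, 0.3)))
        for A in matrices:
            for k, eps in grid:
                F = rank_k_factorize(A, k)
                prof = leverage_scores(F)
                sel = dcss_select(prof, eps)
                rep = verify_spectral_bounds(A, F, sel, eps)
                assert rep.all_ok, (A.shape, k, eps, rep.to_dict())
                lik = likelihood_identity_check(F, prof, sel)
                assert abs(lik.identity_residual) < 1e-6


class TestFrobeniusBound:
    def test_toy_frobenius_values(self, toy_run):
        A, F, _, sel = toy_run
        out = verify_frobenius_bound(A, F, sel, 0.3)
        # column sums of squares: 2000, 500, 325 -> C keeps {3, 1}
        assert np.isclose(out["norm_sq_A"], 2825.0)
        assert np.isclose(out["norm_sq_C"], 2000.0 + 325.0)
        assert out["lower_ok"] and out["upper_ok"]

    def test_full_selection_upper_bound_tight(self, toy):
        F = rank_k_factorize(toy, 2)
        out = verify_frobenius_bound(toy, F, np.arange(3), 0.1)
        assert np.isclose(out["norm_sq_C"], out["norm_sq_A"])

    def test_tiny_epsilon_full_rank_forces_near_equality(self, rng):
        A = random_count_matrix(rng, 5, 8)
        F = rank_k_factorize(A, 5)
        prof = leverage_scores(F)
        sel = dcss_select(prof, 1e-9)
        out = verify_frobenius_bound(A, F, sel, 1e-9)
        # all columns selected: ||C||^2 = ||A||^2 >= ||A_k||^2 = ||A||^2
        assert sel.size == 8
        assert np.isclose(out["norm_sq_C"], out["norm_sq_Ak"])


class TestPowerLawFit:
    def test_exact_power_law_recovered_exactly(self):
        prof, _ = power_law_profile(d=100, a=2.0, k=1)
        fit = fit_power_law(prof, 100)
        assert abs(fit.exponent - 2.0) < 1e-6
        assert fit.r_squared > 1 - 1e-12

    def test_constant_profile_has_zero_exponent(self):
        from dcss.leverage import LeverageProfile

        tau = np.full(20, 0.1)
        prof = LeverageProfile(scores=tau, k=2, order=np.arange(20))
        fit = fit_power_law(prof, 20)
        assert abs(fit.exponent) < 1e-12

    def test_noisy_profile_exponent_recovered(self):
        """Multiplicative lognormal noise (sigma = 0.1) on an i^-1.5
        profile: the log-log fit recovers the decay rate within 0.1."""
        rng = np.random.default_rng(11)
        from dcss.leverage import LeverageProfile

        d, a = 400, 1.5
        raw = np.arange(1, d + 1, dtype=float) ** (-a)
        noisy = raw * np.exp(rng.normal(0, 0.1, size=d))
        noisy = np.sort(noisy)[::-1]  # keep the profile sorted
        tau = noisy * (1.0 / noisy.sum())
        prof = LeverageProfile(scores=tau, k=1, order=np.arange(d))
        fit = fit_power_law(prof, d)
        assert abs(fit.exponent - a) < 0.1

    def test_too_few_positive_scores_raise(self):
        from dcss.leverage import LeverageProfile

        tau = np.array([0.6, 0.4, 0.0, 0.0])
        prof = LeverageProfile(scores=tau, k=1, order=np.arange(4))
        with pytest.raises(ValueError):
            fit_power_law(prof, 4)


class TestSizeFormulas:
    @pytest.mark.parametrize(
        "k,eps,a,expected",
        [(2, 0.2, 2.0, 20), (5, 0.1, 2.0, 100)],
    )
    def test_predicted_size_closed_form(self, k, eps, a, expected):
        n, raw = predicted_dcss_size(k, eps, a)
        assert n == expected
        assert np.isclose(raw, expected)

    def test_steep_decay_limit_is_k(self):
        n, _ = predicted_dcss_size(3, 0.1, a=50.0)
        assert n == 3

    def test_invalid_exponent_raises(self):
        with pytest.raises(ValueError):
            predicted_dcss_size(2, 0.2, 1.0)

    def test_sampling_bound_value(self):
        t = random_sampling_size(k=2, epsilon=0.2, delta=0.1, m=0)
        assert np.isclose(t, 50 * 2 * (1 + 0.2 / 3) * math.log(320), rtol=1e-12)
        assert np.isclose(t, 615.2875728846689)

    def test_sampling_bound_monotone_decreasing_in_delta(self):
        ts = [random_sampling_size(2, 0.2, d) for d in (0.05, 0.1, 0.5, 0.99)]
        assert all(a > b for a, b in zip(ts, ts[1:]))

    def test_deterministic_walk_beats_sampling(self):
        assert dcss_beats_sampling(2, 0.2, a=2.0, delta=0.1)

    def test_selection_size_matches_prediction_on_exact_profile(self):
        """On an exact i^-2 profile the realized selection size stays
        within one column of the closed form (ceiling effects)."""
        prof, _ = power_law_profile(d=2000, a=2.0, k=2)
        sel = dcss_select(prof, 0.2)
        predicted, _ = predicted_dcss_size(2, 0.2, 2.0)
        assert sel.size <= predicted + 1


class TestLikelihood:
    def test_full_data_exponent_term(self, toy_run):
        _, F, prof, _ = toy_run
        ll = log_likelihood(F, prof)
        expected = (
            -0.5 * 2 * 3 * math.log(2 * math.pi)
            - 3 * float(np.log(F.sigma).sum())
            - 0.5 * 2.0  # sum tau = k = 2
        )
        assert np.isclose(ll, expected)

    def test_selected_columns_exponent_term(self, toy_run):
        _, F, prof, sel = toy_run
        ll = log_likelihood(F, prof, sel.theta)
        # kept mass 1.8 -> exponent term -0.9
        base = -0.5 * 2 * 2 * math.log(2 * math.pi) - 2 * float(
            np.log(F.sigma).sum()
        )
        assert np.isclose(ll - base, -0.9)

    def test_identity_residual_zero_on_toy(self, toy_run):
        _, F, prof, sel = toy_run
        rep = likelihood_identity_check(F, prof, sel)
        assert abs(rep.identity_residual) < 1e-9
        assert np.isclose(rep.realized_error, 0.2)

    def test_full_selection_identity_reduces_to_equality(self, toy):
        F = rank_k_factorize(toy, 2)
        prof = leverage_scores(F)
        sel = dcss_select(prof, 1e-12)
        rep = likelihood_identity_check(F, prof, sel)
        assert sel.size == 3
        assert np.isclose(rep.log_L_A, rep.log_L_C)
        assert rep.realized_error < 1e-10

    def test_greedy_selection_maximizes_kept_mass(self, rng):
        """Exhaustive check on small matrices: no equal-size subset keeps
        more leverage mass than the greedy prefix."""
        for _ in range(5):
            A = random_count_matrix(rng, 6, int(rng.integers(8, 13)))
            k = int(rng.integers(1, 4))
            prof = leverage_scores(rank_k_factorize(A, k))
            sel = dcss_select(prof, 0.25)
            kept = prof.scores[sel.theta].sum()
            d = prof.d
            for subset in itertools.combinations(range(d), sel.size):
                assert prof.scores[list(subset)].sum() <= kept + 1e-10


class TestEigenvalueScan:
    def test_toy_trace_identity(self, toy):
        out = eigenvalue_scan(toy, 2)
        assert np.isclose(out["eigenvalues"].sum(), 2825.0)
        assert out["n_positive"] == 2

    def test_rank_one_matrix_hints_one(self):
        vals = np.outer([1.0, 2.0, 3.0], [4.0, 5.0, 6.0, 7.0])
        out = eigenvalue_scan(ExpressionMatrix(vals), 3)
        assert out["n_positive"] == 1
        assert out["elbow_hint"] == 1

    def test_planted_rank_three_gap_hints_three(self, rng):
        # orthogonal construction with eigengap >= 10x after rank 3
        n, d = 20, 40
        U, _ = np.linalg.qr(rng.normal(size=(n, 6)))
        V, _ = np.linalg.qr(rng.normal(size=(d, 6)))
        s = np.array([100.0, 80.0, 60.0, 3.0, 2.0, 1.0])
        A = ExpressionMatrix((U * s) @ V.T, require_nonnegative=False)
        out = eigenvalue_scan(A, 6)
        assert out["elbow_hint"] == 3
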