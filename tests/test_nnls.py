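"""Lawson–Hanson NNLS solver and per-transcript deconvolution fit."""

import numpy as np
import pytest
import scipy.optimize
from hypothesis import given, settings
from hypothesis import strategies as st

from circdeconv import (
    ExpressionMatrix,
    NNLSError,
    ProportionMatrix,
    SimulationConfig,
    ValidationError,
    fit_cell_type_expression,
    nnls_solve,
    simulate,
)

from conftest import brute_force_nnls


class TestSolver:
    def test_unconstrained_mean_when_constraint_slack(self):
        sol = nnls_solve([[1.0], [1.0]], [1.0, 2.0])
        assert sol.beta == pytest.approx([1.5])
        assert sol.active_set == frozenset()

    def test_constraint_binds_at_zero_for_negative_response(self):
        sol = nnls_solve([[1.0], [1.0]], [-1.0, -1.0])
        assert sol.beta[0] == 0.0  # exact zero
        assert sol.residual_norm == pytest.approx(np.sqrt(2.0))
        assert sol.active_set == frozenset({0})

    def test_matches_support_enumeration_oracle(self):
        """Objective equals the brute-force optimum on 200 random instances."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(2, 9))
            k = int(rng.integers(1, 5))
            X = rng.standard_normal((n, k))
            y = rng.standard_normal(n)
            sol = nnls_solve(X, y)
            _, oracle_obj = brute_force_nnls(X, y)
            assert sol.residual_norm == pytest.approx(oracle_obj, abs=1e-8)
            assert np.all(sol.beta >= 0)

    def test_matches_reference_library_solver(self):
        """Cross-check the coefficients themselves against scipy's NNLS."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            X = rng.standard_normal((10, 4))
            y = rng.standard_normal(10)
            ours = nnls_solve(X, y)
            ref_beta, ref_res = scipy.optimize.nnls(X, y)
            assert ours.residual_norm == pytest.approx(ref_res, abs=1e-8)
            assert ours.beta == pytest.approx(ref_beta, abs=1e-7)

    def test_kkt_conditions_hold(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            X = rng.standard_normal((8, 4))
            y = rng.standard_normal(8)
            sol = nnls_solve(X, y)
            grad = X.T @ (X @ sol.beta - y)  # gradient of ½‖Xβ−y‖²
            scale = max(1.0, np.abs(X.T @ y).max())
            # positive coordinates: stationarity; zero coordinates: grad ≥ 0
            assert np.all(np.abs(grad[sol.beta > 0]) <= 1e-8 * scale)
            assert np.all(grad[sol.beta == 0] >= -1e-8 * scale)

    def test_reduces_to_ols_when_unconstrained_solution_feasible(self):
        rng = np.random.default_rng(11)
        X = rng.uniform(0.1, 1.0, size=(12, 3))
        beta_true = np.array([1.0, 2.0, 0.5])
        y = X @ beta_true
        ols = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.all(ols >= 0)
        sol = nnls_solve(X, y)
        assert sol.beta == pytest.approx(ols, abs=1e-8)

    @settings(derandomize=True, max_examples=50)
    @given(
        c=st.floats(min_value=1e-3, max_value=1e3),
        seed=st.integers(min_value=0, max_value=2**16),
    )
    def test_scaling_equivariance(self, c, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((6, 3))
        y = rng.standard_normal(6)
        base = nnls_solve(X, y).beta
        scaled = nnls_solve(X, c * y).beta
        assert scaled == pytest.approx(c * base, rel=1e-8, abs=1e-10)

    @pytest.mark.parametrize(
        "X, y",
        [([[np.nan], [1.0]], [1.0, 2.0]), ([[1.0], [1.0]], [np.inf, 0.0])],
    )
    def test_non_finite_input_rejected(self, X, y):
        with pytest.raises(NNLSError, match="non-finite"):
            nnls_solve(X, y)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(NNLSError):
            nnls_solve([[1.0, 2.0]], [1.0, 2.0])


class TestFit:
    def test_noiseless_mixture_recovers_coefficients_exactly(self):
        truth = simulate(
            SimulationConfig(n_samples=12, n_linear=40, n_circ=0,
                             noise_model="none", seed=5)
        )
        fitted = fit_cell_type_expression(truth.bulk_noiseless, truth.true_proportions)
        err = np.abs(fitted.coefficients - truth.true_coefficients.coefficients).max()
        assert err <= 1e-8

    def test_all_zero_transcript_gives_all_zero_row(self, two_type_proportions):
        bulk = ExpressionMatrix(
            ["z", "t"], ["s1", "s2"], [[0.0, 0.0], [1.0, 2.0]], "TPM"
        )
        fitted = fit_cell_type_expression(bulk, two_type_proportions)
        assert np.all(fitted.coefficients[0] == 0.0)
        assert fitted.coefficients[1].sum() > 0

    def test_single_cell_type_fit_is_clipped_mean(self):
        # k=1 with all-ones design: the NNLS solution is max(mean(y), 0)
        props = ProportionMatrix(["only"], ["s1", "s2", "s3"], [[1.0, 1.0, 1.0]])
        bulk = ExpressionMatrix(
            ["g1"], ["s1", "s2", "s3"], [[1.0, 2.0, 6.0]], "TPM"
        )
        fitted = fit_cell_type_expression(bulk, props)
        assert fitted.coefficients[0, 0] == pytest.approx(3.0)

    def test_sample_mismatch_rejected(self, two_type_proportions):
        bulk = ExpressionMatrix(["g"], ["s1", "sX"], [[1.0, 2.0]], "TPM")
        with pytest.raises(ValidationError, match="sample ids"):
            fit_cell_type_expression(bulk, two_type_proportions)

    def test_groups_fit_independently(self):
        truth = simulate(
            SimulationConfig(n_samples=16, n_linear=10, n_circ=0,
                             noise_model="none", seed=9)
        )
        samples = truth.bulk_noiseless.sample_ids
        groups = {"g1": samples[:8], "g2": samples[8:]}
        fits = fit_cell_type_expression(
            truth.bulk_noiseless, truth.true_proportions, groups=groups
        )
        assert set(fits) == {"g1", "g2"}
        for f in fits.values():  # noiseless → both groups recover the truth
            assert np.abs(
                f.coefficients - truth.true_coefficients.coefficients
            ).max() <= 1e-6
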