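"""Unit tests for the coordinate updates and the ELBO."""

import numpy as np
import pytest

from covtraj import CovariateMatrix, ExpressionMatrix, Hyperparameters, initialize_state
from covtraj import cavi
from covtraj.params import FitOptions

from oracles import log_marginal_two_sample_fa, numeric_gamma_optimum, numeric_normal_optimum


class TestExpectedLoading:
    def test_no_perturbation_returns_lambda_rows(self, problem_factory):
        expr, cov, hyper, state = problem_factory(0, 6, 3, 1)
        state.beta_mean[:] = 0.0
        out = cavi.expected_loading(state, cov)
        np.testing.assert_allclose(out, np.tile(state.lambda_mean, (6, 1)))

    def test_binary_covariate_offsets_loading_by_group(self, problem_factory):
        expr, cov, hyper, state = problem_factory(1, 8, 2, 1)
        state.lambda_mean[:] = 1.0
        state.beta_mean[:] = 0.5
        out = cavi.expected_loading(state, cov)
        expected = np.where(cov.values[:, [0]] > 0, 1.5, 0.5)
        np.testing.assert_allclose(out, np.broadcast_to(expected, out.shape))

    def test_matches_entrywise_double_loop(self, problem_factory):
        expr, cov, hyper, state = problem_factory(2, 5, 3, 2)
        out = cavi.expected_loading(state, cov)
        for n in range(5):
            for g in range(3):
                manual = state.lambda_mean[g] + sum(
                    state.beta_mean[p, g] * cov.values[n, p] for p in range(2)
                )
                assert out[n, g] == pytest.approx(manual, rel=1e-12)


def _zeroed_state(state):
    s = state.copy()
    s.mu_mean[:] = 0.0
    s.alpha_mean[:] = 0.0
    return s


class TestUpdateZ:
    def test_zero_data_gives_zero_posterior_mean(self, problem_factory):
        expr, cov, hyper, state = problem_factory(0, 6, 3, 1)
        zero_expr = ExpressionMatrix(np.zeros_like(expr.values), centred=True)
        new = cavi.update_z(_zeroed_state(state), zero_expr, cov, hyper)
        np.testing.assert_allclose(new.z_mean, 0.0, atol=1e-14)

    def test_negating_data_flips_mean_keeps_variance(self, problem_factory):
        expr, cov, hyper, state = problem_factory(1, 7, 4, 1)
        state = _zeroed_state(state)
        neg_expr = ExpressionMatrix(-expr.values, centred=expr.centred)
        a = cavi.update_z(state, expr, cov, hyper)
        b = cavi.update_z(state, neg_expr, cov, hyper)
        np.testing.assert_allclose(a.z_mean, -b.z_mean, rtol=1e-12)
        np.testing.assert_allclose(a.z_var, b.z_var, rtol=1e-12)

    def test_only_z_factors_touched(self, problem_factory):
        expr, cov, hyper, state = problem_factory(2, 5, 2, 1)
        new = cavi.update_z(state, expr, cov, hyper)
        np.testing.assert_array_equal(new.lambda_mean, state.lambda_mean)
        np.testing.assert_array_equal(new.tau_rate, state.tau_rate)


class TestOracleEquivalence:
    """Analytic conjugate updates equal numeric ELBO coordinate maximisation."""

    def test_z_update_matches_numeric_maximum(self, problem_factory):
        expr, cov, hyper, state = problem_factory(10, 3, 2, 1)
        new = cavi.update_z(state, expr, cov, hyper)
        for n in range(3):
            m, v = numeric_normal_optimum(
                state, expr, cov, hyper,
                lambda s: s.z_mean, lambda s: s.z_var,
                lambda s, i, mm, vv: (s.z_mean.__setitem__(i, mm), s.z_var.__setitem__(i, vv)),
                n,
            )
            assert new.z_mean[n] == pytest.approx(m, rel=1e-4, abs=1e-6)
            assert new.z_var[n] == pytest.approx(v, rel=1e-4)

    def test_lambda_update_matches_simple_regression_posterior(self):
        # z at (near) point mass, P=0, one gene: the loading posterior is the
        # textbook conjugate simple-regression posterior with E[tau] plugged in
        rng = np.random.default_rng(4)
        n = 20
        z = rng.standard_normal(n)
        y = (1.3 * z + 0.1 * rng.standard_normal(n))[:, None]
        y -= y.mean()
        expr = ExpressionMatrix(y, centred=True)
        cov = CovariateMatrix.empty(n)
        hyper = Hyperparameters()
        state = initialize_state(expr, cov, hyper, init="supplied", z_init=z, z_init_var=1e-14)
        state.mu_mean[:] = 0.0
        new = cavi._update_lambda_beta(state, expr, cov, hyper)
        etau = state.tau_shape[0] / state.tau_rate[0]
        prec = hyper.tau_lambda + etau * np.sum(z**2)
        np.testing.assert_allclose(new.lambda_mean[0], etau * np.sum(z * y[:, 0]) / prec, rtol=1e-8)
        np.testing.assert_allclose(new.lambda_var[0], 1.0 / prec, rtol=1e-8)

    def test_gene_regression_updates_match_numeric_maxima(self, problem_factory):
        expr, cov, hyper, state = problem_factory(11, 4, 1, 1)

        current = cavi._update_mu_only(state, expr, cov, hyper)
        m, v = numeric_normal_optimum(
            state, expr, cov, hyper, lambda s: s.mu_mean, lambda s: s.mu_var,
            lambda s, i, mm, vv: (s.mu_mean.__setitem__(i, mm), s.mu_var.__setitem__(i, vv)), 0)
        assert current.mu_mean[0] == pytest.approx(m, rel=1e-4, abs=1e-6)

        after_alpha = cavi._update_alpha_only(current, expr, cov, hyper)
        m, v = numeric_normal_optimum(
            current, expr, cov, hyper, lambda s: s.alpha_mean, lambda s: s.alpha_var,
            lambda s, i, mm, vv: (s.alpha_mean.__setitem__(i, mm), s.alpha_var.__setitem__(i, vv)),
            (0, 0))
        assert after_alpha.alpha_mean[0, 0] == pytest.approx(m, rel=1e-4, abs=1e-6)

        after_lb = cavi._update_lambda_beta(after_alpha, expr, cov, hyper)
        m, v = numeric_normal_optimum(
            after_alpha, expr, cov, hyper, lambda s: s.lambda_mean, lambda s: s.lambda_var,
            lambda s, i, mm, vv: (s.lambda_mean.__setitem__(i, mm), s.lambda_var.__setitem__(i, vv)),
            0)
        assert after_lb.lambda_mean[0] == pytest.approx(m, rel=1e-4, abs=1e-6)

        # beta optimum taken at the post-lambda state (sequential within gene)
        mid = after_alpha.copy()
        mid.lambda_mean = after_lb.lambda_mean.copy()
        mid.lambda_var = after_lb.lambda_var.copy()
        m, v = numeric_normal_optimum(
            mid, expr, cov, hyper, lambda s: s.beta_mean, lambda s: s.beta_var,
            lambda s, i, mm, vv: (s.beta_mean.__setitem__(i, mm), s.beta_var.__setitem__(i, vv)),
            (0, 0))
        assert after_lb.beta_mean[0, 0] == pytest.approx(m, rel=1e-4, abs=1e-6)
        assert after_lb.beta_var[0, 0] == pytest.approx(v, rel=1e-4)

    def test_precision_updates_match_numeric_maxima(self, problem_factory):
        expr, cov, hyper, state = problem_factory(12, 3, 1, 1)
        new = cavi.update_precisions(state, expr, cov, hyper)
        shape, rate = numeric_gamma_optimum(
            state, expr, cov, hyper, lambda s: s.tau_shape, lambda s: s.tau_rate,
            lambda s, i, a, b: (s.tau_shape.__setitem__(i, a), s.tau_rate.__setitem__(i, b)), 0)
        assert new.tau_shape[0] == pytest.approx(shape, rel=1e-3)
        assert new.tau_rate[0] == pytest.approx(rate, rel=1e-3)
        shape, rate = numeric_gamma_optimum(
            state, expr, cov, hyper, lambda s: s.chi_shape, lambda s: s.chi_rate,
            lambda s, i, a, b: (s.chi_shape.__setitem__(i, a), s.chi_rate.__setitem__(i, b)),
            (0, 0))
        assert new.chi_shape[0, 0] == pytest.approx(shape, rel=1e-3)
        assert new.chi_rate[0, 0] == pytest.approx(rate, rel=1e-3)


class TestPrecisionUpdates:
    def test_tau_shape_is_data_independent(self, problem_factory):
        for seed, n in [(0, 5), (1, 17)]:
            expr, cov, hyper, state = problem_factory(seed, n, 2, 1)
            new = cavi.update_precisions(state, expr, cov, hyper)
            np.testing.assert_allclose(new.tau_shape, hyper.a + n / 2.0)

    def test_chi_mean_limit_for_vanishing_beta(self, problem_factory):
        expr, cov, hyper, state = problem_factory(2, 6, 2, 1)
        state.beta_mean[:] = 0.0
        state.beta_var[:] = 1e-300
        new = cavi.update_chi(state, expr, cov, hyper)
        echi = new.chi_shape / new.chi_rate
        np.testing.assert_allclose(echi, (hyper.a_beta + 0.5) / hyper.b_beta, rtol=1e-10)


class TestElbo:
    def test_single_block_updates_never_decrease_elbo(self, problem_factory):
        blocks = ("z", "mu", "alpha", "lambda_beta", "tau", "chi")
        for seed in range(6):
            expr, cov, hyper, state = problem_factory(seed, 8, 4, min(seed % 3, 2))
            e = cavi.compute_elbo(state, expr, cov, hyper)
            for block in blocks:
                state = cavi._apply_block(block, state, expr, cov, hyper)
                e2 = cavi.compute_elbo(state, expr, cov, hyper)
                assert e2 >= e - 1e-8 * abs(e), f"{block} decreased ELBO (seed {seed})"
                e = e2

    def test_reflection_symmetry_of_elbo(self, problem_factory):
        expr, cov, hyper, state = problem_factory(3, 6, 3, 1)
        flipped = state.copy()
        flipped.z_mean = -flipped.z_mean
        flipped.lambda_mean = -flipped.lambda_mean
        flipped.beta_mean = -flipped.beta_mean
        a = cavi.compute_elbo(state, expr, cov, hyper)
        b = cavi.compute_elbo(flipped, expr, cov, hyper)
        assert a == pytest.approx(b, rel=1e-12)

    def test_converged_elbo_is_below_exact_log_marginal(self):
        # smallest non-trivial case: two samples, one gene, no covariates
        y = np.array([[0.8], [-0.8]])
        hyper = Hyperparameters(tau_mu=1.0, tau_lambda=1.0, tau_q=1.0, a=2.0, b=2.0)
        expr = ExpressionMatrix(y, centred=True)
        cov = CovariateMatrix.empty(2)
        state = initialize_state(expr, cov, hyper, init="supplied", z_init=np.array([1.0, -1.0]))
        res = cavi.fit(expr, cov, hyper, state, FitOptions(max_iterations=500, elbo_rel_tol=1e-10))
        log_evidence = log_marginal_two_sample_fa(y[:, 0], hyper)
        assert res.final_elbo <= log_evidence + 1e-6
        assert res.final_elbo >= log_evidence - 5.0  # mean-field gap stays modest here

    def test_unit_rescaling_shifts_elbo_by_constant(self, problem_factory):
        """Scaling Y with consistently rescaled priors and state is an exact
        reparameterisation: per-sweep ELBO increments are unchanged."""
        expr, cov, hyper, state = problem_factory(7, 10, 4, 1)
        c = 3.7
        expr2 = ExpressionMatrix(expr.values * c, centred=expr.centred)
        hyper2 = Hyperparameters(
            tau_alpha=hyper.tau_alpha / c**2, tau_lambda=hyper.tau_lambda / c**2,
            tau_mu=hyper.tau_mu / c**2, tau_q=hyper.tau_q,
            a=hyper.a, b=hyper.b * c**2, a_beta=hyper.a_beta, b_beta=hyper.b_beta * c**2,
            k=hyper.k,
        )
        state2 = state.copy()
        for name in ("mu_mean", "lambda_mean", "alpha_mean", "beta_mean"):
            setattr(state2, name, getattr(state2, name) * c)
        for name in ("mu_var", "lambda_var", "alpha_var", "beta_var"):
            setattr(state2, name, getattr(state2, name) * c**2)
        state2.tau_rate = state2.tau_rate * c**2
        state2.chi_rate = state2.chi_rate * c**2

        opts = FitOptions(max_iterations=5, elbo_rel_tol=1e-300)
        with pytest.warns(cavi.ConvergenceWarning):
            r1 = cavi.fit(expr, cov, hyper, state, opts)
        with pytest.warns(cavi.ConvergenceWarning):
            r2 = cavi.fit(expr2, cov, hyper2, state2, opts)
        d1 = np.diff(r1.state.elbo_trace)
        d2 = np.diff(r2.state.elbo_trace)
        np.testing.assert_allclose(d1, d2, rtol=1e-6, atol=1e-8)

    def test_nonfinite_state_reported(self, problem_factory):
        from covtraj.exceptions import NumericError

        expr, cov, hyper, state = problem_factory(9, 5, 2, 1)
        state.mu_mean[0] = np.inf
        with pytest.raises(NumericError):
            cavi.compute_elbo(state, expr, cov, hyper)
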