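"""End-to-end fitting behaviour: recovery, determinism, nesting, shrinkage."""

import numpy as np
import pytest

from covtraj import (
    CovariateMatrix,
    CovariateTrajectoryModel,
    ExpressionMatrix,
    Hyperparameters,
    simulate_linear,
)
from covtraj.params import FitOptions


def test_fit_is_deterministic():
    expr, cov, _ = simulate_linear(n_samples=60, n_genes=20, seed=3)
    model = CovariateTrajectoryModel(expr, cov)
    a = model.fit(seed=7)
    b = model.fit(seed=7)
    np.testing.assert_array_equal(a.pseudotime, b.pseudotime)
    np.testing.assert_array_equal(a.state.beta_mean, b.state.beta_mean)
    assert a.final_elbo == b.final_elbo


def test_pseudotime_recovery_from_own_generative_process():
    expr, cov, truth = simulate_linear(n_samples=150, n_genes=60, seed=11)
    res = CovariateTrajectoryModel(expr, cov).fit(seed=11)
    r = abs(np.corrcoef(res.pseudotime, truth.z_true)[0, 1])
    assert r > 0.9
    assert res.converged


def test_elbo_trace_is_monotone():
    expr, cov, _ = simulate_linear(n_samples=80, n_genes=30, seed=5)
    res = CovariateTrajectoryModel(expr, cov).fit(seed=5)
    trace = np.asarray(res.elbo_trace)
    assert len(trace) >= 2
    assert np.all(np.diff(trace) >= -1e-8 * np.abs(trace[:-1]))


def test_sign_convention_aligns_with_initialisation():
    from covtraj.model import initialize_state

    expr, cov, _ = simulate_linear(n_samples=80, n_genes=30, seed=9)
    model = CovariateTrajectoryModel(expr, cov)
    res = model.fit(seed=9)
    init = initialize_state(model.expr, model.cov, model.hyper)
    assert float(res.pseudotime @ init.z_mean) >= 0.0


def test_pure_noise_gene_shrinks_to_zero():
    # a null gene (lambda = beta = 0) embedded in an informative panel that
    # pins down the trajectory; its fitted effects must stay within
    # posterior uncertainty of zero
    expr, cov, truth = simulate_linear(n_samples=150, n_genes=40, seed=21)
    rng = np.random.default_rng(22)
    y = np.column_stack([expr.values, rng.standard_normal(150)])
    res = CovariateTrajectoryModel(y, cov.values).fit(seed=0)
    st = res.state
    assert abs(st.lambda_mean[-1]) < 3.0 * np.sqrt(st.lambda_var[-1])
    assert abs(st.beta_mean[0, -1]) < 3.0 * np.sqrt(st.beta_var[0, -1])


def test_nonconvergence_sets_flag_and_warns():
    from covtraj.cavi import ConvergenceWarning

    expr, cov, _ = simulate_linear(n_samples=60, n_genes=20, seed=1)
    model = CovariateTrajectoryModel(expr, cov)
    with pytest.warns(ConvergenceWarning):
        res = model.fit(options=FitOptions(max_iterations=1, elbo_rel_tol=1e-14), seed=1)
    assert not res.converged
    assert res.n_iterations == 1


class TestNesting:
    """Standard models are special cases of the full trajectory model."""

    @staticmethod
    def _standalone_fa_cavi(Y, hyper, z0, n_sweeps=3000):
        """Independent minimal one-factor Bayesian FA coordinate ascent.

        Written from the conjugate formulas directly (no shared code with
        the library) for the P = 0 comparison.
        """
        n, g = Y.shape
        mz, sz = z0.copy(), np.ones(n)
        mm, sm = np.zeros(g), np.ones(g)
        ml = Y.T @ z0 / (z0 @ z0)
        sl = np.ones(g)
        ts, tr = np.full(g, hyper.a), np.full(g, hyper.b)
        for _ in range(n_sweeps):
            et = ts / tr
            pz = hyper.tau_q + et @ (ml**2 + sl)
            mz = ((Y - mm) @ (et * ml)) / pz
            sz = 1.0 / pz
            et = ts / tr
            pm = hyper.tau_mu + n * et
            mm = et * (Y - np.outer(mz, ml)).sum(0) / pm
            sm = 1.0 / pm
            ez2 = mz**2 + sz
            pl = hyper.tau_lambda + et * ez2.sum()
            ml = et * (mz @ (Y - mm)) / pl
            sl = 1.0 / pl
            ts = np.full(g, hyper.a + n / 2.0)
            res2 = (
                (Y - mm - np.outer(mz, ml)) ** 2
                + sm
                + np.outer(ez2, ml**2 + sl)
                - np.outer(mz**2, ml**2)
            )
            tr = hyper.b + 0.5 * res2.sum(0)
        return mz, sz, mm, ml, ts, tr

    def test_p_zero_fit_equals_one_factor_factor_analysis(self):
        rng = np.random.default_rng(2)
        n, g = 60, 15
        z = rng.standard_normal(n)
        lam = rng.standard_normal(g)
        Y = np.outer(z, lam) + 0.5 * rng.standard_normal((n, g))
        Y -= Y.mean(0)
        model = CovariateTrajectoryModel(Y)
        res = model.fit(options=FitOptions(max_iterations=3000, elbo_rel_tol=1e-14), seed=0)

        from covtraj.model import initialize_state

        z0 = initialize_state(model.expr, model.cov, model.hyper).z_mean
        mz, sz, mm, ml, ts, tr = self._standalone_fa_cavi(model.expr.values, model.hyper, z0)
        if mz @ res.pseudotime < 0:
            mz, ml = -mz, -ml
        np.testing.assert_allclose(res.pseudotime, mz, rtol=1e-5, atol=1e-7)
        np.testing.assert_allclose(res.state.lambda_mean, ml, rtol=1e-5, atol=1e-7)
        np.testing.assert_allclose(res.state.tau_rate, tr, rtol=1e-5)

    def test_clamped_pseudotime_reduces_to_bayesian_regression(self):
        """z fixed at 0: gene-wise alpha posteriors equal the closed-form
        conjugate linear-regression posterior, computed independently."""
        rng = np.random.default_rng(7)
        n, g = 80, 6
        x = rng.choice((-1.0, 1.0), n)
        alpha_true = rng.standard_normal(g)
        Y = np.outer(x, alpha_true) + rng.standard_normal((n, g))
        model = CovariateTrajectoryModel(Y, x[:, None])
        res = model.fit(
            options=FitOptions(update_order=("mu", "alpha", "tau"),
                               max_iterations=500, elbo_rel_tol=1e-13),
            init="supplied", z_init=np.zeros(n), z_init_var=1e-12, seed=0,
        )
        h = model.hyper
        Yc = model.expr.values
        # independent fixed-point iteration of the conjugate regression system
        mm, ma = np.zeros(g), np.zeros(g)
        ts, tr = np.full(g, h.a), np.full(g, h.b)
        sm = sa = np.ones(g)
        for _ in range(500):
            et = ts / tr
            pm = h.tau_mu + n * et
            mm = et * (Yc - np.outer(x, ma)).sum(0) / pm
            sm = 1.0 / pm
            pa = h.tau_alpha + et * n
            ma = et * (x @ (Yc - mm)) / pa
            sa = 1.0 / pa
            ts = np.full(g, h.a + n / 2.0)
            tr = h.b + 0.5 * ((Yc - mm - np.outer(x, ma)) ** 2 + sm + sa).sum(0)
        np.testing.assert_allclose(res.state.alpha_mean[0], ma, rtol=0, atol=1e-6)
        np.testing.assert_allclose(res.state.alpha_var[0], sa, rtol=0, atol=1e-6)
        # the clamped pseudotime never moved
        np.testing.assert_allclose(res.pseudotime, 0.0, atol=1e-12)
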