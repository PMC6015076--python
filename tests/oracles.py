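"""Independent oracles used by the test suite.

These deliberately avoid the library's analytic formulas: coordinate optima
are found by direct numerical maximisation of the ELBO, rank correlation
and AUC by O(n^2) pair counting, and marginal likelihoods by quadrature.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

from covtraj import cavi


def numeric_normal_optimum(state, expr, cov, hyper, get_mean, get_var, set_entry, index):
    """Maximise the ELBO over one Normal factor's (mean, log variance)."""

    def neg(v):
        s = state.copy()
        set_entry(s, index, v[0], np.exp(v[1]))
        return -cavi.compute_elbo(s, expr, cov, hyper)

    x0 = [get_mean(state)[index], np.log(get_var(state)[index])]
    res = minimize(neg, x0, method="Nelder-Mead",
                   options=dict(xatol=1e-10, fatol=1e-13, maxiter=20000))
    assert res.success or res.fun <= neg(x0)
    return res.x[0], float(np.exp(res.x[1]))


def numeric_gamma_optimum(state, expr, cov, hyper, get_shape, get_rate, set_entry, index):
    """Maximise the ELBO over one Gamma factor's (log shape, log rate)."""

    def neg(v):
        s = state.copy()
        set_entry(s, index, np.exp(v[0]), np.exp(v[1]))
        return -cavi.compute_elbo(s, expr, cov, hyper)

    x0 = [np.log(get_shape(state)[index]), np.log(get_rate(state)[index])]
    res = minimize(neg, x0, method="Nelder-Mead",
                   options=dict(xatol=1e-11, fatol=1e-13, maxiter=20000))
    return float(np.exp(res.x[0])), float(np.exp(res.x[1]))


def brute_force_kendall(a, b) -> float:
    """Tau-b by explicit pair counting with tie corrections."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n = len(a)
    conc = disc = ties_a = ties_b = 0
    for i in range(n):
        for j in range(i + 1, n):
            da, db = a[i] - a[j], b[i] - b[j]
            if da == 0 and db == 0:
                ties_a += 1
                ties_b += 1
            elif da == 0:
                ties_a += 1
            elif db == 0:
                ties_b += 1
            elif da * db > 0:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) / 2
    denom = np.sqrt((n0 - ties_a) * (n0 - ties_b))
    return (conc - disc) / denom


def brute_force_auc(scores, labels) -> float:
    """Mann-Whitney probability by explicit positive x negative pair counting."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))


def log_marginal_two_sample_fa(y, hyper) -> float:
    """Exact log p(y1, y2) for the G=1, P=0 model by 2-D quadrature.

    With mu, z marginalised analytically given (lambda, tau), the two
    observations are jointly Gaussian with covariance
    (1/tau_mu) J + (lambda^2/tau_q + 1/tau) I; the remaining integral over
    the lambda prior and the Gamma prior on tau is done numerically.
    """
    from scipy.integrate import dblquad
    from scipy.stats import gamma as gamma_dist, norm, multivariate_normal

    y = np.asarray(y, float).ravel()
    assert y.shape == (2,)
    assert hyper.q is None

    def integrand(lam, tau):
        diag = lam**2 / hyper.tau_q + 1.0 / tau
        cov = np.full((2, 2), 1.0 / hyper.tau_mu) + np.eye(2) * diag
        return (
            multivariate_normal.pdf(y, mean=np.zeros(2), cov=cov)
            * norm.pdf(lam, scale=1.0 / np.sqrt(hyper.tau_lambda))
            * gamma_dist.pdf(tau, a=hyper.a, scale=1.0 / hyper.b)
        )

    lam_sd = 1.0 / np.sqrt(hyper.tau_lambda)
    val, _ = dblquad(
        integrand,
        1e-8, gamma_dist.ppf(1.0 - 1e-10, a=hyper.a, scale=1.0 / hyper.b),
        lambda _t: -8.0 * lam_sd, lambda _t: 8.0 * lam_sd,
        epsabs=1e-12, epsrel=1e-10,
    )
    return float(np.log(val))
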