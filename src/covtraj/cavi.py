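"""Coordinate-ascent mean-field variational inference.

Every update below is the exact conjugate optimum of the evidence lower
bound (ELBO) for one factor given the current expectations of all others,
so a full sweep can never decrease the ELBO.  Expectations of products use
full mean-field second moments — no delta approximations — which is what
makes the monotonicity exact rather than approximate.

Notation used throughout (arrays as in :class:`~covtraj.params.VariationalState`):

    c_ng  = lambda_g + sum_p beta_pg x_np      (the perturbed loading)
    A_ng  = sum_p alpha_pg x_np                (static covariate offset)
    E[c_ng]   = lambda_mean_g + (X beta_mean)_ng
    Var[c_ng] = lambda_var_g + (X^2 beta_var)_ng
    E[tau_g]  = tau_shape_g / tau_rate_g,  E[log tau_g] = digamma(shape) - log(rate)

Factors for different samples (z_n) and different genes (mu_g, lambda_g,
tau_g, and each alpha_pg / beta_pg / chi_pg at fixed p) are conditionally
independent, so those updates are vectorised; alpha and beta updates loop
over covariates p sequentially because covariates of the same gene share a
residual.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, gammaln

from .containers import CovariateMatrix, ExpressionMatrix
from .exceptions import InternalStateError, NumericError
from .params import FitOptions, Hyperparameters, VariationalState

logger = logging.getLogger(__name__)

__all__ = [
    "expected_loading",
    "update_z",
    "update_gene_regression",
    "update_precisions",
    "compute_elbo",
    "fit",
    "FitResult",
    "ConvergenceWarning",
]

_LOG_2PI = np.log(2.0 * np.pi)


class ConvergenceWarning(UserWarning):
    """The coordinate-ascent loop stopped before meeting the ELBO tolerance."""


# ---------------------------------------------------------------------------
# expectation helpers

def _moments(state: VariationalState, X: np.ndarray):
    """Shared posterior expectations: E[tau], E[z], E[z^2], E[A], Var[A], E[c], E[c^2]."""
    Etau = state.tau_shape / state.tau_rate
    Ez = state.z_mean
    Ez2 = state.z_mean**2 + state.z_var
    EA = X @ state.alpha_mean
    VA = (X**2) @ state.alpha_var
    Ec = state.lambda_mean[None, :] + X @ state.beta_mean
    Vc = state.lambda_var[None, :] + (X**2) @ state.beta_var
    Ec2 = Ec**2 + Vc
    return Etau, Ez, Ez2, EA, VA, Ec, Ec2


def expected_loading(state: VariationalState, cov: CovariateMatrix) -> np.ndarray:
    """Posterior-mean perturbed loading E[lambda_ng] = E[lambda_g] + sum_p E[beta_pg] x_np.

    Returns an (N, G) matrix: the per-sample slope of expected expression
    with respect to pseudotime.
    """
    X = cov.values
    if X.shape[0] != state.n_samples or state.beta_mean.shape[0] != X.shape[1]:
        from .exceptions import DimensionError

        raise DimensionError(
            f"covariates {X.shape} do not match state with N={state.n_samples}, "
            f"P={state.n_covariates}"
        )
    return state.lambda_mean[None, :] + X @ state.beta_mean


def _expected_sq_residual(state: VariationalState, Y: np.ndarray, X: np.ndarray):
    """E[(y_ng - mu_g - A_ng - c_ng z_n)^2] under the full mean field.

    Independence of the factors gives
        E[r^2] = (E[r])^2 + Var[mu] + Var[A] + Var[c z],
    with Var[c z] = E[c^2]E[z^2] - (E[c]E[z])^2.
    """
    Etau, Ez, Ez2, EA, VA, Ec, Ec2 = _moments(state, X)
    R = Y - state.mu_mean[None, :] - EA - Ec * Ez[:, None]
    Eres2 = (
        R**2
        + state.mu_var[None, :]
        + VA
        + Ec2 * Ez2[:, None]
        - (Ec**2) * (Ez**2)[:, None]
    )
    return Eres2, (Etau, Ez, Ez2, EA, VA, Ec, Ec2)


# ---------------------------------------------------------------------------
# coordinate updates

def update_z(
    state: VariationalState,
    expr: ExpressionMatrix,
    cov: CovariateMatrix,
    hyper: Hyperparameters,
) -> VariationalState:
    """Conjugate update of every pseudotime factor q(z_n).

    Precision: tau_q + sum_g E[tau_g] E[c_ng^2]
    Mean:      (tau_q q_n + sum_g E[tau_g] E[c_ng](y_ng - E[mu_g] - E[A_ng])) / precision
    """
    Y, X = expr.values, cov.values
    Etau, _, _, EA, _, Ec, Ec2 = _moments(state, X)
    q = hyper.prior_means_for(state.n_samples)
    prec = hyper.tau_q + Ec2 @ Etau
    num = hyper.tau_q * q + (Ec * (Y - state.mu_mean[None, :] - EA)) @ Etau
    if np.any(prec <= 0):
        raise InternalStateError("non-positive precision in z update")
    new = state.copy()
    new.z_mean = num / prec
    new.z_var = 1.0 / prec
    return new


def update_gene_regression(
    state: VariationalState,
    expr: ExpressionMatrix,
    cov: CovariateMatrix,
    hyper: Hyperparameters,
) -> VariationalState:
    """Conjugate updates of the per-gene regression factors.

    Order within each gene: mu, then each alpha_pg (p ascending), then
    lambda, then each beta_pg (p ascending).  Genes are independent given z
    and tau, so each step is vectorised over g.
    """
    new = _update_mu_only(state, expr, cov, hyper)
    new = _update_alpha_only(new, expr, cov, hyper)
    new = _update_lambda_beta(new, expr, cov, hyper)
    new.validate()
    return new


def update_precisions(
    state: VariationalState,
    expr: ExpressionMatrix,
    cov: CovariateMatrix,
    hyper: Hyperparameters,
) -> VariationalState:
    """Conjugate Gamma updates of the noise (tau_g) and ARD (chi_pg) precisions.

    q(tau_g)  = Gamma(a + N/2,     b + 0.5 sum_n E[residual_ng^2])
    q(chi_pg) = Gamma(a_beta + 1/2, b_beta + 0.5 (beta_mean^2 + beta_var))
    """
    Y, X = expr.values, cov.values
    N = Y.shape[0]
    Eres2, _ = _expected_sq_residual(state, Y, X)
    new = state.copy()
    new.tau_shape = np.full(state.n_genes, hyper.a + N / 2.0)
    new.tau_rate = hyper.b + 0.5 * Eres2.sum(axis=0)
    new.chi_shape = np.full_like(state.chi_shape, hyper.a_beta + 0.5)
    new.chi_rate = hyper.b_beta + 0.5 * (state.beta_mean**2 + state.beta_var)
    if np.any(new.tau_rate <= 0) or (new.chi_rate.size and np.any(new.chi_rate <= 0)):
        raise InternalStateError("non-positive Gamma rate in precision update")
    return new


def update_tau(state, expr, cov, hyper) -> VariationalState:
    """Noise-precision update only (chi untouched)."""
    new = update_precisions(state, expr, cov, hyper)
    new.chi_shape = state.chi_shape.copy()
    new.chi_rate = state.chi_rate.copy()
    return new


def update_chi(state, expr, cov, hyper) -> VariationalState:
    """ARD-precision update only (tau untouched)."""
    new = state.copy()
    new.chi_shape = np.full_like(state.chi_shape, hyper.a_beta + 0.5)
    new.chi_rate = hyper.b_beta + 0.5 * (state.beta_mean**2 + state.beta_var)
    return new


# ---------------------------------------------------------------------------
# ELBO

def _gamma_entropy(shape: np.ndarray, rate: np.ndarray) -> np.ndarray:
    return shape - np.log(rate) + gammaln(shape) + (1.0 - shape) * digamma(shape)


def compute_elbo(
    state: VariationalState,
    expr: ExpressionMatrix,
    cov: CovariateMatrix,
    hyper: Hyperparameters,
) -> float:
    """Evidence lower bound E_q[log p(Y, theta | X)] - E_q[log q(theta)].

    Every expectation is closed-form under the mean-field factorisation;
    log-Gamma terms use ``scipy.special.gammaln`` for stability at the large
    shapes that arise when N is big.
    """
    Y, X = expr.values, cov.values
    N, G = Y.shape
    P = X.shape[1]
    Eres2, (Etau, Ez, Ez2, EA, VA, Ec, Ec2) = _expected_sq_residual(state, Y, X)
    Elogtau = digamma(state.tau_shape) - np.log(state.tau_rate)
    q = hyper.prior_means_for(N)

    # expected log-likelihood
    ll = 0.5 * N * (Elogtau - _LOG_2PI).sum() - 0.5 * float(Etau @ Eres2.sum(axis=0))

    # expected log-priors
    lp = 0.0
    lp += 0.5 * G * (np.log(hyper.tau_mu) - _LOG_2PI) - 0.5 * hyper.tau_mu * float(
        np.sum(state.mu_mean**2 + state.mu_var)
    )
    lp += 0.5 * G * (np.log(hyper.tau_lambda) - _LOG_2PI) - 0.5 * hyper.tau_lambda * float(
        np.sum(state.lambda_mean**2 + state.lambda_var)
    )
    lp += 0.5 * N * (np.log(hyper.tau_q) - _LOG_2PI) - 0.5 * hyper.tau_q * float(
        np.sum((state.z_mean - q) ** 2 + state.z_var)
    )
    lp += G * (hyper.a * np.log(hyper.b) - gammaln(hyper.a)) + float(
        np.sum((hyper.a - 1.0) * Elogtau - hyper.b * Etau)
    )
    if P:
        lp += 0.5 * P * G * (np.log(hyper.tau_alpha) - _LOG_2PI) - 0.5 * hyper.tau_alpha * float(
            np.sum(state.alpha_mean**2 + state.alpha_var)
        )
        Elogchi = digamma(state.chi_shape) - np.log(state.chi_rate)
        Echi = state.chi_shape / state.chi_rate
        lp += 0.5 * float(np.sum(Elogchi - _LOG_2PI)) - 0.5 * float(
            np.sum(Echi * (state.beta_mean**2 + state.beta_var))
        )
        lp += P * G * (hyper.a_beta * np.log(hyper.b_beta) - gammaln(hyper.a_beta)) + float(
            np.sum((hyper.a_beta - 1.0) * Elogchi - hyper.b_beta * Echi)
        )

    # entropies of the variational factors
    ent = 0.5 * float(
        np.sum(np.log(2.0 * np.pi * np.e * state.z_var))
        + np.sum(np.log(2.0 * np.pi * np.e * state.mu_var))
        + np.sum(np.log(2.0 * np.pi * np.e * state.lambda_var))
    )
    ent += float(np.sum(_gamma_entropy(state.tau_shape, state.tau_rate)))
    if P:
        ent += 0.5 * float(
            np.sum(np.log(2.0 * np.pi * np.e * state.alpha_var))
            + np.sum(np.log(2.0 * np.pi * np.e * state.beta_var))
        )
        ent += float(np.sum(_gamma_entropy(state.chi_shape, state.chi_rate)))

    elbo = ll + lp + ent
    if not np.isfinite(elbo):
        raise NumericError(
            f"non-finite ELBO (log-lik={ll!r}, log-prior={lp!r}, entropy={ent!r})"
        )
    return float(elbo)


# ---------------------------------------------------------------------------
# outer loop

def _apply_block(block, state, expr, cov, hyper):
    if block == "z":
        return update_z(state, expr, cov, hyper)
    if block == "mu":
        return _update_mu_only(state, expr, cov, hyper)
    if block == "alpha":
        return _update_alpha_only(state, expr, cov, hyper)
    if block == "lambda_beta":
        return _update_lambda_beta(state, expr, cov, hyper)
    if block == "tau":
        return update_tau(state, expr, cov, hyper)
    if block == "chi":
        return update_chi(state, expr, cov, hyper)
    raise AssertionError(f"unreachable block {block}")


def _update_mu_only(state, expr, cov, hyper):
    Y, X = expr.values, cov.values
    new = state.copy()
    N = Y.shape[0]
    Etau = new.tau_shape / new.tau_rate
    Ez = new.z_mean
    EA = X @ new.alpha_mean
    Ec = new.lambda_mean[None, :] + X @ new.beta_mean
    prec = hyper.tau_mu + N * Etau
    new.mu_mean = Etau * (Y - EA - Ec * Ez[:, None]).sum(axis=0) / prec
    new.mu_var = 1.0 / prec
    return new


def _update_alpha_only(state, expr, cov, hyper):
    Y, X = expr.values, cov.values
    new = state.copy()
    Etau = new.tau_shape / new.tau_rate
    Ez = new.z_mean
    Ec = new.lambda_mean[None, :] + X @ new.beta_mean
    Xsq = X**2
    for p in range(X.shape[1]):
        EA = X @ new.alpha_mean
        partial = (
            Y
            - new.mu_mean[None, :]
            - (EA - np.outer(X[:, p], new.alpha_mean[p]))
            - Ec * Ez[:, None]
        )
        prec = hyper.tau_alpha + Etau * Xsq[:, p].sum()
        new.alpha_mean[p] = Etau * (X[:, p] @ partial) / prec
        new.alpha_var[p] = 1.0 / prec
    return new


def _update_lambda_beta(state, expr, cov, hyper):
    Y, X = expr.values, cov.values
    new = state.copy()
    Etau = new.tau_shape / new.tau_rate
    Echi = new.chi_shape / new.chi_rate
    Ez = new.z_mean
    Ez2 = new.z_mean**2 + new.z_var
    EA = X @ new.alpha_mean
    Xsq = X**2

    prec = hyper.tau_lambda + Etau * Ez2.sum()
    num = Etau * (Ez @ (Y - new.mu_mean[None, :] - EA) - Ez2 @ (X @ new.beta_mean))
    new.lambda_mean = num / prec
    new.lambda_var = 1.0 / prec

    # beta_pg has coefficient x_np z_n, so its precision picks up x^2 E[z^2]
    # while the cross terms against lambda and the other betas carry a
    # single factor of x_np
    for p in range(X.shape[1]):
        Xb = X @ new.beta_mean
        other = new.lambda_mean[None, :] + (Xb - np.outer(X[:, p], new.beta_mean[p]))
        prec = Echi[p] + Etau * (Xsq[:, p] @ Ez2)
        num = Etau * (
            (X[:, p] * Ez) @ (Y - new.mu_mean[None, :] - EA)
            - (X[:, p] * Ez2) @ other
        )
        new.beta_mean[p] = num / prec
        new.beta_var[p] = 1.0 / prec
    return new


@dataclass
class FitResult:
    """Raw outcome of the coordinate-ascent loop (wrapped by the Results API)."""

    state: VariationalState
    converged: bool
    n_iterations: int
    final_elbo: float
    init_vector: np.ndarray


def fit(
    expr: ExpressionMatrix,
    cov: CovariateMatrix,
    hyper: Hyperparameters,
    state: VariationalState,
    options: FitOptions | None = None,
) -> FitResult:
    """Run coordinate ascent from ``state`` until the ELBO stabilises.

    After convergence the reflection non-identifiability — the ELBO is
    invariant under joint negation of (z, lambda, beta) — is resolved by
    flipping the triple so that the fitted pseudotime correlates positively
    with its initialisation vector.  The flip is skipped when an informative
    pseudotime prior (nonzero q) is supplied, since negation is then not a
    symmetry of the model.
    """
    options = options or FitOptions()
    init_vector = state.z_mean.copy()
    state = state.copy()

    elbo = compute_elbo(state, expr, cov, hyper)
    last_checked = elbo
    converged = False
    it = 0
    for it in range(1, options.max_iterations + 1):
        for block in options.update_order:
            state = _apply_block(block, state, expr, cov, hyper)
        elbo = compute_elbo(state, expr, cov, hyper)
        if options.record_trace:
            state.elbo_trace.append(elbo)
        logger.debug("sweep %d: ELBO = %.6f", it, elbo)
        state.iteration = it
        if it % options.elbo_check_every == 0:
            rel = abs(elbo - last_checked) / max(abs(last_checked), 1e-300)
            if rel < options.elbo_rel_tol:
                converged = True
                break
            last_checked = elbo

    if not converged:
        warnings.warn(
            f"coordinate ascent did not converge in {options.max_iterations} sweeps "
            f"(last relative ELBO change above {options.elbo_rel_tol:g})",
            ConvergenceWarning,
            stacklevel=2,
        )

    q_is_zero = hyper.q is None or not np.any(hyper.q)
    if q_is_zero and float(state.z_mean @ init_vector) < 0.0:
        state.z_mean = -state.z_mean
        state.lambda_mean = -state.lambda_mean
        state.beta_mean = -state.beta_mean

    return FitResult(
        state=state,
        converged=converged,
        n_iterations=it,
        final_elbo=elbo,
        init_vector=init_vector,
    )
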