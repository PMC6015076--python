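"""Hyperparameters, fit options, and the variational state.

Model hierarchy (binary or continuous covariates x_np, latent pseudotime z_n):

    y_ng = mu_g + sum_p alpha_pg x_np + (lambda_g + sum_p beta_pg x_np) z_n + eps_ng

    mu_g      ~ N(0, 1/tau_mu)         gene intercept
    alpha_pg  ~ N(0, 1/tau_alpha)      static covariate effect
    lambda_g  ~ N(0, 1/tau_lambda)     pseudotime loading
    beta_pg   ~ N(0, 1/chi_pg)         covariate x pseudotime interaction
    chi_pg    ~ Gamma(a_beta, b_beta)  ARD-style shrinkage precision
    z_n       ~ N(q_n, 1/tau_q)        pseudotime (q_n = 0 when uninformative)
    tau_g     ~ Gamma(a, b)            gene noise precision
    eps_ng    ~ N(0, 1/tau_g)

Gamma priors are placed on the *precisions* chi_pg and tau_g (shape/rate
parameterisation); this is the choice under which every coordinate update of
the mean-field scheme is conjugate and available in closed form.

The mean-field posterior factorises into independent Normal factors for
z, mu, lambda, alpha, beta and Gamma factors for tau and chi; all of their
parameters live in :class:`VariationalState`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np

from .exceptions import ConfigError, DimensionError

__all__ = ["Hyperparameters", "FitOptions", "VariationalState", "UPDATE_BLOCKS"]


@dataclass(frozen=True)
class Hyperparameters:
    """Fixed prior precisions / Gamma shapes and the ranking constant k.

    Defaults are vague for the location and loading parameters
    (``tau_mu = tau_alpha = tau_lambda = 0.01``), unit-informative for the
    pseudotime (``tau_q = 1``), weakly informative for the noise precision
    (``a = b = 2``), and sparsity-inducing for the interactions
    (``a_beta = b_beta = 0.1``, a heavy-tailed marginal on beta).  ``k = 3``
    labels an interaction as significant when zero lies more than three
    posterior standard deviations from the posterior mean of beta.
    """

    tau_alpha: float = 0.01
    tau_lambda: float = 0.01
    tau_mu: float = 0.01
    tau_q: float = 1.0
    a: float = 2.0
    b: float = 2.0
    a_beta: float = 0.1
    b_beta: float = 0.1
    k: float = 3.0
    q: np.ndarray | None = None  # per-sample pseudotime prior means

    def __post_init__(self):
        for f in fields(self):
            if f.name == "q":
                continue
            v = getattr(self, f.name)
            if not (np.isscalar(v) and np.isfinite(v) and v > 0):
                raise ConfigError(f"hyperparameter {f.name} must be a positive scalar, got {v!r}")
        if self.q is not None:
            q = np.asarray(self.q, dtype=float).ravel()
            if not np.all(np.isfinite(q)):
                raise ConfigError("pseudotime prior means q must be finite")
            object.__setattr__(self, "q", q)

    @classmethod
    def simulation_default(cls) -> "Hyperparameters":
        """Unit-scale hierarchy used by the linear generative simulator.

        All effects are O(1), matching the scale of log-expression data:
        intercepts, static effects and loadings have unit prior variance and
        interaction precisions follow Gamma(2, 2) so that beta is moderate-
        tailed rather than the heavy-tailed fitting default.
        """
        return cls(
            tau_alpha=1.0, tau_lambda=1.0, tau_mu=1.0, tau_q=1.0,
            a=2.0, b=2.0, a_beta=2.0, b_beta=2.0, k=3.0,
        )

    def prior_means_for(self, n_samples: int) -> np.ndarray:
        """The length-N vector q of pseudotime prior means (zeros by default)."""
        if self.q is None:
            return np.zeros(n_samples)
        if self.q.shape[0] != n_samples:
            raise DimensionError(
                f"pseudotime prior means have length {self.q.shape[0]}, expected {n_samples}"
            )
        return self.q


UPDATE_BLOCKS = ("z", "mu", "alpha", "lambda_beta", "tau", "chi")


@dataclass(frozen=True)
class FitOptions:
    """Convergence control for the coordinate-ascent loop.

    The loop sweeps the update blocks in ``update_order`` and stops when the
    relative ELBO change over ``elbo_check_every`` sweeps drops below
    ``elbo_rel_tol`` or ``max_iterations`` sweeps have run.
    """

    max_iterations: int = 500
    elbo_rel_tol: float = 1e-5
    elbo_check_every: int = 1
    update_order: tuple = UPDATE_BLOCKS
    record_trace: bool = True

    def __post_init__(self):
        if self.max_iterations < 1:
            raise ConfigError("max_iterations must be >= 1")
        if not self.elbo_rel_tol > 0:
            raise ConfigError("elbo_rel_tol must be > 0")
        if self.elbo_check_every < 1:
            raise ConfigError("elbo_check_every must be >= 1")
        order = tuple(self.update_order)
        unknown = set(order) - set(UPDATE_BLOCKS)
        if unknown:
            raise ConfigError(f"unknown update blocks {sorted(unknown)}; valid: {UPDATE_BLOCKS}")
        if len(set(order)) != len(order):
            raise ConfigError("update_order must not repeat blocks")
        object.__setattr__(self, "update_order", order)


@dataclass
class VariationalState:
    """All factor-wise variational parameters plus the ELBO trace.

    Normal factors store (mean, variance); Gamma factors store (shape, rate).
    Shapes: z_* are (N,), mu_* / lambda_* / tau_* are (G,), alpha_* / beta_* /
    chi_* are (P, G).
    """

    z_mean: np.ndarray
    z_var: np.ndarray
    mu_mean: np.ndarray
    mu_var: np.ndarray
    lambda_mean: np.ndarray
    lambda_var: np.ndarray
    alpha_mean: np.ndarray
    alpha_var: np.ndarray
    beta_mean: np.ndarray
    beta_var: np.ndarray
    tau_shape: np.ndarray
    tau_rate: np.ndarray
    chi_shape: np.ndarray
    chi_rate: np.ndarray
    elbo_trace: list = field(default_factory=list)
    iteration: int = 0

    @property
    def n_samples(self) -> int:
        return self.z_mean.shape[0]

    @property
    def n_genes(self) -> int:
        return self.mu_mean.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.beta_mean.shape[0]

    def copy(self) -> "VariationalState":
        arrays = {
            f.name: getattr(self, f.name).copy()
            for f in fields(self)
            if f.name not in ("elbo_trace", "iteration")
        }
        return VariationalState(**arrays, elbo_trace=list(self.elbo_trace), iteration=self.iteration)

    def validate(self) -> None:
        """Cheap internal-consistency check on positivity of scale parameters."""
        for name in ("z_var", "mu_var", "lambda_var", "alpha_var", "beta_var",
                     "tau_shape", "tau_rate", "chi_shape", "chi_rate"):
            arr = getattr(self, name)
            if arr.size and not np.all(arr > 0):
                from .exceptions import InternalStateError

                raise InternalStateError(f"variational parameter {name} is not strictly positive")

    def replace(self, **kwargs) -> "VariationalState":
        return replace(self, **kwargs)
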