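"""The user-facing model object, statsmodels-style.

:class:`CovariateTrajectoryModel` bundles a centred expression matrix, a
covariate design matrix and the prior hyperparameters; ``fit()`` runs
coordinate-ascent variational inference and returns a
:class:`~covtraj.results.CovariateTrajectoryResults`.

Example
-------
>>> from covtraj import CovariateTrajectoryModel, simulate_linear
>>> expr, cov, truth = simulate_linear(n_samples=100, n_genes=40, seed=0)
>>> model = CovariateTrajectoryModel(expr, cov)
>>> res = model.fit(seed=0)
>>> res.pseudotime.shape
(100,)
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import cavi
from .containers import CovariateMatrix, ExpressionMatrix, validate_and_center
from .exceptions import ConfigError, DimensionError, UnsupportedCovariateError
from .params import FitOptions, Hyperparameters, VariationalState

__all__ = ["CovariateTrajectoryModel", "initialize_state", "encode_covariate_frame"]

INIT_POLICIES = ("pc1", "random", "supplied")


def initialize_state(
    expr: ExpressionMatrix,
    cov: CovariateMatrix,
    hyper: Hyperparameters,
    init: str = "pc1",
    seed: int = 0,
    z_init: np.ndarray | None = None,
    z_init_var: float = 1.0,
) -> VariationalState:
    """Build the starting variational state.

    Pseudotime means follow the chosen policy; loading means start at the
    per-gene least-squares slope of Y on the initial pseudotime (a zero
    loading init is a degenerate fixed point of the coordinate ascent: the
    first z update would collapse the pseudotime to its prior mean).  All
    other means start at 0, every Normal variance at 1, and the Gamma
    factors at their priors.  The result is a pure function of the
    arguments (same policy + seed, same state).

    Policies
    --------
    ``pc1``
        First principal-component scores of the centred Y, standardised to
        mean 0 / variance 1, computed after projecting out the covariate
        columns (static covariate effects are modelled separately and can
        otherwise dominate the leading component).  The dominant solution
        of this model family lies near this direction, so the policy both
        speeds convergence and anchors the sign convention.
    ``random``
        Independent standard-normal draws from ``seed``.
    ``supplied``
        A user vector passed via ``z_init`` (length N), used as-is.
    """
    n, g = expr.n_samples, expr.n_genes
    p = cov.n_covariates
    if init not in INIT_POLICIES:
        raise ConfigError(f"unknown init policy {init!r}; choose from {INIT_POLICIES}")

    if init == "pc1":
        Yc = expr.values - expr.values.mean(axis=0)
        if p:
            X = cov.values
            coef, *_ = np.linalg.lstsq(X, Yc, rcond=None)
            Yc = Yc - X @ coef
        # scores of the first right singular vector; deterministic sign fix
        _, s, vt = np.linalg.svd(Yc, full_matrices=False)
        scores = Yc @ vt[0]
        if scores[np.argmax(np.abs(scores))] < 0:
            scores = -scores
        sd = scores.std()
        z0 = (scores - scores.mean()) / (sd if sd > 0 else 1.0)
    elif init == "random":
        rng = np.random.default_rng(seed)
        z0 = rng.standard_normal(n)
    else:
        if z_init is None:
            raise ConfigError("init policy 'supplied' requires a z_init vector")
        z0 = np.asarray(z_init, dtype=float).ravel()
        if z0.shape[0] != n:
            raise DimensionError(f"supplied z_init has length {z0.shape[0]}, expected {n}")
    if not z_init_var > 0:
        raise ConfigError("z_init_var must be > 0")

    z0 = z0.astype(float)
    ss = float(z0 @ z0)
    lam0 = (expr.values - expr.values.mean(axis=0)).T @ z0 / ss if ss > 0 else np.zeros(g)

    return VariationalState(
        z_mean=z0,
        z_var=np.full(n, float(z_init_var)),
        mu_mean=np.zeros(g),
        mu_var=np.ones(g),
        lambda_mean=lam0,
        lambda_var=np.ones(g),
        alpha_mean=np.zeros((p, g)),
        alpha_var=np.ones((p, g)),
        beta_mean=np.zeros((p, g)),
        beta_var=np.ones((p, g)),
        tau_shape=np.full(g, hyper.a),
        tau_rate=np.full(g, hyper.b),
        chi_shape=np.full((p, g), hyper.a_beta),
        chi_rate=np.full((p, g), hyper.b_beta),
    )


def encode_covariate_frame(
    frame: pd.DataFrame, standardize: bool = True
) -> tuple[CovariateMatrix, dict]:
    """Numeric-encode a covariate DataFrame.

    Two-level string/categorical columns are coded {-1, +1} with levels in
    sorted order; numeric columns are standardised to mean 0 / unit variance
    when ``standardize`` is true.  Columns with more than two string levels
    are rejected (one-hot encode them upstream if needed).

    Returns the matrix plus a coding record mapping each column to either
    ``{"kind": "binary", "levels": {level: code}}`` or
    ``{"kind": "numeric", "mean": m, "sd": s}``.
    """
    columns = []
    coding: dict = {}
    for name in frame.columns:
        col = frame[name]
        if pd.api.types.is_numeric_dtype(col) and not isinstance(col.dtype, pd.CategoricalDtype):
            vals = col.to_numpy(dtype=float)
            uniq = np.unique(vals)
            if standardize and uniq.size > 2:
                m, s = float(vals.mean()), float(vals.std())
                if s > 0:
                    vals = (vals - m) / s
                coding[str(name)] = {"kind": "numeric", "mean": m, "sd": s}
            elif uniq.size == 2 and set(uniq) != {-1.0, 1.0}:
                lo, hi = sorted(uniq)
                vals = np.where(vals == lo, -1.0, 1.0)
                coding[str(name)] = {
                    "kind": "binary",
                    "levels": {repr(lo): -1.0, repr(hi): 1.0},
                }
            else:
                coding[str(name)] = {"kind": "numeric", "mean": 0.0, "sd": 1.0}
        else:
            levels = sorted(map(str, col.astype(str).unique()))
            if len(levels) == 1:
                raise UnsupportedCovariateError(
                    f"covariate column {name!r} is constant and carries no information"
                )
            if len(levels) > 2:
                raise UnsupportedCovariateError(
                    f"covariate column {name!r} has {len(levels)} levels "
                    f"({', '.join(levels[:4])}...); encode it (e.g. one-hot) before fitting"
                )
            mapping = {levels[0]: -1.0, levels[1]: 1.0}
            vals = col.astype(str).map(mapping).to_numpy(dtype=float)
            coding[str(name)] = {"kind": "binary", "levels": mapping}
        columns.append(vals)
    values = np.column_stack(columns) if columns else np.empty((len(frame), 0))
    return CovariateMatrix(values, covariate_ids=tuple(map(str, frame.columns))), coding


class CovariateTrajectoryModel:
    """Latent-pseudotime regression with covariate-modulated loadings.

    Each gene's expected expression is linear in a shared latent pseudotime
    z, with an intercept and slope that both shift with observed covariates:

        E[y_ng] = mu_g + sum_p alpha_pg x_np + (lambda_g + sum_p beta_pg x_np) z_n

    A sparse (ARD-style) prior on the interaction coefficients beta lets
    covariates bend trajectories only where the data demand it.  With P = 0
    the model is a one-factor Bayesian factor analysis; with z fixed at 0 it
    is gene-wise Bayesian linear regression on the covariates — standard
    models are nested special cases.

    Parameters
    ----------
    expr : ExpressionMatrix or array-like
        N x G continuous expression values (log-scale recommended).
        Columns are mean-centred on construction.
    cov : CovariateMatrix, array-like, or None
        N x P design matrix; None means P = 0 (pure factor analysis).
    hyper : Hyperparameters, optional
        Prior settings; see :class:`~covtraj.params.Hyperparameters`.
    """

    def __init__(self, expr, cov=None, hyper: Hyperparameters | None = None):
        if not isinstance(expr, ExpressionMatrix):
            expr = ExpressionMatrix(np.asarray(expr, dtype=float))
        if cov is not None and not isinstance(cov, CovariateMatrix):
            cov = CovariateMatrix(np.asarray(cov, dtype=float))
        self.expr, self.cov = validate_and_center(expr, cov)
        self.hyper = hyper or Hyperparameters()
        self.covariate_coding: dict = {}

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_dataframe(
        cls,
        expression: pd.DataFrame,
        covariates: pd.DataFrame | None = None,
        hyper: Hyperparameters | None = None,
        standardize_covariates: bool = True,
    ) -> "CovariateTrajectoryModel":
        """Build from pandas DataFrames (samples in rows for both).

        String covariate columns with two levels are auto-coded {-1, +1};
        numeric ones are standardised unless disabled.
        """
        expr = ExpressionMatrix(
            expression.to_numpy(dtype=float),
            sample_ids=tuple(map(str, expression.index)),
            gene_ids=tuple(map(str, expression.columns)),
        )
        coding: dict = {}
        if covariates is not None:
            if len(covariates) != len(expression):
                raise DimensionError(
                    f"expression has {len(expression)} rows but covariates has {len(covariates)}"
                )
            cov, coding = encode_covariate_frame(covariates, standardize=standardize_covariates)
        else:
            cov = None
        model = cls(expr, cov, hyper=hyper)
        model.covariate_coding = coding
        return model

    # -- properties -------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.expr.n_samples

    @property
    def n_genes(self) -> int:
        return self.expr.n_genes

    @property
    def n_covariates(self) -> int:
        return self.cov.n_covariates

    # -- fitting ----------------------------------------------------------
    def fit(
        self,
        options: FitOptions | None = None,
        init: str = "pc1",
        seed: int = 0,
        z_init: np.ndarray | None = None,
        z_init_var: float = 1.0,
        verbose: bool = False,
    ):
        """Run coordinate-ascent variational inference.

        Deterministic given (options, init, seed, z_init).  Non-convergence
        within ``options.max_iterations`` raises no error; it sets
        ``converged = False`` and emits a warning.
        """
        from .results import CovariateTrajectoryResults

        state = initialize_state(
            self.expr, self.cov, self.hyper,
            init=init, seed=seed, z_init=z_init, z_init_var=z_init_var,
        )
        if verbose:
            import logging

            logging.getLogger("covtraj.cavi").setLevel(logging.DEBUG)
        raw = cavi.fit(self.expr, self.cov, self.hyper, state, options)
        return CovariateTrajectoryResults(self, raw, options or FitOptions())
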