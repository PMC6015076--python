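"""Post-fit interpretation: interaction calls, cross-over points, prediction.

An interaction (covariate p, gene g) is *significant* when zero lies more
than ``k`` posterior standard deviations from the posterior mean of the
interaction coefficient:

    |m_beta| / s_beta > k        (strict inequality)

This is a posterior-tail decision rule, not a frequentist test — there are
no p-values and no multiplicity correction by design.

For a binary covariate coded {-1, +1}, the two groups' expected expression
curves

    mu_g + alpha_pg + (lambda_g + beta_pg) z      (x = +1)
    mu_g - alpha_pg + (lambda_g - beta_pg) z      (x = -1)

intersect at the cross-over pseudotime  z* = -alpha_pg / beta_pg, the point
where the covariate stops (or starts) mattering for that gene.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import (
    ConfigError,
    DimensionError,
    UndefinedResultError,
    UnsupportedCovariateError,
)

__all__ = [
    "call_interactions",
    "crossover_point",
    "predict_expression",
    "crossover_unit_interval",
]

#: below this absolute posterior mean, beta is treated as zero (parallel curves)
BETA_TOL = 1e-10

INTERACTION_COLUMNS = [
    "covariate", "gene", "beta_mean", "beta_sd", "z_score",
    "significant", "crossover", "alpha_mean", "lambda_mean",
]


def _is_binary_pm1(x: np.ndarray) -> bool:
    return bool(np.all(np.isin(x, (-1.0, 1.0))) and np.unique(x).size == 2)


def call_interactions(results, k: float | None = None) -> pd.DataFrame:
    """Rank every (covariate, gene) pair by its interaction evidence.

    Returns a DataFrame with one row per pair, sorted significant-first and
    by descending |beta_mean| within each significance class.  ``k``
    defaults to the model hyperparameter (3).  Cross-over points are filled
    where they are defined (binary covariate, |beta| above tolerance) and
    are NaN otherwise.
    """
    if k is None:
        k = results.hyper.k
    if not k > 0:
        raise ConfigError(f"ranking threshold k must be > 0, got {k}")
    state = results.state
    P, G = state.beta_mean.shape
    rows = []
    for p in range(P):
        x = results.covariate_values[:, p]
        binary = _is_binary_pm1(x)
        for g in range(G):
            m = float(state.beta_mean[p, g])
            s = float(np.sqrt(state.beta_var[p, g]))
            z = abs(m) / s
            cross = np.nan
            if binary and abs(m) > BETA_TOL:
                cross = -float(state.alpha_mean[p, g]) / m
            rows.append(
                {
                    "covariate": results.covariate_ids[p],
                    "gene": results.gene_ids[g],
                    "beta_mean": m,
                    "beta_sd": s,
                    "z_score": z,
                    "significant": z > k,
                    "crossover": cross,
                    "alpha_mean": float(state.alpha_mean[p, g]),
                    "lambda_mean": float(state.lambda_mean[g]),
                }
            )
    table = pd.DataFrame(rows, columns=INTERACTION_COLUMNS)
    table["abs_beta"] = table["beta_mean"].abs()
    table = (
        table.sort_values(["significant", "abs_beta"], ascending=[False, False], kind="mergesort")
        .drop(columns="abs_beta")
        .reset_index(drop=True)
    )
    return table


def crossover_point(results, gene, covariate) -> float:
    """Pseudotime z* = -alpha / beta at which the two covariate groups' curves meet.

    Requires the covariate to be binary {-1, +1}-coded and the interaction
    coefficient to be numerically nonzero; otherwise the trajectories are
    parallel and no cross-over exists.
    """
    g = results.gene_index(gene)
    p = results.covariate_index(covariate)
    x = results.covariate_values[:, p]
    if not _is_binary_pm1(x):
        raise UnsupportedCovariateError(
            f"covariate {results.covariate_ids[p]!r} is not binary {{-1, +1}}-coded; "
            "cross-over points are only defined for two-group covariates"
        )
    beta = float(results.state.beta_mean[p, g])
    if abs(beta) <= BETA_TOL:
        raise UndefinedResultError(
            f"interaction effect for gene {results.gene_ids[g]!r} is numerically zero; "
            "the group trajectories are parallel and never cross"
        )
    return -float(results.state.alpha_mean[p, g]) / beta


def crossover_unit_interval(results, gene, covariate) -> float:
    """Cross-over point mapped to [0, 1] by min-max over the fitted pseudotimes.

    Values outside [0, 1] mean the curves cross beyond the observed
    trajectory; they are returned unclipped.
    """
    z_star = crossover_point(results, gene, covariate)
    z = results.state.z_mean
    lo, hi = float(z.min()), float(z.max())
    if hi <= lo:
        raise UndefinedResultError("fitted pseudotimes are constant; cannot rescale")
    return (z_star - lo) / (hi - lo)


def predict_expression(results, z_grid, x_row) -> np.ndarray:
    """Posterior-mean expression curves on a pseudotime grid.

    Evaluates  mu_g + sum_p alpha_pg x_p + (lambda_g + sum_p beta_pg x_p) z
    at each z in ``z_grid`` for one covariate profile ``x_row``; returns a
    (len(z_grid), G) matrix on the centred expression scale.
    """
    z_grid = np.atleast_1d(np.asarray(z_grid, dtype=float))
    if not np.all(np.isfinite(z_grid)):
        raise UndefinedResultError("z_grid must be finite")
    x_row = np.asarray(x_row, dtype=float).ravel()
    state = results.state
    P = state.beta_mean.shape[0]
    if x_row.shape[0] != P:
        raise DimensionError(f"x_row has length {x_row.shape[0]}, expected P = {P}")
    intercept = state.mu_mean + x_row @ state.alpha_mean
    slope = state.lambda_mean + x_row @ state.beta_mean
    return intercept[None, :] + np.outer(z_grid, slope)
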