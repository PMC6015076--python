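"""Results object returned by :meth:`CovariateTrajectoryModel.fit`.

Carries the converged variational state, exposes the fitted pseudotime and
its uncertainty, delegates interpretation to :mod:`covtraj.interactions`,
and round-trips losslessly through a JSON container on disk.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from . import interactions as _interactions
from .exceptions import ValidationError
from .params import FitOptions, Hyperparameters, VariationalState

__all__ = ["CovariateTrajectoryResults", "load_fit", "save_fit"]

_FORMAT = "covtraj-fit"
_FORMAT_VERSION = 1

_STATE_ARRAYS = [
    "z_mean", "z_var", "mu_mean", "mu_var", "lambda_mean", "lambda_var",
    "alpha_mean", "alpha_var", "beta_mean", "beta_var",
    "tau_shape", "tau_rate", "chi_shape", "chi_rate",
]


class CovariateTrajectoryResults:
    """A completed covariate-trajectory fit.

    Attributes
    ----------
    state : VariationalState
        All variational posterior parameters and the ELBO trace.
    converged : bool
        Whether the ELBO met the relative tolerance before the sweep limit.
    pseudotime : (N,) array
        Posterior mean of the latent progression z (sign-anchored to the
        initialisation vector).
    """

    def __init__(self, model, raw, options: FitOptions, *, _loaded=None):
        if _loaded is not None:
            (self.state, self.hyper, self.converged, self.n_iterations,
             self.final_elbo, self.sample_ids, self.gene_ids,
             self.covariate_ids, self.covariate_values, self.covariate_coding) = _loaded
            self.model = None
            self.options = options
        else:
            self.model = model
            self.state = raw.state
            self.hyper = model.hyper
            self.options = options
            self.converged = raw.converged
            self.n_iterations = raw.n_iterations
            self.final_elbo = raw.final_elbo
            self.sample_ids = model.expr.sample_ids
            self.gene_ids = model.expr.gene_ids
            self.covariate_ids = model.cov.covariate_ids
            self.covariate_values = model.cov.values.copy()
            self.covariate_coding = dict(getattr(model, "covariate_coding", {}))

    # -- lookups ----------------------------------------------------------
    def gene_index(self, gene) -> int:
        if isinstance(gene, (int, np.integer)):
            return int(gene)
        return self.gene_ids.index(str(gene))

    def covariate_index(self, covariate) -> int:
        if isinstance(covariate, (int, np.integer)):
            return int(covariate)
        return self.covariate_ids.index(str(covariate))

    # -- headline quantities ----------------------------------------------
    @property
    def pseudotime(self) -> np.ndarray:
        return self.state.z_mean

    @property
    def pseudotime_sd(self) -> np.ndarray:
        return np.sqrt(self.state.z_var)

    @property
    def elbo_trace(self) -> list:
        return self.state.elbo_trace

    def pseudotime_series(self) -> pd.Series:
        return pd.Series(self.state.z_mean, index=list(self.sample_ids), name="pseudotime")

    # -- interpretation (delegates) ---------------------------------------
    def interactions(self, k: float | None = None) -> pd.DataFrame:
        """Ranked interaction table; see :func:`covtraj.interactions.call_interactions`."""
        return _interactions.call_interactions(self, k=k)

    def crossover_point(self, gene, covariate=0) -> float:
        return _interactions.crossover_point(self, gene, covariate)

    def crossover_unit_interval(self, gene, covariate=0) -> float:
        return _interactions.crossover_unit_interval(self, gene, covariate)

    def predict(self, z_grid, x_row=None) -> np.ndarray:
        if x_row is None:
            x_row = np.zeros(self.state.beta_mean.shape[0])
        return _interactions.predict_expression(self, z_grid, x_row)

    # -- reporting ---------------------------------------------------------
    def summary(self, top: int = 5) -> str:
        """Human-readable fit summary with the top-ranked interactions."""
        n = self.state.n_samples
        g = self.state.n_genes
        p = self.state.n_covariates
        lines = [
            "Covariate-modulated pseudotime trajectory fit",
            "=" * 53,
            f"Samples:            {n}",
            f"Genes:              {g}",
            f"Covariates:         {p}",
            f"Converged:          {self.converged}  ({self.n_iterations} sweeps)",
            f"Final ELBO:         {self.final_elbo:.4f}",
            f"Pseudotime range:   [{self.state.z_mean.min():.3f}, {self.state.z_mean.max():.3f}]",
        ]
        if p:
            table = self.interactions()
            n_sig = int(table["significant"].sum())
            lines.append(f"Significant interactions (k={self.hyper.k:g}): {n_sig} / {len(table)}")
            lines.append("-" * 53)
            head = table.head(top)[["covariate", "gene", "beta_mean", "beta_sd", "z_score", "significant"]]
            lines.append(head.to_string(index=False, float_format=lambda v: f"{v: .4f}"))
        return "\n".join(lines)

    # -- serialization ------------------------------------------------------
    def save(self, path) -> None:
        """Write the fit to a single JSON container (lossless round trip)."""
        save_fit(self, path)

    @classmethod
    def load(cls, path) -> "CovariateTrajectoryResults":
        return load_fit(path)


def save_fit(results: CovariateTrajectoryResults, path) -> None:
    """Serialise a fit to JSON.

    Floats are written via Python's shortest-repr rule, which round-trips
    binary64 exactly, so save -> load -> save is byte-identical.
    """
    state = results.state
    payload = {
        "format": _FORMAT,
        "format_version": _FORMAT_VERSION,
        "software_version": _pkg_version,
        "state": {name: getattr(state, name).tolist() for name in _STATE_ARRAYS},
        "elbo_trace": list(state.elbo_trace),
        "iteration": state.iteration,
        "hyper": {
            **{k: getattr(results.hyper, k) for k in
               ("tau_alpha", "tau_lambda", "tau_mu", "tau_q", "a", "b", "a_beta", "b_beta", "k")},
            "q": None if results.hyper.q is None else results.hyper.q.tolist(),
        },
        "options": {
            "max_iterations": results.options.max_iterations,
            "elbo_rel_tol": results.options.elbo_rel_tol,
            "elbo_check_every": results.options.elbo_check_every,
            "update_order": list(results.options.update_order),
            "record_trace": results.options.record_trace,
        },
        "labels": {
            "sample_ids": list(results.sample_ids),
            "gene_ids": list(results.gene_ids),
            "covariate_ids": list(results.covariate_ids),
        },
        "covariate_values": results.covariate_values.tolist(),
        "covariate_coding": results.covariate_coding,
        "converged": results.converged,
        "n_iterations": results.n_iterations,
        "final_elbo": results.final_elbo,
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def load_fit(path) -> CovariateTrajectoryResults:
    """Load a fit saved by :func:`save_fit`; the expression data itself is
    not stored, so the returned object has ``model = None``."""
    text = Path(path).read_text()
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ValidationError(f"fit file {path} is not valid JSON (truncated?): {exc}") from exc
    if payload.get("format") != _FORMAT:
        raise ValidationError(f"{path} is not a covtraj fit container")
    fv = payload.get("format_version")
    if fv != _FORMAT_VERSION:
        raise ValidationError(
            f"fit container version {fv} is not supported by this software "
            f"(expects {_FORMAT_VERSION}, written by covtraj {payload.get('software_version')})"
        )
    sd = payload["state"]
    n_cov = len(payload["labels"]["covariate_ids"])
    n_genes = len(payload["labels"]["gene_ids"])

    def arr(name, ndim):
        a = np.asarray(sd[name], dtype=float)
        if ndim == 2 and a.size == 0:
            a = a.reshape(n_cov, n_genes)
        return a

    state = VariationalState(
        **{name: arr(name, 2 if name.startswith(("alpha", "beta", "chi")) else 1)
           for name in _STATE_ARRAYS},
        elbo_trace=list(payload["elbo_trace"]),
        iteration=int(payload["iteration"]),
    )
    h = payload["hyper"]
    hyper = Hyperparameters(**{k: v for k, v in h.items() if k != "q"},
                            q=None if h["q"] is None else np.asarray(h["q"]))
    o = payload["options"]
    options = FitOptions(
        max_iterations=o["max_iterations"],
        elbo_rel_tol=o["elbo_rel_tol"],
        elbo_check_every=o["elbo_check_every"],
        update_order=tuple(o["update_order"]),
        record_trace=o["record_trace"],
    )
    labels = payload["labels"]
    cov_values = np.asarray(payload["covariate_values"], dtype=float)
    if cov_values.size == 0:
        cov_values = cov_values.reshape(len(labels["sample_ids"]), 0)
    loaded = (
        state, hyper, payload["converged"], payload["n_iterations"],
        payload["final_elbo"], tuple(labels["sample_ids"]),
        tuple(labels["gene_ids"]), tuple(labels["covariate_ids"]),
        cov_values, payload["covariate_coding"],
    )
    return CovariateTrajectoryResults(None, None, options, _loaded=loaded)
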