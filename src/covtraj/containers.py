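"""Data containers: expression and covariate matrices with validation.

The model works on a samples-by-genes matrix ``Y`` of continuous expression
values (typically log-transformed normalised counts) and a samples-by-
covariates design matrix ``X``.  Columns of ``Y`` must be mean-centred before
fitting; gene- and covariate-specific intercepts are part of the model, so
centring loses no information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import DimensionError, ValidationError

__all__ = [
    "ExpressionMatrix",
    "CovariateMatrix",
    "validate_and_center",
    "ZeroVarianceWarning",
]

class ZeroVarianceWarning(UserWarning):
    """A gene column has zero variance; its loadings will shrink to the prior."""


def _as_float_matrix(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise DimensionError(f"{name} must be 2-dimensional, got shape {arr.shape}")
    return arr


def _check_finite(arr: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(arr)):
        bad = np.argwhere(~np.isfinite(arr))
        head = ", ".join(f"({i}, {j})" for i, j in bad[:10])
        more = "" if len(bad) <= 10 else f" and {len(bad) - 10} more"
        raise ValidationError(
            f"{name} contains non-finite entries at coordinates {head}{more}"
        )


@dataclass(frozen=True)
class ExpressionMatrix:
    """N samples x G genes matrix of continuous expression values.

    Parameters
    ----------
    values : (N, G) float array
        Expression values, samples in rows.
    sample_ids, gene_ids : sequences of str
        Row / column labels.  Generated automatically when omitted.
    centred : bool
        True once every gene column has been mean-centred.
    """

    values: np.ndarray
    sample_ids: tuple = field(default=None)
    gene_ids: tuple = field(default=None)
    centred: bool = False

    def __post_init__(self):
        arr = _as_float_matrix(self.values, "expression matrix")
        object.__setattr__(self, "values", arr)
        n, g = arr.shape
        if n < 2 or g < 1:
            raise DimensionError(
                f"expression matrix needs N >= 2 samples and G >= 1 genes, got {n} x {g}"
            )
        sids = self.sample_ids
        gids = self.gene_ids
        sids = tuple(f"sample_{i}" for i in range(n)) if sids is None else tuple(map(str, sids))
        gids = tuple(f"gene_{j}" for j in range(g)) if gids is None else tuple(map(str, gids))
        if len(sids) != n:
            raise DimensionError(f"{len(sids)} sample ids for {n} rows")
        if len(gids) != g:
            raise DimensionError(f"{len(gids)} gene ids for {g} columns")
        object.__setattr__(self, "sample_ids", sids)
        object.__setattr__(self, "gene_ids", gids)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class CovariateMatrix:
    """N samples x P covariates design matrix.

    P may be zero, in which case the model degenerates to a pure one-factor
    factor analysis.  Binary covariates are conventionally coded {-1, +1}
    so that alpha is the half-difference of group intercepts and beta the
    half-difference of group loadings.
    """

    values: np.ndarray
    covariate_ids: tuple = field(default=None)

    def __post_init__(self):
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        if arr.ndim != 2:
            raise DimensionError(f"covariate matrix must be 2-d, got shape {arr.shape}")
        object.__setattr__(self, "values", arr)
        cids = self.covariate_ids
        p = arr.shape[1]
        cids = tuple(f"covariate_{j}" for j in range(p)) if cids is None else tuple(map(str, cids))
        if len(cids) != p:
            raise DimensionError(f"{len(cids)} covariate ids for {p} columns")
        object.__setattr__(self, "covariate_ids", cids)

    @classmethod
    def empty(cls, n_samples: int) -> "CovariateMatrix":
        """A P = 0 design for the pure factor-analysis special case."""
        return cls(np.empty((n_samples, 0)), covariate_ids=())

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.values.shape[1]


def validate_and_center(
    expr: ExpressionMatrix, cov: CovariateMatrix | None = None
) -> tuple[ExpressionMatrix, CovariateMatrix]:
    """Validate paired inputs and mean-centre every gene column.

    Returns new containers; the inputs are never mutated.  Centring is
    idempotent: an already-centred matrix is returned unchanged.  Genes with
    zero variance are retained (their loadings simply shrink to the prior)
    but trigger a :class:`ZeroVarianceWarning` so callers can drop them
    deliberately.
    """
    if cov is None:
        cov = CovariateMatrix.empty(expr.n_samples)
    if cov.n_samples != expr.n_samples:
        raise DimensionError(
            f"expression matrix has {expr.n_samples} samples (shape "
            f"{expr.values.shape}) but covariate matrix has {cov.n_samples} "
            f"(shape {cov.values.shape})"
        )
    _check_finite(expr.values, "expression matrix")
    _check_finite(cov.values, "covariate matrix")

    zero_var = np.flatnonzero(expr.values.std(axis=0) == 0.0)
    if zero_var.size:
        names = ", ".join(expr.gene_ids[j] for j in zero_var[:5])
        warnings.warn(
            f"{zero_var.size} gene(s) have zero variance (e.g. {names}); "
            "their loadings will shrink to the prior",
            ZeroVarianceWarning,
            stacklevel=2,
        )

    # an already-centred matrix passes through bit-identically (idempotence)
    if expr.centred:
        return expr, cov
    col_means = expr.values.mean(axis=0)
    centred_values = expr.values - col_means
    centred = replace(expr, values=centred_values, centred=True)
    return centred, cov
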