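"""Synthetic-data generators.

Two complementary generators:

``simulate_linear``
    Exact draws from the model's own linear-Gaussian hierarchy, for
    parameter-recovery testing.  Well-specified by construction.

``simulate_nonlinear_nb``
    A deliberately *misspecified* single-cell-like RNA-seq generator:
    sigmoidal mean curves along a Uniform(0, 1) pseudotime with negative-
    binomial counts, where a tunable fraction of genes flips the direction
    of its pseudotemporal regulation with a binary covariate x in {-1, +1}.
    Nothing about it is linear or Gaussian, which is the point — it probes
    robustness of the trajectory model to a wrong likelihood.

``enumerate_grid``
    The full factorial benchmark design over interaction fractions, sample
    sizes, noise regimes and replicates, with one reproducible derived seed
    per cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .containers import CovariateMatrix, ExpressionMatrix
from .exceptions import ConfigError
from .params import Hyperparameters

__all__ = [
    "SimulationTruth",
    "SimGridSpec",
    "GridCell",
    "simulate_linear",
    "simulate_nonlinear_nb",
    "enumerate_grid",
    "to_log1p",
    "DEFAULT_FRACTIONS",
]

#: benchmark interaction fractions: 5-50% of genes carry an interaction
DEFAULT_FRACTIONS = (0.05, 0.10, 0.20, 0.30, 0.40, 0.50)

#: NB dispersion by noise regime (variance = mean + dispersion * mean^2)
NB_DISPERSION = {"low": 0.1, "high": 1.0}


@dataclass
class SimulationTruth:
    """Ground truth attached to a synthetic dataset."""

    z_true: np.ndarray
    x: np.ndarray
    gene_regime: np.ndarray  # {"static", "dynamic_common", "dynamic_interacting"}
    interaction_flags: np.ndarray
    true_params: dict
    seed: int

    def to_json_dict(self) -> dict:
        return {
            "z_true": self.z_true.tolist(),
            "x": self.x.tolist(),
            "gene_regime": self.gene_regime.tolist(),
            "interaction_flags": self.interaction_flags.astype(bool).tolist(),
            "true_params": {k: np.asarray(v).tolist() for k, v in self.true_params.items()},
            "seed": self.seed,
        }


def _check_fraction(fraction: float) -> None:
    if not (0.0 <= fraction <= 1.0):
        raise ConfigError(f"fraction_interacting must be in [0, 1], got {fraction}")


def _interaction_mask(n_genes: int, fraction: float, rng) -> np.ndarray:
    n_int = int(round(fraction * n_genes))
    mask = np.zeros(n_genes, dtype=bool)
    mask[rng.choice(n_genes, size=n_int, replace=False)] = True
    return mask


def simulate_linear(
    n_samples: int = 200,
    n_genes: int = 100,
    n_covariates: int = 1,
    fraction_interacting: float = 0.2,
    hyper: Hyperparameters | None = None,
    seed: int = 0,
) -> tuple[ExpressionMatrix, CovariateMatrix, SimulationTruth]:
    """Draw a dataset exactly from the linear-Gaussian model hierarchy.

    Every parameter (intercepts, static effects, loadings, interaction
    coefficients and their ARD precisions, pseudotimes, noise precisions)
    is sampled from its prior under ``hyper`` — by default the unit-scale
    :meth:`Hyperparameters.simulation_default` — except that beta is forced
    to zero for the non-interacting gene fraction.  Covariates are drawn
    uniformly from {-1, +1}.  Fully reproducible from ``seed``.
    """
    _check_fraction(fraction_interacting)
    hyper = hyper or Hyperparameters.simulation_default()
    rng = np.random.default_rng(seed)
    N, G, P = n_samples, n_genes, n_covariates

    x = rng.choice((-1.0, 1.0), size=(N, P))
    q = hyper.prior_means_for(N)
    z = q + rng.standard_normal(N) / np.sqrt(hyper.tau_q)
    mu = rng.standard_normal(G) / np.sqrt(hyper.tau_mu)
    lam = rng.standard_normal(G) / np.sqrt(hyper.tau_lambda)
    alpha = rng.standard_normal((P, G)) / np.sqrt(hyper.tau_alpha)
    chi = rng.gamma(hyper.a_beta, scale=1.0 / hyper.b_beta, size=(P, G))
    beta = rng.standard_normal((P, G)) / np.sqrt(chi)
    interacting = _interaction_mask(G, fraction_interacting, rng)
    beta[:, ~interacting] = 0.0
    tau = rng.gamma(hyper.a, scale=1.0 / hyper.b, size=G)

    loading = lam[None, :] + x @ beta
    Y = (
        mu[None, :]
        + x @ alpha
        + loading * z[:, None]
        + rng.standard_normal((N, G)) / np.sqrt(tau)[None, :]
    )

    regime = np.where(interacting, "dynamic_interacting", "dynamic_common")
    truth = SimulationTruth(
        z_true=z,
        x=x,
        gene_regime=regime.astype(object),
        interaction_flags=interacting,
        true_params={"mu": mu, "lambda": lam, "alpha": alpha, "beta": beta,
                     "chi": chi, "tau": tau},
        seed=seed,
    )
    expr = ExpressionMatrix(Y)
    cov = CovariateMatrix(x)
    return expr, cov, truth


def simulate_nonlinear_nb(
    n_samples: int = 200,
    n_genes: int = 200,
    fraction_interacting: float = 0.2,
    noise_regime: str = "low",
    seed: int = 0,
    t0_range: tuple = (0.2, 0.8),
    slope_range: tuple = (5.0, 20.0),
    log2_amplitude_range: tuple = (2.0, 6.0),
    dispersion: float | None = None,
) -> tuple[ExpressionMatrix, CovariateMatrix, SimulationTruth]:
    """Misspecified RNA-seq counts with covariate-flipped sigmoidal trajectories.

    Per sample: pseudotime z ~ Uniform(0, 1) and one binary covariate
    x in {-1, +1}.  Per gene g: a switch time t0_g, an absolute slope k_g
    with random sign, and an amplitude 2^a_g; the mean curve is

        mean_ng = 2^{a_g} * sigmoid(k_ng (z_n - t0_g)),

    with k_ng = k_g * x_n for interaction genes (the covariate reverses the
    direction of regulation, splitting the trajectory into two limbs) and
    k_ng = k_g otherwise.  Counts are negative binomial around mean_ng with
    dispersion 0.1 (low noise) or 1.0 (high noise), variance
    mean + dispersion * mean^2, drawn as a Gamma-Poisson mixture.

    Returns raw counts; feed them through :func:`to_log1p` before fitting.
    """
    _check_fraction(fraction_interacting)
    if noise_regime not in NB_DISPERSION:
        raise ConfigError(f"noise_regime must be one of {sorted(NB_DISPERSION)}, got {noise_regime!r}")
    phi = NB_DISPERSION[noise_regime] if dispersion is None else float(dispersion)
    if not phi > 0:
        raise ConfigError("dispersion must be > 0")
    rng = np.random.default_rng(seed)
    N, G = n_samples, n_genes

    z = rng.uniform(0.0, 1.0, size=N)
    x = rng.choice((-1.0, 1.0), size=N)
    t0 = rng.uniform(*t0_range, size=G)
    k_abs = rng.uniform(*slope_range, size=G)
    k_sign = rng.choice((-1.0, 1.0), size=G)
    k_gene = k_abs * k_sign
    amplitude = 2.0 ** rng.uniform(*log2_amplitude_range, size=G)
    interacting = _interaction_mask(G, fraction_interacting, rng)

    slope = np.where(interacting[None, :], x[:, None] * k_gene[None, :], k_gene[None, :])
    mean = amplitude[None, :] * expit(slope * (z[:, None] - t0[None, :]))

    # Gamma-Poisson mixture == NB with var = mean + phi * mean^2
    shape = 1.0 / phi
    lam = rng.gamma(shape, scale=mean * phi)
    counts = rng.poisson(lam).astype(float)

    regime = np.where(interacting, "dynamic_interacting", "dynamic_common")
    truth = SimulationTruth(
        z_true=z,
        x=x[:, None],
        gene_regime=regime.astype(object),
        interaction_flags=interacting,
        true_params={"t0": t0, "k": k_gene, "amplitude": amplitude, "dispersion": phi},
        seed=seed,
    )
    expr = ExpressionMatrix(counts)
    cov = CovariateMatrix(x[:, None])
    return expr, cov, truth


def to_log1p(counts: ExpressionMatrix) -> ExpressionMatrix:
    """log(1 + count) view of a count matrix, ready for centring and fitting."""
    return ExpressionMatrix(
        np.log1p(counts.values),
        sample_ids=counts.sample_ids,
        gene_ids=counts.gene_ids,
    )


# ---------------------------------------------------------------------------
# benchmark grid

@dataclass(frozen=True)
class GridCell:
    """One benchmark condition with its reproducible derived seed."""

    index: int
    fraction: float
    n_samples: int
    noise_regime: str
    replicate: int
    seed: int


@dataclass
class SimGridSpec:
    """Factorial benchmark design.

    Defaults reproduce the 6 fractions x 2 sample sizes x 2 noise regimes
    x 40 replicates = 960-dataset design.
    """

    interaction_fractions: tuple = DEFAULT_FRACTIONS
    sample_sizes: tuple = (200, 500)
    noise_regimes: tuple = ("high", "low")
    replicates: int = 40
    base_seed: int = 0
    n_genes: int = 200

    def __post_init__(self):
        if not self.interaction_fractions or not self.sample_sizes or not self.noise_regimes:
            raise ConfigError("grid factor lists must be non-empty")
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")

    @property
    def size(self) -> int:
        return (
            len(self.interaction_fractions)
            * len(self.sample_sizes)
            * len(self.noise_regimes)
            * self.replicates
        )


def enumerate_grid(spec: SimGridSpec) -> list[GridCell]:
    """Expand a grid spec into one descriptor per dataset.

    Seeds are derived counter-style: ``SeedSequence(base_seed)`` yields one
    offset word and cell i gets ``(offset + i) mod 2^31``, so any single
    cell is reproducible in isolation from (base_seed, index) and seeds are
    pairwise distinct by construction for any grid smaller than 2^31 cells.
    """
    offset = int(np.random.SeedSequence(spec.base_seed).generate_state(1)[0]) % (2**31)
    seeds = (offset + np.arange(spec.size)) % (2**31)
    cells = []
    idx = 0
    for fraction in spec.interaction_fractions:
        for n in spec.sample_sizes:
            for regime in spec.noise_regimes:
                for rep in range(spec.replicates):
                    cells.append(
                        GridCell(
                            index=idx,
                            fraction=float(fraction),
                            n_samples=int(n),
                            noise_regime=str(regime),
                            replicate=rep,
                            seed=int(seeds[idx]),
                        )
                    )
                    idx += 1
    return cells
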