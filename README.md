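# covtraj

Covariate-modulated pseudotime trajectory inference for bulk and single-cell
expression data.

## The problem

Trajectory (pseudotime) methods order samples along a latent axis of
biological progression — differentiation, immune activation, tumour
development — from a snapshot expression matrix.  Standard methods ignore
what else is known about each sample: the stimulant a cell received, a
tumour's receptor or microsatellite status.  When such a covariate *changes
how genes behave along the trajectory*, ignoring it both degrades the
inferred ordering and hides the genes whose temporal behaviour depends on
the covariate — often the biologically interesting ones.

`covtraj` fits a Bayesian hybrid of factor analysis and linear regression in
which each gene `g` of a column-centred `N × G` matrix `Y` follows

```
y_ng = μ_g + Σ_p α_pg x_np + (λ_g + Σ_p β_pg x_np) z_n + ε_ng,   ε_ng ~ N(0, τ_g⁻¹)
```

with latent pseudotime `z_n ~ N(q_n, τ_q⁻¹)`, gene intercepts `μ_g`, static
covariate effects `α_pg`, pseudotime loadings `λ_g`, and
covariate–pseudotime **interactions** `β_pg ~ N(0, χ_pg⁻¹)` under a sparse
ARD-style prior (`χ_pg ~ Gamma(a_β, b_β)`) that lets covariates bend
trajectories only where the data demand it.  Setting `P = 0` recovers
one-factor Bayesian factor analysis; clamping `z = 0` recovers gene-wise
Bayesian regression — standard models are nested special cases.

Inference is coordinate-ascent mean-field variational Bayes: every update is
a closed-form conjugate optimum, the evidence lower bound (ELBO) increases
monotonically, and thousands of genes and samples fit in seconds.  An
interaction is called significant when zero lies more than `k` posterior
standard deviations from the posterior mean, `|m_β|/s_β > k` (default
`k = 3`), and for a binary covariate coded `{−1, +1}` the two group
trajectories cross at the pseudotime `z* = −α_pg / β_pg`.

## Worked example

Simulate misspecified single-cell-like data — sigmoidal expression along a
uniform pseudotime, negative-binomial counts, 20% of genes reversing their
regulation direction with a binary covariate — then fit on log1p counts:

```python
import numpy as np, pandas as pd
from covtraj import CovariateTrajectoryModel, simulate_nonlinear_nb, to_log1p

counts, cov, truth = simulate_nonlinear_nb(
    n_samples=200, n_genes=100, fraction_interacting=0.2,
    noise_regime="low", seed=42,
)
expr = pd.DataFrame(to_log1p(counts).values,
                    columns=[f"gene_{i}" for i in range(100)])
covdf = pd.DataFrame({"status": np.where(cov.values[:, 0] > 0,
                                         "mutant", "wildtype")})

model = CovariateTrajectoryModel.from_dataframe(expr, covdf)
res = model.fit(seed=0)
print(res.summary(top=3))
```

```
Covariate-modulated pseudotime trajectory fit
=====================================================
Samples:            200
Genes:              100
Covariates:         1
Converged:          True  (5 sweeps)
Final ELBO:         -18043.1577
Pseudotime range:   [-0.392, 0.423]
Significant interactions (k=3): 20 / 100
-----------------------------------------------------
covariate    gene  beta_mean  beta_sd  z_score  significant
   status gene_58     4.8049   0.1384  34.7155         True
   status gene_80    -4.6351   0.1482  31.2734         True
   status gene_51     4.1158   0.1885  21.8369         True
```

The rule `|m_β|/s_β > 3` flags exactly the 20 simulated interaction genes.
`gene_58`'s mutant and wildtype trajectories intersect near the middle of
the fitted pseudotime range (`res.crossover_point("gene_58", "status")`
returns `0.013`), and the fitted ordering matches the simulated truth with
sign-aligned Kendall τ = 0.941 despite the entirely non-Gaussian generative
process.

A command-line interface mirrors the library
(`covtraj simulate|fit|rank|benchmark|evaluate`), writing TSV interaction
tables, a JSON fit container and provenance sidecars; see `covtraj --help`.

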