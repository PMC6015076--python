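import numpy as np
import pytest

from covtraj import CovariateMatrix, ExpressionMatrix, Hyperparameters, initialize_state
from covtraj.containers import validate_and_center


def make_problem(seed, n, g, p, hyper=None):
    """A centred random dataset with a randomised (valid) variational state.

    The state is deliberately *not* at any coordinate optimum so that update
    tests exercise a generic point of the ELBO landscape.
    """
    rng = np.random.default_rng(seed)
    hyper = hyper or Hyperparameters()
    Y = rng.standard_normal((n, g)) + np.outer(rng.standard_normal(n), rng.standard_normal(g))
    X = rng.choice((-1.0, 1.0), (n, p)) if p else np.empty((n, 0))
    expr, cov = validate_and_center(ExpressionMatrix(Y), CovariateMatrix(X) if p else None)
    state = initialize_state(expr, cov, hyper, init="random", seed=seed)
    state.mu_mean = rng.standard_normal(g)
    state.lambda_mean = rng.standard_normal(g)
    state.alpha_mean = rng.standard_normal((p, g))
    state.beta_mean = rng.standard_normal((p, g))
    state.z_var = rng.uniform(0.5, 2.0, n)
    state.mu_var = rng.uniform(0.5, 2.0, g)
    state.lambda_var = rng.uniform(0.5, 2.0, g)
    state.alpha_var = rng.uniform(0.5, 2.0, (p, g))
    state.beta_var = rng.uniform(0.5, 2.0, (p, g))
    state.tau_shape = rng.uniform(1.0, 3.0, g)
    state.tau_rate = rng.uniform(1.0, 3.0, g)
    state.chi_shape = rng.uniform(0.5, 2.0, (p, g))
    state.chi_rate = rng.uniform(0.5, 2.0, (p, g))
    return expr, cov, hyper, state


@pytest.fixture
def problem_factory():
    return make_problem
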