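import numpy as np
import pytest

import hieropt as hp

CASCADE_SEED = 202
COMPARE_SEED = 3001
N_COMPARE_STARTS = 20


@pytest.fixture(scope="session")
def exp_decay():
    return hp.make_benchmark("exp_decay")


@pytest.fixture(scope="session")
def exp_decay_truth(exp_decay):
    return hp.generate_data(
        exp_decay.problem, exp_decay.theta_true, exp_decay.statics_true, seed=101
    )


@pytest.fixture(scope="session")
def cascade():
    return hp.make_benchmark("cascade3")


@pytest.fixture(scope="session")
def cascade_truth(cascade):
    return hp.generate_data(
        cascade.problem, cascade.theta_true, cascade.statics_true, seed=CASCADE_SEED
    )


@pytest.fixture(scope="session")
def cascade_compare(cascade_truth):
    """Paired 20-start standard-vs-hierarchical runs with a 150-iteration cap.

    Shared between the parameter-recovery and mode-comparison checks; solver
    tolerances are relaxed for the optimization loop (gradient-accuracy
    checks elsewhere use tight tolerances).
    """
    config = hp.OptimizerConfig(max_iter=150, rtol=1e-6, atol=1e-9)
    report, standard, hierarchical = hp.compare_modes(
        cascade_truth.problem, N_COMPARE_STARTS, COMPARE_SEED, config
    )
    return report, standard, hierarchical


def true_objective(benchmark, truth):
    """J(theta_true, statics_true) on the generated data."""
    statics = {k: {} for k in ("scaling", "offset", "noise")}
    for (kind, gid), value in benchmark.statics_true.items():
        statics[kind][gid] = value
    return hp.negative_log_likelihood(
        benchmark.theta_true_vector,
        statics["scaling"],
        statics["offset"],
        statics["noise"],
        truth.problem,
    ).value


def random_inner_group(rng, n=None, heteroscedastic=True):
    """One synthetic datapoint-sharing group for inner-solver checks."""
    n = n or rng.integers(3, 12)
    h = rng.uniform(0.2, 3.0, n)
    y = rng.normal(0.0, 2.0, n)
    sigma = rng.uniform(0.3, 2.0, n) if heteroscedastic else np.full(n, rng.uniform(0.3, 2.0))
    return h, y, sigma


def restricted_nll(h, y, s, b, sigma):
    """Eq.-style Gaussian negative log-likelihood restricted to one group
    (independent oracle formula, coded directly)."""
    h, y = np.asarray(h, float), np.asarray(y, float)
    s = np.broadcast_to(np.asarray(s, float), h.shape)
    b = np.broadcast_to(np.asarray(b, float), h.shape)
    sigma = np.broadcast_to(np.asarray(sigma, float), h.shape)
    r = y - (s * h + b)
    return float(
        0.5 * np.sum(np.log(2 * np.pi * sigma**2) + (r / sigma) ** 2)
    )
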