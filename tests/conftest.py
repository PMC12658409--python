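import numpy as np
import pytest

import gesturebias as gb


@pytest.fixture(scope="session")
def exp1_cohort():
    """Default preference-experiment cohort (160 per condition)."""
    return gb.simulate_exp1(seed=101)


@pytest.fixture(scope="session")
def matcher_cohort():
    """Pure probability-matching learning cohort with no participant
    heterogeneity: exactly the Monte-Carlo null model."""
    return gb.simulate_exp2_experiment(params=gb.matcher(sigma_u=0.0), seed=202)


@pytest.fixture(scope="session")
def mixture_cohort():
    """Default mixture-learner cohort (matchers, regularizers,
    conditioners)."""
    return gb.simulate_exp2_experiment(seed=303)


@pytest.fixture(scope="session")
def null_delta_h():
    return gb.simulate_null(statistic="delta_h", n_runs=10_000, seed=404)


@pytest.fixture(scope="session")
def null_delta_mi():
    return gb.simulate_null(statistic="delta_mi", n_runs=10_000, seed=505)


@pytest.fixture
def rng():
    return np.random.default_rng(606)
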