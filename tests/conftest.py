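import numpy as np
import pytest

from survstack import SimulationConfig, generate_cohort


def random_survival_data(rng, n=40, tie_prob=0.4, censor_prob=0.4):
    """Small random censored dataset with deliberate time and risk ties."""
    if rng.uniform() < tie_prob:
        times = rng.integers(1, max(n // 4, 2), size=n).astype(float)
    else:
        times = rng.exponential(scale=10.0, size=n)
    events = (rng.uniform(size=n) > censor_prob).astype(int)
    if rng.uniform() < tie_prob:
        risk = rng.integers(0, 5, size=n).astype(float)
    else:
        risk = rng.standard_normal(n)
    return risk, times, events


@pytest.fixture
def linear_cohort():
    """Moderate cohort with purely linear true risk and 30% censoring."""
    cfg = SimulationConfig(
        n_patients=1200,
        n_covariates=3,
        linear_effects=(1.0, -0.5, 0.0),
        censoring_rate_target=0.3,
        seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture
def nonlinear_cohort():
    """Cohort whose risk mixes linear, interaction and quadratic terms."""
    cfg = SimulationConfig(
        n_patients=1500,
        n_covariates=4,
        linear_effects=(0.5, -0.5, 0.3),
        interaction_effects=((0, 1, 1.0),),
        quadratic_effects=((2, 0.8),),
        censoring_rate_target=0.3,
        seed=23,
    )
    return generate_cohort(cfg)
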