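import numpy as np
import pytest

from crfdk import (
    CohortSpec,
    NRParams,
    StimulusProtocol,
    generate_cohort,
    simulate_experiment,
)


@pytest.fixture(scope="session")
def demo_params() -> NRParams:
    """Mid-range parameter set used across tests (steep curve, low baseline)."""
    return NRParams(r_max=15.0, c50=20.0, n=2.0, b=1.0)


@pytest.fixture(scope="session")
def small_cohort():
    """Four synthetic units at the reference protocol, reduced dimensions.

    Two directions keep generation fast; contrasts/trials/duration match the
    reference protocol so patterns up to {24, 50, 4.0} stay feasible.
    """
    spec = CohortSpec(n_units=4, directions=(0.0, 90.0), seed=7)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def noisy_spikes(demo_params):
    protocol = StimulusProtocol(
        contrasts=(0.0, 5.0, 10.0, 20.0, 40.0, 80.0, 100.0),
        trial_length=2.0,
        n_repetitions=10,
    )
    return simulate_experiment(demo_params, protocol, seed=11)
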