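import numpy as np
import pytest

from icnet.prep import AbundanceTable
from icnet.simulate import ObservationConfig, SimulationConfig, simulate_community

# canonical 2-species oscillatory Ricker system: moderate nonlinearity,
# strongly time-varying Jacobian, identifiable by local linear fits
RICKER_A = np.array([[2.5, 0.3], [0.4, 2.5]])


def make_ricker_truth(n_steps=200, noise_sd=0.01, seed=11):
    cfg = SimulationConfig(
        n_species=2,
        n_steps=n_steps,
        interaction_matrix=RICKER_A,
        growth_rates=np.array([2.5, 2.5]),
        process_noise_sd=noise_sd,
        temperature_sensitivity=np.zeros(2),
        seed=seed,
        initial_abundance=np.array([1.0, 1.1]),
    )
    return simulate_community(cfg)


@pytest.fixture(scope="session")
def ricker_truth():
    return make_ricker_truth()


@pytest.fixture(scope="session")
def five_species_truth():
    A = np.array(
        [
            [2.5, 0.3, 0.0, 0.0, 0.0],
            [0.4, 2.5, 0.0, 0.0, 0.0],
            [0.0, 0.3, 2.5, 0.0, 0.0],
            [0.0, 0.0, 0.0, 2.5, 0.35],
            [0.0, 0.0, 0.0, 0.0, 2.5],
        ]
    )
    cfg = SimulationConfig(
        n_species=5,
        n_steps=122,
        interaction_matrix=A,
        growth_rates=np.full(5, 2.5),
        process_noise_sd=0.02,
        temperature_sensitivity=np.zeros(5),
        seed=7,
        initial_abundance=np.ones(5),
        observation=ObservationConfig(sampling="expected"),
    )
    return simulate_community(cfg)


@pytest.fixture
def small_table():
    """3 taxa x 60 days x 1 plot with varied prevalence patterns."""
    rng = np.random.default_rng(5)
    vals = np.zeros((3, 60, 1))
    vals[0, :, 0] = rng.lognormal(1.0, 0.5, 60)          # always present
    vals[1, ::7, 0] = rng.lognormal(0.0, 0.3, 9)          # rare
    vals[2, :, 0] = 4.0                                   # constant positive
    return AbundanceTable(vals)
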