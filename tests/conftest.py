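import math

import pytest

from finitek import ClusterModel, SimulationSpec, metropolis_chain, sample_states


@pytest.fixture(scope="session")
def two_particle_model():
    """N=2, V=10 nm^3, b_2=2 nm^3, c_std=1: P(dimer)=1/6, K_2=1."""
    return ClusterModel(2, 10.0, [1.0, 2.0], c_std=1.0)


@pytest.fixture(scope="session")
def factorial_model_n4():
    """N=4, V=10, b_m=m!, c_std=1: every K_m = 1."""
    return ClusterModel(4, 10.0, [math.factorial(m) for m in range(1, 5)], c_std=1.0)


@pytest.fixture(scope="session")
def generic_model_n8():
    """N=8 with non-trivial b_m (not m!), generic c_std and volume."""
    b = [1.0] + [math.factorial(m) * 1.3**m / (1 + 0.1 * m) for m in range(2, 9)]
    return ClusterModel(8, 37.0, b, c_std=0.7)


@pytest.fixture(scope="session")
def sampled_series_n4(factorial_model_n4):
    return sample_states(factorial_model_n4, 200_000, seed=11)


@pytest.fixture(scope="session")
def lj_chain_n2_eps10():
    """Short production chain of the 2-particle LJ system at eps=10 kJ/mol."""
    spec = SimulationSpec(n_total=2, box_length=5.0, epsilon=10.0, seed=7)
    return spec, metropolis_chain(spec, 2_000_000, thin=5)
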