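import pytest

from rumenserial.simulate import SimulationParams, generate_experiment

KEY = ["incubation", "sequence", "substrate", "dilution_level", "transfer"]


@pytest.fixture(scope="session")
def noiseless_bundle():
    """Full synthetic experiment with noise and air contamination off."""
    return generate_experiment(SimulationParams(rng_seed=1).noiseless())


@pytest.fixture(scope="session")
def noisy_bundle():
    """Full synthetic experiment with the default noise model."""
    return generate_experiment(SimulationParams(rng_seed=2))
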