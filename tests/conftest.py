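import numpy as np
import pytest

from cfmarrow import synthetic as syn


@pytest.fixture(scope="session")
def noiseless_config() -> syn.SimulationConfig:
    """Study-scale noiseless configuration: 1000 genes, 6 cell types, 30 markers each."""
    return syn.SimulationConfig(noise_model="none", seed=0)


@pytest.fixture(scope="session")
def reference_and_truth(noiseless_config):
    return syn.generate_reference(noiseless_config)


@pytest.fixture(scope="session")
def mixture_set(reference_and_truth, noiseless_config):
    """24 noiseless samples at Dirichlet-drawn known proportions."""
    reference, _ = reference_and_truth
    rng = np.random.default_rng(42)
    proportions = rng.dirichlet(np.ones(noiseless_config.n_celltypes), size=24)
    return syn.generate_mixture(reference, proportions, noiseless_config)
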