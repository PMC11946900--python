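import numpy as np
import pytest

from tumorevo.simulate import SimulationConfig, simulate_tumor


@pytest.fixture(scope="session")
def clonal_wgd_tumor():
    """One simulated tumor with a truncal (clonal) WGD in every region."""
    config = SimulationConfig(
        seed=11, n_mutations=600, wgd_probability=1.0,
        subclonal_wgd_probability=0.0, second_wgd_probability=0.0,
        purity_range=(0.5, 0.8), mean_depth=400.0)
    return config, simulate_tumor(config)


@pytest.fixture(scope="session")
def no_wgd_tumor():
    config = SimulationConfig(seed=5, n_mutations=200, wgd_probability=0.0,
                              fraction_pre_wgd=0.0)
    return config, simulate_tumor(config)
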