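import pytest

from citemux.config import PipelineConfig, Seeds
from citemux.pipeline import run_all
from citemux.simulate import SynthConfig, simulate_experiment


@pytest.fixture(scope="session")
def small_exp():
    """A 4k-droplet default-design experiment shared across module tests."""
    return simulate_experiment(SynthConfig(seed=11, n_droplets=4000))


@pytest.fixture(scope="session")
def pipe_config():
    return PipelineConfig(seeds=Seeds.from_base(11))


@pytest.fixture(scope="session")
def small_result(small_exp, pipe_config):
    return run_all(small_exp, config=pipe_config)
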