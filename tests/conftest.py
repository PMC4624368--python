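import pytest

from seqsimnet import PipelineConfig, run_pipeline
from seqsimnet.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The default planted dataset: one passing family with environmental
    clades and fragments, one failing (cross-connected) family."""
    return simulate_dataset(SimConfig(rng_seed=1))


@pytest.fixture(scope="session")
def default_result(default_dataset):
    """Full pipeline run on the default dataset (in memory)."""
    return run_pipeline(default_dataset.proteins, PipelineConfig(),
                        cds=default_dataset.cds)
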