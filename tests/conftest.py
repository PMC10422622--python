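import numpy as np
import pytest
from hypothesis import settings

from mudring_ecg import evaluation

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def pipeline_artifacts():
    """One full default-config end-to-end run, shared across tests.

    Scaled-down study conditions: 600 records (6 NULL), five balanced
    diagnostic classes, tuning budget 6 agents x 5 iterations.
    """
    cfg = evaluation.PipelineConfig(seed=7)
    return evaluation.run_pipeline(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
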