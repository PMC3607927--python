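import numpy as np
import pytest

from endoquant import synthetic as syn
from endoquant.pipeline import RunConfig, run_imaging_pipeline


@pytest.fixture(scope="session")
def small_run_config():
    return RunConfig(fields_per_timepoint=2, cells_per_field=4, master_seed=1)


@pytest.fixture(scope="session")
def small_imaging_results(small_run_config):
    """One small simulated two-ligand experiment, analyzed end to end."""
    return run_imaging_pipeline(small_run_config)


@pytest.fixture(scope="session")
def event_dataset():
    """Default simulated cytometry dataset (tables by time, control, truth)."""
    return syn.generate_event_dataset(syn.EventSimConfig(), seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
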