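import numpy as np
import pytest

from cbsnn import (NetworkConfig, ScheduleConfig, synth_clusters,
                   train_test_split)
from cbsnn.lif_core import NeuronParams


@pytest.fixture(scope="session")
def small_task():
    """Tiny 3-class cluster task for fast integration tests."""
    ds = synth_clusters(n_classes=3, n_per_class=40, dims=4,
                        separation=6.0, overlap_fraction=0.2, seed=7)
    return train_test_split(ds, 0.25, seed=7)


@pytest.fixture
def small_config():
    """Reduced window and width so per-test training stays fast."""
    return NetworkConfig(layer_sizes=(4, 16, 3), T=30, seed=3)


@pytest.fixture
def default_neuron():
    return NeuronParams()


@pytest.fixture
def short_schedule():
    return ScheduleConfig(n_epochs=6)
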