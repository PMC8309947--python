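import numpy as np
import pytest

import snncluster as sc

#: desk-scale grid that still resolves all 26 electrodes to distinct neurons
SMALL_GRID = (7, 7, 6)


@pytest.fixture(scope="session")
def small_dataset() -> sc.SampleSet:
    return sc.generate_dataset(n_per_class=4, planted=(10, 12, 21), effect=2.0, seed=7)


@pytest.fixture(scope="session")
def trained(small_dataset):
    """A small trained reservoir with recording, shared across tests."""
    rasters = sc.encode_samples(small_dataset)
    model = sc.init_reservoir(SMALL_GRID, seed=7)
    log = sc.train_unsupervised(model, rasters, snapshot_every=25, record=True)
    return model, log, rasters, small_dataset
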