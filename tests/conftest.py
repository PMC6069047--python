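import numpy as np
import pytest

import cecganc as c


@pytest.fixture(scope="session")
def clean_record():
    """Noise-free 30-s record with ground truth."""
    params = c.preset_params("clean", duration_s=30.0, seed=3)
    record, truth = c.generate_record(params)
    return record, truth


@pytest.fixture(scope="session")
def moderate_record():
    """Moderate-noise 60-s record with ground truth."""
    params = c.preset_params("moderate", duration_s=60.0, seed=3)
    record, truth = c.generate_record(params)
    return record, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
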