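import numpy as np
import pytest

from ppgnet import preprocess, synth


@pytest.fixture(scope="session")
def bandpass_kernel():
    """Default equiripple bandpass, designed once per session."""
    return preprocess.design_remez_bandpass(preprocess.FilterSpec())


@pytest.fixture(scope="session")
def small_cohort():
    """20-subject balanced cohort shared by split/pipeline tests."""
    cfg = synth.desk_scale_config(seed=123, n_subjects=20)
    manifest, records = synth.generate_cohort(cfg)
    return cfg, manifest, records


@pytest.fixture
def rng():
    return np.random.default_rng(20240)
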