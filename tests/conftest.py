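import numpy as np
import pytest

from emocat import synthetic


@pytest.fixture(scope="session")
def ans_events_4clusters():
    cfg = synthetic.AnsGeneratorConfig.well_separated(n_clusters=4, n_events=200, seed=7)
    return synthetic.generate_ans_events(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
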