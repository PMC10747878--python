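import numpy as np
import pytest

import connectofuse as cf
from connectofuse import PipelineConfig


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small strong-effect cohort shared across tests (24 subjects, 10 ROIs)."""
    return cf.make_cohort(
        n_asd=12, n_tc=12, n_roi=10, n_timepoints=60,
        n_signal_edges=5, effect_size=0.6, seed=7,
    )


@pytest.fixture()
def fast_config():
    """Pipeline config scaled down for quick smoke runs."""
    cfg = PipelineConfig()
    cfg.train.epochs = 5
    cfg.train.batch_size = 16
    cfg.selection.n_keep = 10
    cfg.selection.step_fraction = 0.3
    return cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
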