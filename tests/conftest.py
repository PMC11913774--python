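import warnings

import numpy as np
import pytest

from cardiosync.synthetic import CouplingConfig, generate_dyad_ibi


@pytest.fixture(autouse=True)
def _quiet():
    # statsmodels emits convergence/frequency warnings that are expected in
    # grid searches over deliberately mis-specified candidates
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def coupled_pair():
    """A strongly coupled 2-minute dyad at 4 Hz with known ground truth."""
    cfg = CouplingConfig(coupling_gain=1.5, block_duration_s=120.0, seed=42)
    return generate_dyad_ibi(cfg)


@pytest.fixture
def uncoupled_pair():
    cfg = CouplingConfig(coupling_gain=0.0, block_duration_s=120.0, seed=43)
    return generate_dyad_ibi(cfg)
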