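import numpy as np
import pytest

from ambicode.codes import BUILTIN_CODES
from ambicode.simulate import SimConfig, simulate_transcriptome


@pytest.fixture(scope="session")
def standard_code():
    return BUILTIN_CODES["standard"]


@pytest.fixture(scope="session")
def ambiguous_code():
    return BUILTIN_CODES["ambiguous-cmag"]


@pytest.fixture(scope="session")
def small_cohort():
    """A small ambiguous-code cohort shared by read-only tests."""
    cfg = SimConfig(seed=11, n_transcripts=200, code="ambiguous-cmag")
    transcripts, truth = simulate_transcriptome(cfg)
    return cfg, transcripts, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
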