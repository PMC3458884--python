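import numpy as np
import pytest

from _helpers import make_alignment


@pytest.fixture
def aln_factory():
    return make_alignment


@pytest.fixture
def rng():
    return np.random.default_rng(20120730)
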