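import numpy as np
import pytest

from qmrinet.sequence import (
    IsochromatEnsemble,
    SequenceConfig,
    TissueParams,
    make_flip_schedule,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def short_seq():
    """A 100-excitation sequence: fast, still T1/T2-sensitive."""
    return SequenceConfig(flip_schedule=make_flip_schedule({"kind": "sinusoidal", "length": 100}))


@pytest.fixture(scope="session")
def wm_tissue():
    return TissueParams(t1=1.0, t2=0.08)


@pytest.fixture(scope="session")
def uniform_ensemble():
    """Ideal-spoiling ensemble: uniform 2*pi dephasing, no slice profile."""
    return IsochromatEnsemble.uniform_dephasing(256)
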