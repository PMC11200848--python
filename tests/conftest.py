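import numpy as np
import pytest

from mcomeda import Signal, SynthConfig, generate_eda, preprocess


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def eda_signal():
    """A 120-s synthetic EDA recording at 5 Hz."""
    return generate_eda(SynthConfig(seed=7))


@pytest.fixture
def clean_signal(eda_signal):
    """The z-scored noiseless version of ``eda_signal``."""
    return preprocess(eda_signal)


@pytest.fixture
def short_series(rng):
    """A 60-sample noisy series for brute-force oracle comparisons."""
    return rng.normal(size=60)


@pytest.fixture
def make_signal():
    def _make(values, fs=5.0):
        return Signal(values=np.asarray(values, dtype=float), fs=fs)

    return _make
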