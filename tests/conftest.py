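import numpy as np
import pytest

from ramantdm.core_io import SampleMeta, Spectrum
from ramantdm.synthetic_urine import SyntheticConfig


@pytest.fixture
def grid():
    return np.arange(600.0, 1901.0)


@pytest.fixture
def meta():
    return SampleMeta(sample_id="s1", sex="female", replicate=1)


@pytest.fixture
def make_spectrum(grid, meta):
    def _make(intensities, **meta_kwargs):
        m = meta if not meta_kwargs else SampleMeta(**{"sample_id": "s1", **meta_kwargs})
        return Spectrum(grid.copy(), np.asarray(intensities, float), m)

    return _make


@pytest.fixture
def quiet_config():
    """Generator config with every stochastic term switched off."""
    return SyntheticConfig(
        noise_sd=0.0,
        scatter_gain_sd=0.0,
        scatter_offset_sd=0.0,
        aliquot_cv=0.0,
        composition_cv=0.0,
        seed=123,
    )


@pytest.fixture
def default_config():
    return SyntheticConfig(seed=123)
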