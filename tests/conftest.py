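import pytest

from criticaldyn import epileptor as ep
from criticaldyn import synthetic as syn


@pytest.fixture(scope="session")
def params():
    return ep.EpileptorParams()


@pytest.fixture(scope="session")
def fixed_point(params):
    return ep.find_fixed_point(params)


@pytest.fixture(scope="session")
def small_session():
    """Short parametric session: 12 trials at 500 Hz, tight ISI."""
    cfg = syn.SyntheticConfig(sampling_rate_hz=500.0, seed=7,
                              isi_range_s=(2.0, 3.0))
    return syn.generate_session(cfg, n_stimulations=12)


@pytest.fixture(scope="session")
def labelled_dataset():
    """Balanced 3-condition dataset small enough for repeated CV fits."""
    cfg = syn.SyntheticConfig(sampling_rate_hz=500.0, isi_range_s=(2.0, 3.0))
    return syn.generate_labelled_dataset(5, cfg, seed=11, n_stimulations=8)
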