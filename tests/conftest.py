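import numpy as np
import pytest

import loglira as ll


@pytest.fixture(scope="session")
def fs():
    return 20_000.0


@pytest.fixture()
def cfg():
    return ll.LogLiraConfig(seed=0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def noise_recording(fs):
    """Two seconds of band-limited noise with a 10-stimulus train."""
    from loglira.synthetic import band_limited_noise
    r = np.random.default_rng(7)
    sig = band_limited_noise(int(2 * fs), fs, 4.0, r)
    onsets = np.arange(10) * int(0.18 * fs) + int(0.05 * fs)
    return ll.Recording(sig, fs), ll.StimTrain(onsets)


@pytest.fixture(scope="session")
def small_dictionary(fs):
    """A synthetic template dictionary with a heavy-tailed onset train."""
    tpl = ll.gen_templates(ll.SyntheticTemplateSpec(seed=3), fs)
    src = ll.gen_stim_onsets(10.0, 60.0, fs, seed=2, sigma=0.8)
    return ll.TemplateDictionary("fix", tpl, src.onsets, fs)
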