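import pytest

from tonguevcp import FrequencySweep, build_default_array


@pytest.fixture(scope="session")
def default_array():
    return build_default_array()


@pytest.fixture(scope="session")
def sweep():
    return FrequencySweep()
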