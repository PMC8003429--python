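import pytest

from wlharm import default_italian_profile, default_parameter_ranges


@pytest.fixture(scope="session")
def italian_profile():
    return default_italian_profile()


@pytest.fixture(scope="session")
def italian_ranges():
    return default_parameter_ranges()
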