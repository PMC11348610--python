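import pytest

from sptcca import base_case_inputs


@pytest.fixture(scope="session")
def base_inputs():
    return base_case_inputs()


@pytest.fixture(scope="session")
def base_values(base_inputs):
    return base_inputs.values()
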