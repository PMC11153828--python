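import pytest

from hedline import synth


@pytest.fixture(scope="session")
def mini_schema():
    return synth.mini_schema()


@pytest.fixture(scope="session")
def sart_schema():
    return synth.sart_schema()
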