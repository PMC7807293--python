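import pytest

from prtcea import load_default


@pytest.fixture
def base():
    """Fresh base-case (parameters, settings) per test; both are mutable."""
    return load_default()


@pytest.fixture
def params(base):
    return base[0]


@pytest.fixture
def settings(base):
    return base[1]
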