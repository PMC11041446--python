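import pytest

from anthroagree import synthetic_reference


@pytest.fixture(scope="session")
def ref():
    """Shared synthetic LMS reference (expensive enough to build once)."""
    return synthetic_reference()
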