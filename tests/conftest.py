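import pytest

from fhprs.panel import load_panel


@pytest.fixture(scope="session")
def panel():
    """The packaged 12-SNP score panel."""
    return load_panel()
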