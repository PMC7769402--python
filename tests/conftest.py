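import pytest
from hypothesis import settings

from mkrbe import nci_h460_6mv

settings.register_profile("repeatable", derandomize=True)
settings.load_profile("repeatable")


@pytest.fixture(scope="session")
def bundle():
    """Packaged NCI-H460 / 6-MV photon parameter bundle."""
    return nci_h460_6mv()
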