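import pytest

from chemocomp.allometry import study_profiles


@pytest.fixture(scope="session")
def profiles():
    return study_profiles()
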