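import pytest

from rrmeta import load_fixture


@pytest.fixture(scope="session")
def diuretics():
    """Nine pre-eclampsia prevention trials (benefit outcome, RR < 1)."""
    return load_fixture("diuretics")


@pytest.fixture(scope="session")
def tca():
    """Sixteen antidepressant side-effect trials (harm outcome, RR > 1)."""
    return load_fixture("tca")
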