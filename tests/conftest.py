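import pytest

from kleptocarbon import Treatment


@pytest.fixture
def treatment() -> Treatment:
    """Default mid-light treatment with the study's conversion constants."""
    return Treatment(treatment_id="I40", irradiance=40.0, prey_target=4e4)
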