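import pytest

from proteocost.model import ModelConfig
from proteocost.synth import generate_workbook


@pytest.fixture(scope="session")
def config():
    return ModelConfig()


@pytest.fixture(scope="session")
def workbook(config):
    """Calibrated synthetic workbook under the base-case configuration."""
    return generate_workbook(seed=1, config=config)
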