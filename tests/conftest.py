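import pytest
from hypothesis import settings

from fermkin import BatchFermentationModel

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_model() -> BatchFermentationModel:
    return BatchFermentationModel()


@pytest.fixture(scope="session")
def calibrated_model() -> BatchFermentationModel:
    return BatchFermentationModel.calibrated()
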