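import numpy as np
import pytest

from fmloop import EndocrineParams, SteroidMapParams, ThalamoParams


@pytest.fixture(scope="session")
def thalamo_defaults() -> ThalamoParams:
    return ThalamoParams()


@pytest.fixture(scope="session")
def steroid_defaults() -> SteroidMapParams:
    return SteroidMapParams()


@pytest.fixture(scope="session")
def endocrine_defaults() -> EndocrineParams:
    return EndocrineParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240613)
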