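import logging

import pytest

from primetime_br import FixtureConfig, Pipeline, make_fixture, make_null_fixture

logging.getLogger("primetime_br").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def bundle():
    return make_fixture(FixtureConfig(seed=1))


@pytest.fixture(scope="session")
def pipeline(bundle):
    return Pipeline(bundle)


@pytest.fixture(scope="session")
def null_pipeline():
    return Pipeline(make_null_fixture(FixtureConfig(seed=1)))
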