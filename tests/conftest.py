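import pytest
from hypothesis import settings

from depmon.config import RunConfig, build_profiles

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

SEED = 1234


@pytest.fixture(scope="session")
def run_config() -> RunConfig:
    return RunConfig(seed=SEED)


@pytest.fixture(scope="session")
def profiles(run_config):
    return build_profiles(run_config)


@pytest.fixture(scope="session")
def lines(run_config):
    return run_config.treatment_lines()


@pytest.fixture(scope="session")
def params(run_config):
    return run_config.model_params()


@pytest.fixture(scope="session")
def econ(run_config):
    return run_config.economic_params()


@pytest.fixture(scope="session")
def options(run_config):
    return run_config.engine_options()


@pytest.fixture(scope="session")
def strategies(run_config):
    return run_config.strategy_presets()
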