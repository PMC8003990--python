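import pytest

from lncpod import synthetic_fixtures as fx
from lncpod.pipeline import fixture_config, run_pipeline

FIXTURE_SEED = 1


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle")
    fx.generate(fx.FixtureConfig(seed=FIXTURE_SEED), str(out))
    return str(out)


@pytest.fixture(scope="session")
def manifest(fixture_dir):
    import os

    return fx.FixtureManifest.load(os.path.join(fixture_dir, "manifest.json"))


@pytest.fixture(scope="session")
def pipeline_result(fixture_dir):
    return run_pipeline(fixture_config(fixture_dir))
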