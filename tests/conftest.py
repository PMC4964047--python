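import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def fixture_dataset(tmp_path_factory):
    """The synthetic planted-truth dataset, generated once per session."""
    from balnoise.fixtures import write_fixtures

    out = tmp_path_factory.mktemp("dataset")
    manifest = write_fixtures(str(out))
    return str(out), manifest


@pytest.fixture(scope="session")
def pipeline_results(fixture_dataset, tmp_path_factory):
    from balnoise.workflow import run_pipeline

    data_dir, manifest = fixture_dataset
    out = tmp_path_factory.mktemp("results")
    res = run_pipeline(data_dir, out_dir=str(out))
    return res, manifest, str(out), data_dir
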