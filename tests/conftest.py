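import pytest
from hypothesis import HealthCheck, settings

from famseg.pipeline import run_all
from famseg.synthdata import generate_scenario, paper_scenario_config

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def paper_bundle(tmp_path_factory):
    """The packaged four-family scenario (seed 42) plus its ground truth."""
    out = tmp_path_factory.mktemp("bundle")
    config = paper_scenario_config(seed=42)
    files, truth = generate_scenario(config, out)
    return out, files, truth


@pytest.fixture(scope="session")
def paper_run(paper_bundle, tmp_path_factory):
    """Full pipeline output on the packaged scenario."""
    bundle_dir, _files, _truth = paper_bundle
    out = tmp_path_factory.mktemp("run")
    report, summary = run_all(bundle_dir / "run.yaml", out)
    return report, summary, out
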