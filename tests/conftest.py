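import json
from pathlib import Path

import pytest

from moni.fixtures import FixtureConfig, generate_bundle
from moni.pipeline import RunConfig, run_pipeline


@pytest.fixture(scope="session")
def noise_free_bundle(tmp_path_factory):
    """Full-scale noise-free synthetic bundle (200 TFs, 50 background
    samples, seed 1) shared by end-to-end tests."""
    out = tmp_path_factory.mktemp("bundle") / "noise_free"
    truth = generate_bundle(out, FixtureConfig(), seed=1)
    return out, truth


@pytest.fixture(scope="session")
def noise_free_run(noise_free_bundle):
    """The reconstructed network and metrics for the noise-free bundle."""
    out, truth = noise_free_bundle
    grn = run_pipeline(RunConfig.from_yaml(out / "config.yaml"))
    metrics = json.loads((out / "results" / "metrics.json").read_text())
    return grn, metrics, truth


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A smaller bundle for tests that re-run the pipeline with variations."""
    out = tmp_path_factory.mktemp("bundle") / "small"
    cfg = FixtureConfig(n_tfs=60, n_other_genes=30, n_background=30)
    truth = generate_bundle(out, cfg, seed=11)
    return out, truth
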