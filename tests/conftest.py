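import numpy as np
import pytest

from proteomelt.pipeline import PipelineConfig, run_tpp_pipeline
from proteomelt.synthetic import TppSimConfig, simulate_tpp_experiment
from proteomelt.types import TemperatureGrid


@pytest.fixture(scope="session")
def grid():
    return TemperatureGrid.default()


@pytest.fixture(scope="session")
def small_tpp():
    """Small simulated TPP experiment shared by clustering/pipeline tests."""
    cfg = TppSimConfig(n_genes=30)
    records, truth = simulate_tpp_experiment(cfg, seed=7)
    return cfg, records, truth


@pytest.fixture(scope="session")
def tpp_run(tmp_path_factory):
    """One full TPP pipeline run on a 25-gene experiment."""
    out = tmp_path_factory.mktemp("tpp_run")
    cfg = PipelineConfig(out_dir=str(out), seed=5)
    cfg.tpp_sim = TppSimConfig(n_genes=25)
    results = run_tpp_pipeline(cfg)
    return cfg, results
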