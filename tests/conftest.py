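import numpy as np
import pytest

from ciliareg import pipeline
from ciliareg.simulate import SimulationConfig, generate_genome


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_genes=120, n_targets=20, n_indirect=10, seed=123)


@pytest.fixture(scope="session")
def small_genome(small_config):
    return generate_genome(small_config)


@pytest.fixture(scope="session")
def small_workspace(tmp_path_factory):
    """A complete small pipeline run shared by integration-level tests."""
    ws = tmp_path_factory.mktemp("ws")
    cfg = pipeline.load_config(seed=77)
    cfg["simulate"] = {"n_genes": 300, "n_targets": 40, "n_indirect": 20}
    cfg["motifs"]["n_restarts"] = 3
    pipeline.run_all(ws, cfg)
    return ws, cfg
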