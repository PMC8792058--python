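import numpy as np
import pytest

from finerange.grid import RasterGrid
from finerange.orchestrator import PipelineConfig, run_pipeline
from finerange.synthetic_landscape import LandscapeConfig


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def grid_from(array, cell_m=50.0):
    return RasterGrid(np.asarray(array, float), cell_m)


@pytest.fixture(scope="session")
def demo_result():
    """One full default-demo pipeline run shared by the end-to-end tests."""
    cfg = PipelineConfig(landscape=LandscapeConfig(seed=1), seed=1)
    return run_pipeline(cfg)
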