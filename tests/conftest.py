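import numpy as np
import pytest

from reefconnect.core_grids import BathymetryGrid
from reefconnect.pipeline import demo_config, run_pipeline


@pytest.fixture(scope="session")
def demo_result():
    """One full end-to-end run of the reduced two-lagoon study.

    Shared across the suite: the flow solve plus ~10^5 tracked particles
    take a few minutes, and every emergent-behaviour check (sticky water,
    residence times, retention contrast, model-vs-field comparison) reads
    from the same run.
    """
    return run_pipeline(demo_config(seed=1))


@pytest.fixture()
def flat_grid():
    """Small flat open-water grid (30 x 30 cells, 50 m deep)."""
    depth = np.full((30, 30), 50.0)
    return BathymetryGrid(depth=depth, land_mask=np.zeros((30, 30), bool),
                          dx=500.0)
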