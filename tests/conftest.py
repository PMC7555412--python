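import numpy as np
import pytest

from mgmorph.config import PipelineConfig


@pytest.fixture
def cfg() -> PipelineConfig:
    return PipelineConfig(seed=0)


@pytest.fixture
def small_forest_cfg() -> PipelineConfig:
    """Default parameters but a lighter ensemble, for fast unit tests."""
    return PipelineConfig(seed=0, n_trees=101)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
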