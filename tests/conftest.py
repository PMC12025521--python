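import dataclasses

import numpy as np
import pytest

from sonoquant import synth
from sonoquant.cli import PipelineConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def abdomen_phantom():
    """One seeded abdominal phantom at default speckle."""
    return synth.generate_phantom(synth.default_abdomen_spec(seed=5))


@pytest.fixture(scope="session")
def leg_transverse_phantom():
    return synth.generate_phantom(synth.default_leg_spec(seed=7))


@pytest.fixture(scope="session")
def noiseless_abdomen():
    spec = dataclasses.replace(synth.default_abdomen_spec(seed=0), speckle_sigma=0.0)
    return synth.generate_phantom(spec)


@pytest.fixture(scope="session")
def abdomen_templates():
    """Cross-seed template library for the default abdominal geometry."""
    img, truth = synth.generate_phantom(synth.default_abdomen_spec(seed=999))
    return synth.extract_templates(img, truth)


@pytest.fixture(scope="session")
def leg_transverse_templates():
    img, truth = synth.generate_phantom(synth.default_leg_spec(seed=999))
    return synth.extract_templates(img, truth)


@pytest.fixture
def pipeline_config():
    return PipelineConfig(cm_per_px=0.01)
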