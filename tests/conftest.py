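import numpy as np
import pytest

from bundleseg.io import Section
from bundleseg.network import ModelConfig, build_model
from bundleseg.synthetic import SynthConfig, generate_section, generate_stack


@pytest.fixture(scope="session")
def tiny_synth_cfg() -> SynthConfig:
    """A small, fast synthetic world: 160 px sections at 100 um/px (16 mm wide)."""
    return SynthConfig(
        image_height_px=160,
        image_width_px=160,
        um_per_px=100.0,
        n_sections=3,
        n_bundles=2,
        drift_mm_per_section=0.5,
        seed=3,
    )


@pytest.fixture(scope="session")
def tiny_section(tiny_synth_cfg):
    return generate_section(tiny_synth_cfg, 0)


@pytest.fixture(scope="session")
def tiny_stack(tiny_synth_cfg):
    return generate_stack(tiny_synth_cfg)


@pytest.fixture(scope="session")
def tiny_model_cfg() -> ModelConfig:
    return ModelConfig(base_width=2, depth=2, fc_sizes=(8, 6))


@pytest.fixture()
def tiny_model(tiny_model_cfg):
    return build_model(tiny_model_cfg, seed=1)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture()
def flat_section() -> Section:
    """A constant mid-gray section for inference sanity checks."""
    img = np.full((96, 96, 3), 0.3, dtype=np.float32)
    return Section(image=img, um_per_px=10.0, section_index=0)
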