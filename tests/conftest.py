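import numpy as np
import pytest

import lightdermo as ld

# reduced-width configuration used wherever a full forward/backward pass is
# needed at desk scale; same topology as the canonical model, smaller widths
SMALL_CFG = ld.ModelConfig(
    stem_channels=8,
    stage_widths=(8, 16, 32, 64),
    stage_repeats=(1, 1, 1, 1),
    se_reduction=4,
    head_width=32,
    input_size=64,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_model():
    return ld.build_model(SMALL_CFG, seed=0)


@pytest.fixture(scope="session")
def tiny_manifest():
    """Seven classes, 12 images each, 32x32 — cheap end-to-end material."""
    return ld.make_fixture(
        {c: 12 for c in ld.CLASSES}, ld.SyntheticSpec(image_size=32, seed=42)
    )
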