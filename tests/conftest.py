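import numpy as np
import pytest

from adgnet.backbone import BackboneConfig
from adgnet.heads import DecoderConfig
from adgnet.phantoms import PhantomSpec, generate_dataset


@pytest.fixture(scope="session")
def tiny_backbone_cfg() -> BackboneConfig:
    """Smallest sensible 2D backbone: 32x32 input, narrow stages."""
    return BackboneConfig(
        dimensionality=2,
        stage_channels=(4, 8, 8, 8, 8),
        blocks_per_stage=(1, 1, 1, 1, 1),
        attention_reduction=4,
        input_channels=1,
        input_size=(32, 32),
    )


@pytest.fixture(scope="session")
def tiny_decoder_cfg() -> DecoderConfig:
    return DecoderConfig(M=5, base_size=1, base_channels=8, out_channels=1, dimensionality=2)


@pytest.fixture(scope="session")
def small_phantom_split():
    """32 two-class phantoms with the calibrated severity/noise, split 80/20."""
    spec = PhantomSpec(
        dimensionality=2, size=32, n_classes=2, counts_per_class=(16, 16), seed=3
    )
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
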