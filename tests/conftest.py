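import numpy as np
import pytest

from cpseg.preprocess import TilingPlan
from cpseg.synthdata import SynthConfig, generate_volume


@pytest.fixture(scope="session")
def small_synth():
    """Desk-scale synthetic volume shared by sampling/training tests:
    64 slices of 128x128 with sparse nucleoli (~0.3% foreground)."""
    cfg = SynthConfig(z=64, h=128, w=128, n_cells=2,
                      nucleus_radius_range=(28, 40),
                      nucleolus_radius_range=(4, 6),
                      nucleolus_fg_target=0.002, seed=3)
    image, nuclei, nucleoli = generate_volume(cfg)
    return cfg, image, nuclei, nucleoli


@pytest.fixture(scope="session")
def default_synth():
    """Default-scale synthetic volume (64 x 512 x 512, ~0.1% nucleolus
    foreground) — the regime where uniform crops are mostly empty."""
    cfg = SynthConfig()
    image, nuclei, nucleoli = generate_volume(cfg)
    return cfg, image, nuclei, nucleoli


@pytest.fixture()
def tiny_plan():
    """Crop geometry for desk-scale training: 64 px context windows
    downsampled to 32 px tiles."""
    return TilingPlan(context_size=64, out_size=32, stride=32)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
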