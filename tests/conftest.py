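import numpy as np
import pytest
from hypothesis import settings

from ciliashift.simulate import CiliaRegion, CiliaSimConfig, generate_cilia_stack

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")


@pytest.fixture
def square_region_mask():
    mask = np.zeros((64, 64), dtype=bool)
    mask[16:48, 16:48] = True
    return mask


@pytest.fixture
def beating_stack(square_region_mask):
    """256-frame 64x64 stack with a 22 Hz region at SNR 3, 250 Hz acquisition."""
    config = CiliaSimConfig(
        height=64,
        width=64,
        n_frames=256,
        acquisition_frequency=250.0,
        regions=(CiliaRegion(mask=square_region_mask, frequency=22.0, amplitude=30.0),),
        baseline_intensity=100.0,
        noise_sd=10.0,
        seed=42,
    )
    stack, truth = generate_cilia_stack(config)
    return stack, truth
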