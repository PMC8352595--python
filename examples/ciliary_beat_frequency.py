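"""Estimate ciliary beat frequency from a simulated high-speed recording.

Builds a 128x128, 512-frame stack at 250 Hz with a square patch beating at
22 Hz (amplitude 30 on a baseline of 100, Gaussian noise SD 10) and runs the
per-pixel FFT pipeline on it.
"""

import numpy as np

from ciliashift.cilia import run_cbf
from ciliashift.simulate import CiliaRegion, CiliaSimConfig, generate_cilia_stack

mask = np.zeros((128, 128), dtype=bool)
mask[32:96, 32:96] = True
config = CiliaSimConfig(
    height=128,
    width=128,
    n_frames=512,
    acquisition_frequency=250.0,
    regions=(CiliaRegion(mask=mask, frequency=22.0, amplitude=30.0),),
    baseline_intensity=100.0,
    noise_sd=10.0,
    seed=3,
)
stack, truth = generate_cilia_stack(config)
report = run_cbf(stack, config.acquisition_frequency)[0]

bin_width = config.acquisition_frequency / config.n_frames
print(f"planted beat frequency:  22.0 Hz")
print(f"estimated CBF:           {report.cbf_hz:.3f} Hz (bin width {bin_width:.3f} Hz)")
print(f"signal pixels:           {report.n_signal_pixels} of {mask.size}")
print(f"power threshold:         {report.power_threshold:.3g}")
# The CBF lands on the spectral bin nearest the planted frequency; the signal
# mask covers the oscillating patch plus background pixels whose noise peaks
# clear the permissive bottom-20% + 1.5 SD threshold.
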