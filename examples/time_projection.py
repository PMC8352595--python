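"""Preprocess a time-lapse stack and render a colour-coded time projection.

Builds a small stack with a static dark spot and a moving dark spot on a
bright background, removes the static background (inversion, rescale, blur,
temporal-median subtraction, rolling-ball), and colour-codes time so the
moving object leaves a rainbow trail.
"""

import numpy as np

from ciliashift.cilia import preprocess_stack, temporal_color_projection

T = 12
stack = np.full((T, 32, 32), 255, dtype=np.uint8)
stack[:, 10, 10] = 0  # static object
for t in range(T):
    stack[t, 20, 8 + t] = 0  # object moving left to right

clean = preprocess_stack(stack)
print(f"static pixel intensity after preprocessing:  {clean[:, 10, 10].max()}")
print(f"moving pixel trail intensity (max):          {clean.max()}")

rgb = temporal_color_projection(clean, lut_name="jet")
early = rgb[20, 8 + 1]
late = rgb[20, 8 + T - 2]
print(f"early trail colour (RGB): {np.round(early, 2)}")
print(f"late trail colour (RGB):  {np.round(late, 2)}")
# The static object is erased by temporal-median subtraction; the moving
# object survives, and its trail runs from the colormap's first colour
# (early frames, blue in 'jet') to its last (late frames, red).
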