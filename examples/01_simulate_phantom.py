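"""Simulate one synthetic RF frame per class and inspect its spectrum.

The malignant preset has a stronger quadratic nonlinearity (beta) and a
denser scatterer population, so its lines carry a visible second-harmonic
bump around 2*f0 = 0.25 cycles/sample.
"""

import numpy as np
from dataclasses import replace

from rfbispec import BENIGN_PRESET, MALIGNANT_PRESET, simulate_frame


def band_power(frame, lo, hi):
    spec = np.abs(np.fft.rfft(frame.samples, axis=0)) ** 2
    f = np.fft.rfftfreq(frame.samples.shape[0])
    return spec[(f >= lo) & (f <= hi)].mean()


for preset in (BENIGN_PRESET, MALIGNANT_PRESET):
    params = replace(preset, n_samples=1024, n_lines=32)
    frame = simulate_frame(params, seed=0)
    fund = band_power(frame, 0.105, 0.145)
    harm = band_power(frame, 0.23, 0.27)
    print(
        f"{params.label:9s}  beta={params.beta:<5} "
        f"fundamental-band power={fund:9.1f}  "
        f"second-harmonic-band power={harm:7.2f}  "
        f"harmonic/fundamental={harm / fund:.4f}"
    )

print(
    "\nThe harmonic/fundamental ratio is an order of magnitude larger for\n"
    "the malignant preset: the quadratic distortion that models stiffer,\n"
    "more heterogeneous tissue phase-couples the pulse band with itself."
)
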