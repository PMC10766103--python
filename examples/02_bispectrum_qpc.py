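"""Detect quadratic phase coupling with the bispectrum.

A triple of cosines at 0.12, 0.18 and 0.30 cycles/sample whose phases
satisfy phi3 = phi1 + phi2 is quadratically phase coupled: its bispectrum
peaks at the coupled bifrequency.  Breaking the phase relation removes
the peak even though the power spectrum is unchanged — the whole point of
going to third order.
"""

import numpy as np

from rfbispec import HOSConfig, bispectrum_indirect, estimate_c3, principal_domain

cfg = HOSConfig()
rng = np.random.default_rng(0)
n = np.arange(256)
masks = principal_domain(cfg.nfft)
freqs = np.fft.fftshift(np.fft.fftfreq(cfg.nfft))

for coupled in (True, False):
    acc = np.zeros((cfg.nfft, cfg.nfft), complex)
    for _ in range(64):
        p1, p2 = rng.uniform(0, 2 * np.pi, 2)
        p3 = p1 + p2 if coupled else rng.uniform(0, 2 * np.pi)
        x = (
            np.cos(2 * np.pi * 0.12 * n + p1)
            + np.cos(2 * np.pi * 0.18 * n + p2)
            + np.cos(2 * np.pi * 0.30 * n + p3)
        )
        acc += bispectrum_indirect(estimate_c3(x, cfg.max_lag), cfg.nfft).values
    mag = np.where(masks.S0, np.abs(acc) / 64, 0.0)
    i, j = np.unravel_index(mag.argmax(), mag.shape)
    tag = "coupled  " if coupled else "uncoupled"
    print(
        f"{tag}: peak |BS| = {mag.max():8.2f} at (f1, f2) = "
        f"({freqs[i]:+.4f}, {freqs[j]:+.4f})"
    )

print(
    "\nWith coupling the peak sits within one bin of (0.18, 0.12) — the\n"
    "principal-domain representative of the coupled pair; randomizing the\n"
    "third phase collapses the averaged bispectrum toward zero."
)
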