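import numpy as np
import pytest
from dataclasses import replace

from rfbispec.phantom import (
    BENIGN_PRESET,
    MALIGNANT_PRESET,
    simulate_frame,
    frame_seed,
)

# Desk-scale frame geometry used throughout the suite (full clinical-style
# defaults are 2048 x 128; see docs/methods.md).
SMALL_GEOM = dict(n_samples=1024, n_lines=32)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_benign_frame():
    return simulate_frame(replace(BENIGN_PRESET, **SMALL_GEOM), frame_seed(0, 0))


@pytest.fixture(scope="session")
def small_malignant_frame():
    return simulate_frame(
        replace(MALIGNANT_PRESET, **SMALL_GEOM), frame_seed(0, 1)
    )


def qpc_segment(n=256, f1=0.12, f2=0.18, phases=(0.0, 0.0), coupled=True):
    """Quadratically phase-coupled cosine triple: components at f1, f2 and
    f1+f2 with the sum phase equal to the phase sum (the QPC condition)."""
    n_ = np.arange(n)
    p1, p2 = phases
    p3 = p1 + p2 if coupled else p1 - 2.0 * p2 + 1.0
    return (
        np.cos(2 * np.pi * f1 * n_ + p1)
        + np.cos(2 * np.pi * f2 * n_ + p2)
        + np.cos(2 * np.pi * (f1 + f2) * n_ + p3)
    )
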