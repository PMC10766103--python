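"""Synthetic nonlinear RF phantom generator.

Emulates labeled ultrasound radiofrequency frames whose bispectral band
energies differ by class.  Each scanline is a sparse train of point
scatterers (Poisson counts, uniform positions, Gaussian amplitudes)
convolved with a Gaussian-modulated pulse; a memoryless quadratic
distortion y = s + beta * s^2 then injects second-harmonic phase coupling,
and white Gaussian noise is added at a configurable SNR.  A larger beta
produces stronger quadratic phase coupling and hence larger high-band
bispectral energy, which is what separates the "malignant" preset from the
"benign" one.

The default geometry (2048 axial samples x 128 lines, f0 at 1/8 of the
sampling rate) mimics a 5 MHz probe sampled at 40 MHz, keeping the second
harmonic well inside Nyquist.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import gausspulse, fftconvolve

__all__ = [
    "PhantomParams",
    "RFFrame",
    "BENIGN_PRESET",
    "MALIGNANT_PRESET",
    "make_pulse",
    "simulate_frame",
    "simulate_dataset",
    "frame_seed",
]

#: reference window used to express the scatterer rate (scatterers / window)
RATE_WINDOW = 256


@dataclass(frozen=True)
class PhantomParams:
    """Acquisition + tissue parameters of one synthetic frame class.

    f0_norm:        pulse center frequency as a fraction of the sampling rate.
    rel_bandwidth:  fractional -6 dB bandwidth of the pulse.
    beta:           memoryless quadratic nonlinearity coefficient (>= 0).
    scatterer_rate: expected scatterers per 256-sample axial window.
    snr_db:         additive white-noise SNR in dB relative to unit signal
                    power; ``inf`` disables noise.
    """

    f0_norm: float = 0.125
    rel_bandwidth: float = 0.6
    beta: float = 0.0
    scatterer_rate: float = 8.0
    snr_db: float = 20.0
    n_samples: int = 2048
    n_lines: int = 128
    fs_hz: float = 40e6
    label: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.f0_norm < 0.25:
            raise ValueError("f0_norm must lie in (0, 0.25)")
        if self.rel_bandwidth <= 0:
            raise ValueError("rel_bandwidth must be positive")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.scatterer_rate < 0:
            raise ValueError("scatterer_rate must be >= 0")
        if self.n_samples < 256:
            raise ValueError("n_samples must be >= 256")
        if self.n_lines < 1:
            raise ValueError("n_lines must be >= 1")
        if self.label is not None and self.label not in ("benign", "malignant"):
            raise ValueError("label must be 'benign' or 'malignant'")


@dataclass
class RFFrame:
    """One RF frame: axial samples (axis 0) by scanlines (axis 1)."""

    samples: np.ndarray
    fs_hz: float
    f0_hz: float
    frame_id: str = ""
    label: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D array (axial x lateral)")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("RF samples contain non-finite values")


BENIGN_PRESET = PhantomParams(beta=0.05, scatterer_rate=4.0, label="benign")
MALIGNANT_PRESET = PhantomParams(beta=0.3, scatterer_rate=12.0, label="malignant")


def make_pulse(f0_norm: float, rel_bandwidth: float, length: int) -> np.ndarray:
    """Gaussian-modulated sinusoid with unit peak envelope.

    ``length`` must be odd so the envelope is even-symmetric about the
    center sample, where the carrier phase is zero (pure cosine peak).
    """
    if length % 2 != 1:
        raise ValueError("pulse length must be odd")
    if not 0 < f0_norm < 0.5:
        raise ValueError("f0_norm must lie in (0, 0.5)")
    if rel_bandwidth <= 0:
        raise ValueError("rel_bandwidth must be positive")
    t = np.arange(length) - length // 2
    return gausspulse(t.astype(float), fc=f0_norm, bw=rel_bandwidth, bwr=-6)


def _pulse_length(params: PhantomParams) -> int:
    # long enough to contain the envelope at the narrowest supported band
    n = int(np.ceil(8.0 / (params.rel_bandwidth * params.f0_norm)))
    return n + 1 if n % 2 == 0 else n


def simulate_frame(params: PhantomParams, seed: int) -> RFFrame:
    """Simulate one RF frame; a pure function of (params, seed)."""
    rng = np.random.default_rng(seed)
    pulse = make_pulse(params.f0_norm, params.rel_bandwidth, _pulse_length(params))
    n, m = params.n_samples, params.n_lines
    trains = np.zeros((n, m))
    mean_count = params.scatterer_rate * n / RATE_WINDOW
    for line in range(m):
        count = rng.poisson(mean_count)
        if count:
            pos = rng.integers(0, n, size=count)
            amp = rng.standard_normal(count)
            np.add.at(trains[:, line], pos, amp)
    s = fftconvolve(trains, pulse[:, None], mode="same", axes=0)
    rms = np.sqrt(np.mean(s**2))
    if rms > 0:
        s /= rms
    y = s + params.beta * s**2
    if np.isfinite(params.snr_db):
        sigma = 10.0 ** (-params.snr_db / 20.0)
        y = y + rng.normal(0.0, sigma, size=y.shape)
    return RFFrame(
        samples=y,
        fs_hz=params.fs_hz,
        f0_hz=params.f0_norm * params.fs_hz,
        label=params.label,
    )


def frame_seed(master_seed: int, index: int) -> int:
    """Per-frame seed derived from (master_seed, frame index).

    Uses numpy's SeedSequence entropy pooling so nearby master seeds and
    indices give statistically independent streams; result is < 2**31.
    """
    ss = np.random.SeedSequence((int(master_seed), int(index)))
    return int(ss.generate_state(1)[0] % (2**31))


def _split_assignment(
    n: int, fractions: tuple[float, float, float]
) -> list[str]:
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    names = (
        ["train"] * n_train
        + ["val"] * n_val
        + ["test1"] * (n - n_train - n_val)
    )
    return names


def simulate_dataset(
    n_per_class: int,
    benign: PhantomParams | None = None,
    malignant: PhantomParams | None = None,
    seed: int = 0,
    out_dir=None,
    split_fractions: tuple[float, float, float] = (0.7, 0.15, 0.15),
):
    """Generate a labeled two-class dataset and (optionally) write it out.

    Returns ``(frames, manifest_rows)``; when ``out_dir`` is given each
    frame is written as an HDF5 RF container and a CSV manifest
    (frame_id,label,split) is produced alongside.  Per-frame seeds derive
    deterministically from the master seed via :func:`frame_seed`.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    benign = benign or BENIGN_PRESET
    malignant = malignant or MALIGNANT_PRESET
    frames: list[RFFrame] = []
    rows: list[tuple[str, str, str]] = []
    for ci, params in enumerate((benign, malignant)):
        label = params.label or ("benign", "malignant")[ci]
        splits = _split_assignment(n_per_class, split_fractions)
        for i in range(n_per_class):
            idx = ci * n_per_class + i
            frame = simulate_frame(
                replace(params, label=label), frame_seed(seed, idx)
            )
            frame.frame_id = f"{label}_{i:04d}"
            frames.append(frame)
            rows.append((frame.frame_id, label, splits[i]))
    if out_dir is not None:
        from . import io as rfio
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for frame in frames:
            rfio.write_rf_frame(frame, out / f"{frame.frame_id}.h5", force=True)
        rfio.write_manifest(rows, out / "manifest.csv")
    return frames, rows
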