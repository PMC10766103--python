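"""Higher-order spectral analysis of RF signal segments.

This module implements the indirect (cumulant-based) bispectrum estimator:
the third-order cumulant lattice of a segment is estimated by lagged
triple-product averaging and Fourier-transformed onto a grid of normalized
bifrequencies (f1, f2).  The non-redundant principal domain

    S0 = { (f1, f2) : 0 <= f2 <= f1,  f1 + f2 <= 1/2 }

is subdivided into three equal-width frequency bands A1/A2/A3, whose
intersections with S0 give a low- (S1), mid- (S2) and high-frequency (S3)
non-overlapping region.  The energies of S1, S2, S3 and S0 are the four
per-segment features that downstream code assembles into feature maps.

The bispectrum of a zero-mean Gaussian process vanishes, so these energies
respond selectively to non-Gaussian structure such as the quadratic phase
coupling produced by harmonic distortion in tissue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "HOSConfig",
    "CumulantLattice",
    "BispectrumGrid",
    "RegionMasks",
    "SegmentFeatures",
    "estimate_c3",
    "bispectrum_indirect",
    "bispectrum_direct_oracle",
    "principal_domain",
    "subdivide_bands",
    "region_energy",
    "segment_features",
]


@dataclass(frozen=True)
class HOSConfig:
    """Configuration of the per-segment bispectrum pipeline.

    window:       segment length in samples.
    max_lag:      maximum cumulant lag L; the lattice spans [-L, L]^2.
    nfft:         bifrequency grid size (nfft x nfft), must be >= 2*max_lag+1.
    energy_mode:  "power" sums |BS|^2 over a region, "magnitude" sums |BS|.
    split_axis:   which bifrequency axis is cut into the three equal bands.
    demean:       subtract the segment mean before cumulant estimation.
    lag_window:   "none" (uniform) or "parzen" lag-domain smoothing window.
    """

    window: int = 256
    max_lag: int = 63
    nfft: int = 128
    energy_mode: str = "power"
    split_axis: str = "f1"
    demean: bool = True
    lag_window: str = "none"

    def __post_init__(self) -> None:
        if self.window < 8:
            raise ValueError("window must be >= 8")
        if not 0 < self.max_lag < self.window:
            raise ValueError("max_lag must satisfy 0 < max_lag < window")
        if self.nfft < 2 * self.max_lag + 1:
            raise ValueError("nfft must be >= 2*max_lag + 1")
        if self.energy_mode not in ("power", "magnitude"):
            raise ValueError(f"unknown energy_mode {self.energy_mode!r}")
        if self.split_axis not in ("f1", "f2"):
            raise ValueError(f"unknown split_axis {self.split_axis!r}")
        if self.lag_window not in ("none", "parzen"):
            raise ValueError(f"unknown lag_window {self.lag_window!r}")


@dataclass
class CumulantLattice:
    """Third-order cumulant estimates C3(k, l) on the square lag lattice.

    ``values[k + max_lag, l + max_lag]`` holds C3(k, l) for lags in
    [-max_lag, max_lag]; the lattice is symmetric under lag exchange.
    """

    values: np.ndarray
    max_lag: int

    def at(self, k: int, l: int) -> float:
        L = self.max_lag
        return float(self.values[k + L, l + L])


@dataclass
class BispectrumGrid:
    """Complex bispectrum on an nfft x nfft grid of normalized bifrequencies.

    Axis 0 is f1, axis 1 is f2; ``freqs`` gives the frequency of each bin in
    cycles/sample, monotonically increasing over [-1/2, 1/2).
    """

    values: np.ndarray
    freqs: np.ndarray

    @property
    def nfft(self) -> int:
        return self.values.shape[0]


@dataclass
class RegionMasks:
    """Boolean masks over a bifrequency grid: principal domain and bands."""

    S0: np.ndarray
    S1: np.ndarray | None = None
    S2: np.ndarray | None = None
    S3: np.ndarray | None = None
    band_edges: tuple[float, ...] = ()
    split_axis: str = "f1"


@dataclass(frozen=True)
class SegmentFeatures:
    """The four region energies of one RF segment."""

    E_S1: float
    E_S2: float
    E_S3: float
    E_S0: float

    def as_array(self) -> np.ndarray:
        return np.array([self.E_S1, self.E_S2, self.E_S3, self.E_S0])


# ---------------------------------------------------------------------------
# third-order cumulant
# ---------------------------------------------------------------------------


def _c3_batch(x: np.ndarray, max_lag: int, demean: bool = True) -> np.ndarray:
    """Cumulant lattices for a batch of segments, shape (S, 2L+1, 2L+1).

    For each segment, C3(k, l) = (1/N) * sum_n x(n) x(n+k) x(n+l) over the n
    for which all three indices fall inside the segment.  The half-plane
    k >= 0 is computed by FFT cross-correlation of y_k(n) = x(n) x(n+k)
    against x; the remainder follows from the exact estimator symmetries

        C3(k, l) = C3(l, k)          (summand exchange)
        C3(-a, -b) = C3(a, a-b)      (index shift n -> n - a)

    both of which hold bin-for-bin for the valid-range finite-sample sum.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 1:
        x = x[None, :]
    S, N = x.shape
    L = int(max_lag)
    if not 0 < L < N:
        raise ValueError("max_lag must satisfy 0 < max_lag < segment length")
    if demean:
        x = x - x.mean(axis=1, keepdims=True)

    nfft_corr = 1
    while nfft_corr < 2 * N:
        nfft_corr *= 2
    X = np.fft.rfft(x, nfft_corr, axis=1)

    # R[s, k, l] for k in [0, L], l in [-L, L]
    R = np.empty((S, L + 1, 2 * L + 1), dtype=np.float64)
    for k in range(L + 1):
        y = np.zeros_like(x)
        y[:, : N - k] = x[:, : N - k] * x[:, k:]
        Y = np.fft.rfft(y, nfft_corr, axis=1)
        # c[l] = sum_n y(n) x(n+l): positive lags at c[l], negative at c[nfft+l]
        c = np.fft.irfft(np.conj(Y) * X, nfft_corr, axis=1)
        R[:, k, L:] = c[:, : L + 1]
        R[:, k, :L] = c[:, nfft_corr - L :]
    R /= N

    lat = np.empty((S, 2 * L + 1, 2 * L + 1), dtype=np.float64)
    ks = np.arange(-L, L + 1)
    for i, k in enumerate(ks):
        for j, l in enumerate(ks):
            if k >= 0:
                lat[:, i, j] = R[:, k, l + L]
            elif l >= 0:
                lat[:, i, j] = R[:, l, k + L]  # C3(k,l) = C3(l,k)
            else:
                a, b = -k, -l  # C3(-a,-b) = C3(a, a-b)
                lat[:, i, j] = R[:, a, (a - b) + L]
    return lat


def estimate_c3(
    segment: np.ndarray, max_lag: int, demean: bool = True
) -> CumulantLattice:
    """Estimate the third-order cumulant lattice of one segment.

    Uses the biased 1/N normalization over the valid-index range; with
    ``demean`` the segment mean is removed first (disable only for
    controlled unit checks).
    """
    segment = np.asarray(segment, dtype=np.float64)
    if segment.ndim != 1:
        raise ValueError("segment must be 1-D")
    if not np.all(np.isfinite(segment)):
        raise ValueError("segment contains non-finite values")
    lat = _c3_batch(segment, max_lag, demean=demean)[0]
    return CumulantLattice(values=lat, max_lag=int(max_lag))


def _parzen(L: int) -> np.ndarray:
    m = np.abs(np.arange(-L, L + 1)) / (L + 1)
    w = np.where(m <= 0.5, 1 - 6 * m**2 + 6 * m**3, 2 * (1 - m) ** 3)
    return w


def _apply_lag_window(lat: np.ndarray, L: int, kind: str) -> np.ndarray:
    if kind == "none":
        return lat
    w = _parzen(L)
    ks = np.arange(-L, L + 1)
    dk = np.clip(np.abs(ks[:, None] - ks[None, :]), 0, L)
    wkl = w[:, None] * w[None, :] * w[dk]
    return lat * wkl


# ---------------------------------------------------------------------------
# bispectrum estimators
# ---------------------------------------------------------------------------


def _bispectrum_fft_batch(lat: np.ndarray, nfft: int) -> np.ndarray:
    """2-D DFT of zero-padded cumulant lattices; output in fftshift order."""
    S = lat.shape[0]
    L = (lat.shape[1] - 1) // 2
    if nfft < 2 * L + 1:
        raise ValueError("nfft must be >= 2*max_lag + 1")
    ks = np.arange(-L, L + 1) % nfft
    buf = np.zeros((S, nfft, nfft), dtype=np.float64)
    buf[:, ks[:, None], ks[None, :]] = lat
    bs = np.fft.fft2(buf, axes=(1, 2))
    return np.fft.fftshift(bs, axes=(1, 2))


def bispectrum_indirect(c3: CumulantLattice, nfft: int) -> BispectrumGrid:
    """Bispectrum BS(f1, f2) = sum_{k,l} C3(k,l) e^{-j2pi f1 k} e^{-j2pi f2 l}.

    Evaluated on an nfft x nfft grid of normalized frequencies via a
    zero-padded 2-D FFT of the lag lattice; axis 0 is f1, axis 1 is f2.
    """
    vals = _bispectrum_fft_batch(c3.values[None, ...], nfft)[0]
    freqs = np.fft.fftshift(np.fft.fftfreq(nfft))
    return BispectrumGrid(values=vals, freqs=freqs)


def bispectrum_direct_oracle(
    segment: np.ndarray, nfft: int, n_blocks: int
) -> BispectrumGrid:
    """Direct (FFT-based) bispectrum estimate, for cross-estimator checks.

    The segment is split into ``n_blocks`` equal blocks; each block b yields
    X_b(f) and the estimate averages X_b(f1) X_b(f2) conj(X_b(f1+f2)) over
    blocks.  Kept deliberately independent of the indirect path.
    """
    x = np.asarray(segment, dtype=np.float64)
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    blen = x.size // n_blocks
    if blen < 2:
        raise ValueError("segment too short for the requested block count")
    acc = np.zeros((nfft, nfft), dtype=np.complex128)
    idx = np.arange(nfft)
    sum_idx = (idx[:, None] + idx[None, :]) % nfft
    for b in range(n_blocks):
        blk = x[b * blen : (b + 1) * blen]
        blk = blk - blk.mean()
        X = np.fft.fft(blk, nfft)
        acc += X[:, None] * X[None, :] * np.conj(X[sum_idx])
    acc /= n_blocks
    freqs = np.fft.fftshift(np.fft.fftfreq(nfft))
    return BispectrumGrid(values=np.fft.fftshift(acc), freqs=freqs)


# ---------------------------------------------------------------------------
# principal domain and frequency bands
# ---------------------------------------------------------------------------

_EPS = 1e-12


def principal_domain(nfft: int) -> RegionMasks:
    """Mask of the non-redundant triangle {0 <= f2 <= f1, f1+f2 <= 1/2}."""
    if nfft < 4:
        raise ValueError("nfft must be >= 4")
    freqs = np.fft.fftshift(np.fft.fftfreq(nfft))
    F1 = freqs[:, None]
    F2 = freqs[None, :]
    S0 = (F2 >= -_EPS) & (F2 <= F1 + _EPS) & (F1 + F2 <= 0.5 + _EPS)
    return RegionMasks(S0=S0)


def subdivide_bands(
    masks: RegionMasks, n_bands: int = 3, split_axis: str = "f1"
) -> RegionMasks:
    """Cut the split axis of S0 into equal bands A1..A3 and intersect.

    The bands tile [0, 1/2] with half-open intervals [lo, hi), the last band
    closed at 1/2, so every S0 bin lands in exactly one of S1/S2/S3.
    """
    if n_bands != 3:
        raise ValueError("only the three-band subdivision is defined")
    if split_axis not in ("f1", "f2"):
        raise ValueError(f"unknown split_axis {split_axis!r}")
    nfft = masks.S0.shape[0]
    freqs = np.fft.fftshift(np.fft.fftfreq(nfft))
    axis_vals = freqs[:, None] if split_axis == "f1" else freqs[None, :]
    axis_vals = np.broadcast_to(axis_vals, masks.S0.shape)
    edges = (0.0, 1 / 6, 1 / 3, 1 / 2)
    bands = []
    for b in range(3):
        lo, hi = edges[b], edges[b + 1]
        in_band = (axis_vals >= lo - _EPS) & (axis_vals < hi - _EPS)
        if b == 2:
            in_band = (axis_vals >= lo - _EPS) & (axis_vals <= hi + _EPS)
        bands.append(masks.S0 & in_band)
    return RegionMasks(
        S0=masks.S0,
        S1=bands[0],
        S2=bands[1],
        S3=bands[2],
        band_edges=edges,
        split_axis=split_axis,
    )


def region_energy(
    grid: BispectrumGrid | np.ndarray, mask: np.ndarray, mode: str = "power"
) -> float:
    """Energy of the masked bins: sum |BS|^2 ("power") or sum |BS|."""
    vals = grid.values if isinstance(grid, BispectrumGrid) else np.asarray(grid)
    if vals.shape != mask.shape:
        raise ValueError("mask shape does not match grid shape")
    mag = np.abs(vals[mask])
    if mode == "power":
        return float(np.sum(mag**2))
    if mode == "magnitude":
        return float(np.sum(mag))
    raise ValueError(f"unknown energy mode {mode!r}")


# ---------------------------------------------------------------------------
# per-segment feature pipeline
# ---------------------------------------------------------------------------


def _masks_for(cfg: HOSConfig) -> RegionMasks:
    return subdivide_bands(principal_domain(cfg.nfft), split_axis=cfg.split_axis)


def segment_features_batch(
    segments: np.ndarray, cfg: HOSConfig, chunk: int = 128
) -> np.ndarray:
    """Region energies for many segments at once; returns (S, 4) array
    ordered (E_S1, E_S2, E_S3, E_S0).  Chunked to bound FFT memory.

    E_S0 is formed as the float sum of the three band energies, so the
    partition identity E_S1 + E_S2 + E_S3 = E_S0 holds exactly (the bands
    are a disjoint partition of the principal domain, hence the same
    summands)."""
    segments = np.atleast_2d(np.asarray(segments, dtype=np.float64))
    if segments.shape[1] < cfg.window:
        raise ValueError("segments shorter than the configured window")
    masks = _masks_for(cfg)
    mlist = [masks.S1, masks.S2, masks.S3]
    out = np.empty((segments.shape[0], 4), dtype=np.float64)
    for s0 in range(0, segments.shape[0], chunk):
        blk = segments[s0 : s0 + chunk]
        lat = _c3_batch(blk, cfg.max_lag, demean=cfg.demean)
        if cfg.lag_window != "none":
            lat = _apply_lag_window(lat, cfg.max_lag, cfg.lag_window)
        bs = _bispectrum_fft_batch(lat, cfg.nfft)
        mag = np.abs(bs)
        if cfg.energy_mode == "power":
            mag = mag**2
        for j, m in enumerate(mlist):
            out[s0 : s0 + blk.shape[0], j] = mag[:, m].sum(axis=1)
        out[s0 : s0 + blk.shape[0], 3] = out[s0 : s0 + blk.shape[0], :3].sum(
            axis=1
        )
    return out


def segment_features(segment: np.ndarray, cfg: HOSConfig | None = None) -> SegmentFeatures:
    """Four bispectral band energies (S1, S2, S3, S0) of one RF segment."""
    cfg = cfg or HOSConfig()
    segment = np.asarray(segment, dtype=np.float64)
    if segment.size < cfg.window:
        raise ValueError(
            f"segment length {segment.size} shorter than window {cfg.window}"
        )
    e = segment_features_batch(segment[None, : segment.size], cfg)[0]
    return SegmentFeatures(E_S1=e[0], E_S2=e[1], E_S3=e[2], E_S0=e[3])
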