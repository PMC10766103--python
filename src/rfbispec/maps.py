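"""Per-frame bispectral energy feature maps and inter-map statistics.

Segments tile each frame with an axial sliding window (default 256 samples,
hop 64) and one column per scanline; every segment contributes its four
region energies, yielding four co-registered maps BS_S1 (low band), BS_S2
(mid band), BS_S3 (high band) and BS_A (whole principal domain).  Raw maps
satisfy BS_S1 + BS_S2 + BS_S3 = BS_A elementwise because the bands
partition the principal domain.

The maps are min-max normalized to 8-bit images for the classifier, and
mutual information / RMSE / histograms quantify how much the four maps
differ from one another.  A simple envelope-detected, log-compressed
B-mode rendering is included for grayscale-image baselines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import hilbert

from .hos import HOSConfig, segment_features_batch
from .phantom import RFFrame

__all__ = [
    "MapGeometry",
    "FeatureMapSet",
    "MapStatsReport",
    "MAP_NAMES",
    "build_feature_maps",
    "normalize_map",
    "mutual_information",
    "rmse",
    "pairwise_stats",
    "bmode_from_rf",
]

MAP_NAMES = ("BS_S1", "BS_S2", "BS_S3", "BS_A")


@dataclass(frozen=True)
class MapGeometry:
    """How segments tile a frame: axial window/hop, lateral stride."""

    window: int = 256
    hop: int = 64
    lateral_stride: int = 1

    def __post_init__(self) -> None:
        if not 1 <= self.hop <= self.window:
            raise ValueError("hop must satisfy 1 <= hop <= window")
        if self.lateral_stride < 1:
            raise ValueError("lateral_stride must be >= 1")

    def n_rows(self, n_samples: int) -> int:
        if n_samples < self.window:
            raise ValueError("frame shorter than one analysis window")
        return (n_samples - self.window) // self.hop + 1


@dataclass
class FeatureMapSet:
    """Four raw energy maps + their 8-bit images for one frame."""

    maps: dict[str, np.ndarray]
    images: dict[str, np.ndarray]
    geometry: MapGeometry
    frame_id: str = ""
    label: str | None = None


@dataclass
class MapStatsReport:
    """Pairwise MI/RMSE matrices (map order BS_S1, BS_S2, BS_S3, BS_A)."""

    mi: np.ndarray
    rmse: np.ndarray
    histograms: dict[str, np.ndarray]
    avg_mi: dict[str, float]
    avg_rmse: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "map_order": list(MAP_NAMES),
            "mi": self.mi.tolist(),
            "rmse": self.rmse.tolist(),
            "histograms": {k: v.tolist() for k, v in self.histograms.items()},
            "avg_mi": self.avg_mi,
            "avg_rmse": self.avg_rmse,
        }


def build_feature_maps(
    frame: RFFrame,
    geometry: MapGeometry | None = None,
    hos_cfg: HOSConfig | None = None,
    image_mode: str = "log",
) -> FeatureMapSet:
    """Slide the analysis window over the frame and assemble the four maps.

    Row r, column c of each map holds the corresponding region energy of
    the segment starting at axial sample ``r * hop`` on scanline
    ``c * lateral_stride``; trailing samples that do not fill a window are
    dropped.

    Images default to log compression (``image_mode="log"``) because raw
    bispectral energies span many decades; linear min-max collapses almost
    every pixel to zero, which starves the classifier.  Pass
    ``image_mode="linear"`` for plain min-max images.
    """
    geometry = geometry or MapGeometry()
    hos_cfg = hos_cfg or HOSConfig(window=geometry.window)
    if geometry.window != hos_cfg.window:
        raise ValueError("geometry.window must match hos_cfg.window")
    x = np.asarray(frame.samples, dtype=np.float64)
    n_rows = geometry.n_rows(x.shape[0])
    cols = np.arange(0, x.shape[1], geometry.lateral_stride)
    # (n_rows, n_cols, window) view, then flattened into a segment batch
    wins = sliding_window_view(x, geometry.window, axis=0)[:: geometry.hop]
    wins = wins[:n_rows][:, cols, :]
    segs = wins.reshape(-1, geometry.window)
    energies = segment_features_batch(segs, hos_cfg)
    shaped = energies.reshape(n_rows, len(cols), 4)
    maps = {
        "BS_S1": shaped[:, :, 0],
        "BS_S2": shaped[:, :, 1],
        "BS_S3": shaped[:, :, 2],
        "BS_A": shaped[:, :, 3],
    }
    images = {k: normalize_map(v, mode=image_mode) for k, v in maps.items()}
    return FeatureMapSet(
        maps=maps,
        images=images,
        geometry=geometry,
        frame_id=frame.frame_id,
        label=frame.label,
    )


def normalize_map(raw: np.ndarray, mode: str = "linear") -> np.ndarray:
    """Min-max scale a raw map to uint8; constant maps become all zeros.

    ``mode="log"`` applies log10(1 + E) before scaling, compressing the
    large dynamic range of bispectral energies.
    """
    raw = np.asarray(raw, dtype=np.float64)
    if not np.all(np.isfinite(raw)):
        raise ValueError("raw map contains non-finite values")
    if mode == "log":
        raw = np.log10(1.0 + raw)
    elif mode != "linear":
        raise ValueError(f"unknown normalization mode {mode!r}")
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        return np.zeros(raw.shape, dtype=np.uint8)
    return np.round(255.0 * (raw - lo) / (hi - lo)).astype(np.uint8)


def mutual_information(imgA: np.ndarray, imgB: np.ndarray, bins: int = 64) -> float:
    """Mutual information in bits from the joint histogram of two images."""
    a = np.asarray(imgA).ravel()
    b = np.asarray(imgB).ravel()
    if a.shape != b.shape:
        raise ValueError("images must share a shape")
    joint, _, _ = np.histogram2d(a, b, bins=bins)
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    return float(np.sum(pxy[nz] * np.log2(pxy[nz] / (px @ py)[nz])))


def rmse(imgA: np.ndarray, imgB: np.ndarray) -> float:
    """Root mean square difference between two equal-shape images."""
    a = np.asarray(imgA, dtype=np.float64)
    b = np.asarray(imgB, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("images must share a shape")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def pairwise_stats(fmset: FeatureMapSet, bins: int = 64) -> MapStatsReport:
    """Full 4x4 MI and RMSE matrices over the 8-bit images, plus per-map
    averages against the other three maps and per-map histograms."""
    imgs = [fmset.images[name] for name in MAP_NAMES]
    K = len(imgs)
    mi = np.zeros((K, K))
    rm = np.zeros((K, K))
    for i in range(K):
        for j in range(i, K):
            mi[i, j] = mi[j, i] = mutual_information(imgs[i], imgs[j], bins=bins)
            rm[i, j] = rm[j, i] = rmse(imgs[i], imgs[j])
    others = lambda i: [j for j in range(K) if j != i]
    avg_mi = {MAP_NAMES[i]: float(np.mean(mi[i, others(i)])) for i in range(K)}
    avg_rmse = {MAP_NAMES[i]: float(np.mean(rm[i, others(i)])) for i in range(K)}
    hists = {
        name: np.bincount(img.ravel(), minlength=256)
        for name, img in zip(MAP_NAMES, imgs)
    }
    return MapStatsReport(
        mi=mi, rmse=rm, histograms=hists, avg_mi=avg_mi, avg_rmse=avg_rmse
    )


def bmode_from_rf(frame: RFFrame, dynamic_range_db: float = 60.0) -> np.ndarray:
    """Grayscale B-mode stand-in: per-line analytic-signal envelope,
    log compression over ``dynamic_range_db``, min-max to uint8.

    This is a plain display rendering, not any vendor's reconstruction.
    """
    x = np.asarray(frame.samples, dtype=np.float64)
    env = np.abs(hilbert(x, axis=0))
    peak = env.max()
    if peak == 0:
        return np.zeros(x.shape, dtype=np.uint8)
    db = 20.0 * np.log10(env / peak + 1e-12)
    db = np.clip(db, -dynamic_range_db, 0.0)
    img = (db + dynamic_range_db) / dynamic_range_db
    return np.round(255.0 * img).astype(np.uint8)
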