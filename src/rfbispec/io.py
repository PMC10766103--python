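"""RF containers, manifests and run configuration.

The canonical on-disk RF dialect is an HDF5 file with a 2-D float32
dataset ``rf`` (axial x lateral) and root attributes ``fs_hz``, ``f0_hz``,
``frame_id`` and optionally ``label``.  A raw-binary dialect — a
little-endian float32 ``.bin`` next to a ``.json`` sidecar carrying the
same metadata plus the array shape — is accepted on read and write for
interoperability with tools that cannot speak HDF5.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import h5py
import numpy as np

from .phantom import RFFrame

__all__ = [
    "read_rf_frame",
    "write_rf_frame",
    "read_manifest",
    "write_manifest",
    "Manifest",
    "RunConfig",
]

_REQUIRED_ATTRS = ("fs_hz", "f0_hz", "frame_id")
VALID_LABELS = ("benign", "malignant")
VALID_SPLITS = ("train", "val", "test1", "test2")


class FormatError(ValueError):
    """Raised when an on-disk artifact does not match its dialect."""


def write_rf_frame(frame: RFFrame, path, force: bool = False) -> Path:
    """Write an RF frame; dialect chosen by extension (.h5/.hdf5 or .bin)."""
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")
    data = np.asarray(frame.samples, dtype=np.float32)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("rf", data=data)
            f.attrs["fs_hz"] = float(frame.fs_hz)
            f.attrs["f0_hz"] = float(frame.f0_hz)
            f.attrs["frame_id"] = frame.frame_id
            if frame.label is not None:
                f.attrs["label"] = frame.label
    elif path.suffix == ".bin":
        data.tofile(path)
        meta = {
            "fs_hz": float(frame.fs_hz),
            "f0_hz": float(frame.f0_hz),
            "frame_id": frame.frame_id,
            "shape": list(data.shape),
            "dtype": "<f4",
        }
        if frame.label is not None:
            meta["label"] = frame.label
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    else:
        raise FormatError(f"unsupported RF container extension {path.suffix!r}")
    return path


def read_rf_frame(path) -> RFFrame:
    """Read an RF frame from either supported dialect."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            if "rf" not in f:
                raise FormatError(f"{path}: missing 'rf' dataset")
            for attr in _REQUIRED_ATTRS:
                if attr not in f.attrs:
                    raise FormatError(f"{path}: missing required attribute {attr!r}")
            return RFFrame(
                samples=np.asarray(f["rf"], dtype=np.float64),
                fs_hz=float(f.attrs["fs_hz"]),
                f0_hz=float(f.attrs["f0_hz"]),
                frame_id=str(f.attrs["frame_id"]),
                label=str(f.attrs["label"]) if "label" in f.attrs else None,
            )
    if path.suffix == ".bin":
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise FormatError(f"{path}: raw dialect requires sidecar {sidecar.name}")
        meta = json.loads(sidecar.read_text())
        for attr in _REQUIRED_ATTRS:
            if attr not in meta:
                raise FormatError(f"{sidecar}: missing required attribute {attr!r}")
        data = np.fromfile(path, dtype=meta.get("dtype", "<f4"))
        data = data.reshape(meta["shape"]).astype(np.float64)
        return RFFrame(
            samples=data,
            fs_hz=float(meta["fs_hz"]),
            f0_hz=float(meta["f0_hz"]),
            frame_id=str(meta["frame_id"]),
            label=meta.get("label"),
        )
    raise FormatError(f"unsupported RF container extension {path.suffix!r}")


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

_HEADER = ["frame_id", "label", "split"]


@dataclass
class Manifest:
    rows: list[tuple[str, str, str]]

    def __iter__(self):
        return iter(self.rows)

    def __len__(self):
        return len(self.rows)


def write_manifest(rows, path) -> Path:
    path = Path(path)
    _validate_rows(rows)
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(_HEADER)
        w.writerows(rows)
    return path


def _validate_rows(rows) -> None:
    seen = set()
    for frame_id, label, split in rows:
        if frame_id in seen:
            raise FormatError(f"duplicate frame_id {frame_id!r} in manifest")
        seen.add(frame_id)
        if label not in VALID_LABELS:
            raise FormatError(f"unknown label {label!r} (expected {VALID_LABELS})")
        if split not in VALID_SPLITS:
            raise FormatError(f"unknown split {split!r} (expected {VALID_SPLITS})")


def read_manifest(path) -> Manifest:
    path = Path(path)
    with open(path, newline="") as f:
        r = csv.reader(f)
        header = next(r, None)
        if header != _HEADER:
            raise FormatError(
                f"{path}: expected header {','.join(_HEADER)}, got {header}"
            )
        rows = [tuple(row) for row in r if row]
    for row in rows:
        if len(row) != 3:
            raise FormatError(f"{path}: malformed row {row}")
    _validate_rows(rows)
    return Manifest(rows=list(rows))


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


def _from_dict(cls, d: dict):
    """Dataclass construction that rejects unknown keys."""
    known = {f.name for f in fields(cls)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**d)


@dataclass
class RunConfig:
    """Merged configuration tree for a full pipeline run.

    Nested sections mirror the pipeline stages; every key has a default and
    unknown keys are rejected so that typos fail loudly.  Round-trips
    unchanged through ``to_dict``/``from_dict`` and JSON.
    """

    phantom: dict = field(default_factory=dict)
    hos: dict = field(default_factory=dict)
    geometry: dict = field(default_factory=dict)
    network: dict = field(default_factory=dict)
    training: dict = field(default_factory=dict)

    def resolve(self):
        """Instantiate the typed per-stage configs (validating all keys)."""
        from .phantom import PhantomParams
        from .hos import HOSConfig
        from .maps import MapGeometry
        from .msnet import NetConfig
        from .train import TrainConfig

        return {
            "phantom": _from_dict(PhantomParams, self.phantom),
            "hos": _from_dict(HOSConfig, self.hos),
            "geometry": _from_dict(MapGeometry, self.geometry),
            "network": _from_dict(NetConfig, self.network),
            "training": _from_dict(TrainConfig, self.training),
        }

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        cfg = _from_dict(cls, d)
        cfg.resolve()
        return cfg

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))
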