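"""Lightweight schemas for every JSON document the pipeline writes.

Each schema maps required key -> expected type (or tuple of types); a
``None`` entry means the key is required but may hold any JSON value.
``validate_json`` raises ``SchemaError`` naming the offending key, so
CLI outputs can be checked without an external schema library.
"""

from __future__ import annotations

__all__ = ["SCHEMAS", "SchemaError", "validate_json"]


class SchemaError(ValueError):
    pass


_NUMBER = (int, float)

SCHEMAS: dict[str, dict] = {
    "map_sidecar": {
        "frame_id": str,
        "maps": list,
        "geometry": dict,
        "hos": dict,
        "image_mode": str,
        "map_shape": list,
    },
    "map_stats": {
        "map_order": list,
        "mi": list,
        "rmse": list,
        "histograms": dict,
        "avg_mi": dict,
        "avg_rmse": dict,
    },
    "metrics_report": {
        "accuracy": (*_NUMBER, type(None)),
        "sensitivity": (*_NUMBER, type(None)),
        "specificity": (*_NUMBER, type(None)),
        "PPV": (*_NUMBER, type(None)),
        "NPV": (*_NUMBER, type(None)),
        "AUC": (*_NUMBER, type(None)),
        "confusion": dict,
    },
    "checkpoint_meta": {
        "network": dict,
        "training": dict,
    },
}


def validate_json(payload: dict, kind: str) -> None:
    """Check ``payload`` against the named schema; extra keys are allowed."""
    if kind not in SCHEMAS:
        raise SchemaError(f"unknown schema kind {kind!r}")
    if not isinstance(payload, dict):
        raise SchemaError(f"{kind}: document must be a JSON object")
    for key, expected in SCHEMAS[kind].items():
        if key not in payload:
            raise SchemaError(f"{kind}: missing required key {key!r}")
        if expected is not None and not isinstance(payload[key], expected):
            raise SchemaError(
                f"{kind}: key {key!r} has type "
                f"{type(payload[key]).__name__}, expected {expected}"
            )
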