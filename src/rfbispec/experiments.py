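"""End-to-end synthetic study: phantom -> feature maps -> classifier.

Bundles the full pipeline at desk scale so the same experiment backs the
examples, the test suite and the results-reproduction script.  Frame
geometry defaults to 1024 axial samples x 32 lines — small enough to run
on one CPU core in a couple of minutes while preserving the bispectral
class contrast the phantom is built around.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .hos import HOSConfig
from .maps import MapGeometry, build_feature_maps
from .msnet import MSNet, NetConfig
from .phantom import (
    BENIGN_PRESET,
    MALIGNANT_PRESET,
    frame_seed,
    simulate_frame,
)
from .train import (
    TrainConfig,
    dataset_from_mapsets,
    evaluate,
    importance_report,
    train,
)

__all__ = ["make_synthetic_mapsets", "synthetic_end_to_end"]


def make_synthetic_mapsets(
    n_per_class: int,
    seed: int = 0,
    n_samples: int = 1024,
    n_lines: int = 32,
    geometry: MapGeometry | None = None,
    hos_cfg: HOSConfig | None = None,
):
    """Simulate ``n_per_class`` frames per class and extract their maps."""
    geometry = geometry or MapGeometry()
    hos_cfg = hos_cfg or HOSConfig()
    mapsets = []
    idx = 0
    for preset in (BENIGN_PRESET, MALIGNANT_PRESET):
        params = replace(preset, n_samples=n_samples, n_lines=n_lines)
        for i in range(n_per_class):
            frame = simulate_frame(params, frame_seed(seed, idx))
            frame.frame_id = f"{params.label}_{i:04d}"
            mapsets.append(build_feature_maps(frame, geometry, hos_cfg))
            idx += 1
    return mapsets


def synthetic_end_to_end(
    seed: int = 0,
    n_train_per_class: int = 20,
    n_test_per_class: int = 10,
    max_epochs: int = 10,
    n_samples: int = 1024,
    n_lines: int = 32,
    run_ablation: bool = True,
) -> dict:
    """Train the full method on synthetic phantoms and evaluate held out.

    Returns a dict with the held-out metrics of the full model (weight
    sharing + attention + similarity constraint), the per-map attention
    importance, the training history, and — when ``run_ablation`` — the
    matching backbone-only model trained on the same split.
    """
    n_total = n_train_per_class + n_test_per_class
    mapsets = make_synthetic_mapsets(
        n_total, seed=seed, n_samples=n_samples, n_lines=n_lines
    )
    train_sets, test_sets = [], []
    for ci in range(2):
        cls = mapsets[ci * n_total : (ci + 1) * n_total]
        train_sets.extend(cls[:n_train_per_class])
        test_sets.extend(cls[n_train_per_class:])
    ds_train = dataset_from_mapsets(train_sets)
    ds_test = dataset_from_mapsets(test_sets)
    train_cfg = TrainConfig(max_epochs=max_epochs, seed=seed)

    model = MSNet(NetConfig(backbone="tinycnn"), seed=seed)
    model, history = train(model, ds_train, None, train_cfg)
    report = evaluate(model, ds_test)
    out = {
        "full": report,
        "history": history,
        "importance": importance_report(model, ds_test),
        "n_train": len(ds_train),
        "n_test": len(ds_test),
    }
    if run_ablation:
        ablated = MSNet(
            NetConfig(backbone="tinycnn", use_fatt=False, use_sm=False),
            seed=seed,
        )
        ablated, _ = train(ablated, ds_train, None, train_cfg)
        out["backbone_only"] = evaluate(ablated, ds_test)
    return out
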