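"""Backbone registry: one runnable CNN plus analytic parameter accounting.

``tinycnn`` is a four-block strided CNN (feature dim 128) small enough to
train on a CPU in tests and demos.  The large standard backbones are
registered with exact trainable-parameter counts derived from their
architecture definitions (conv kernels and batch-norm affine pairs; batch
statistics are not trainable and are excluded), which is all that the
weight-sharing parameter-ratio analysis needs.  Their forward passes
require a pretrained model zoo and are not provided here.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = ["TinyCNN", "backbone_info", "feature_param_count", "BACKBONES"]


# ---------------------------------------------------------------------------
# analytic parameter counts
# ---------------------------------------------------------------------------


def _resnet_feature_params(blocks: tuple[int, ...]) -> int:
    """Trainable parameters of a bottleneck ResNet feature extractor
    (stem + residual stages, global-average-pool output, no classifier)."""
    total = 7 * 7 * 3 * 64  # stem conv, no bias
    total += 2 * 64  # stem BN affine
    in_ch = 64
    for stage, n_blocks in enumerate(blocks):
        w = 64 * 2**stage
        out_ch = 4 * w
        for b in range(n_blocks):
            total += in_ch * w + 2 * w          # 1x1 reduce + BN
            total += 9 * w * w + 2 * w          # 3x3 + BN
            total += w * out_ch + 2 * out_ch    # 1x1 expand + BN
            if b == 0:
                total += in_ch * out_ch + 2 * out_ch  # projection shortcut
            in_ch = out_ch
    return total


def _vgg19_feature_params() -> int:
    """Conv part of VGG-19 (biased 3x3 convs)."""
    cfg = [64, 64, 128, 128, 256, 256, 256, 256,
           512, 512, 512, 512, 512, 512, 512, 512]
    total, in_ch = 0, 3
    for out_ch in cfg:
        total += 9 * in_ch * out_ch + out_ch
        in_ch = out_ch
    return total


_TINY_CHANNELS = (3, 16, 32, 64, 128)


def _tinycnn_params() -> int:
    return sum(
        9 * cin * cout + cout
        for cin, cout in zip(_TINY_CHANNELS[:-1], _TINY_CHANNELS[1:])
    )


#: name -> (feature_param_count or None, feature dim M, runnable flag)
BACKBONES: dict[str, tuple[int | None, int | None, bool]] = {
    "tinycnn": (_tinycnn_params(), 128, True),
    "resnet50": (_resnet_feature_params((3, 4, 6, 3)), 2048, False),
    "resnet101": (_resnet_feature_params((3, 4, 23, 3)), 2048, False),
    "vgg19": (_vgg19_feature_params(), 512, False),
    "inceptionv3": (None, 2048, False),
    "swin": (None, 768, False),
}


def backbone_info(name: str) -> tuple[int, int, bool]:
    """(feature params, feature dim M, runnable) for a registered backbone."""
    if name not in BACKBONES:
        raise ValueError(f"unknown backbone {name!r}; choices: {sorted(BACKBONES)}")
    params, dim, runnable = BACKBONES[name]
    if params is None:
        raise NotImplementedError(
            f"backbone {name!r} requires a pretrained model zoo, which this "
            "installation does not bundle; use tinycnn, resnet50, resnet101 "
            "or vgg19 for parameter accounting"
        )
    return params, dim, runnable


def feature_param_count(name: str) -> int:
    return backbone_info(name)[0]


# ---------------------------------------------------------------------------
# the runnable backbone
# ---------------------------------------------------------------------------


class TinyCNN:
    """Four strided 3x3 conv blocks with ReLU, global average pool.

    Input (B, 3, H, W); output features (B, 128).  Spatial size shrinks by
    2 per block, so a 224x224 input reaches a 14x14 grid before pooling.
    """

    feature_dim = 128

    def __init__(self, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.params: dict[str, Tensor] = {}
        for i, (cin, cout) in enumerate(
            zip(_TINY_CHANNELS[:-1], _TINY_CHANNELS[1:])
        ):
            fan_in = 9 * cin
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, 3, 3))
            self.params[f"conv{i}_w"] = Tensor(w, requires_grad=True)
            self.params[f"conv{i}_b"] = Tensor(
                np.zeros(cout), requires_grad=True
            )

    def forward(self, x: Tensor) -> Tensor:
        h = x
        for i in range(len(_TINY_CHANNELS) - 1):
            h = h.conv2d(
                self.params[f"conv{i}_w"],
                self.params[f"conv{i}_b"],
                stride=2,
                padding=1,
            ).relu()
        return h.mean(axis=3).mean(axis=2)  # global average pool

    def n_params(self) -> int:
        return sum(int(np.prod(p.shape)) for p in self.params.values())
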