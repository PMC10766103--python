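"""Training loop, preprocessing and prediction for the multi-map classifier.

Follows the published schedule: batch size 8, Adam, cosine-annealed
learning rate from 2e-3 down to 1e-4, inputs resized to 3x256x256 then
center-cropped to 3x224x224, early stopping when the validation loss
stops improving.  Training is seeded and fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image

from .maps import MAP_NAMES, FeatureMapSet
from .metrics import MetricsReport, evaluate_scores
from .msnet import MSNet, NetConfig
from .nn.autograd import Tensor

__all__ = [
    "TrainConfig",
    "MapDataset",
    "preprocess",
    "dataset_from_mapsets",
    "train",
    "predict",
    "evaluate",
    "cosine_lr",
    "importance_report",
]

LABEL_TO_INT = {"benign": 0, "malignant": 1}


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 8
    lr_init: float = 0.002
    lr_final: float = 1e-4
    max_epochs: int = 10
    patience: int = 5
    seed: int = 0
    resize_to: int = 256
    crop_to: int = 224
    augment_hflip: bool = False

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.lr_final > self.lr_init:
            raise ValueError("lr_final must be <= lr_init")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


def preprocess(
    image: np.ndarray, resize_to: int = 256, crop_to: int = 224
) -> np.ndarray:
    """8-bit grayscale map image -> float32 (3, crop, crop) network input.

    Bilinear resize to ``resize_to`` square, center crop to ``crop_to``,
    scale to [0, 1], replicate to three channels.
    """
    img = np.asarray(image)
    if img.size == 0:
        raise ValueError("empty image")
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    pil = Image.fromarray(img.astype(np.uint8), mode="L")
    pil = pil.resize((resize_to, resize_to), Image.BILINEAR)
    arr = np.asarray(pil, dtype=np.float32) / 255.0
    off = (resize_to - crop_to) // 2
    arr = arr[off : off + crop_to, off : off + crop_to]
    return np.broadcast_to(arr, (3, crop_to, crop_to)).copy()


@dataclass
class MapDataset:
    """Preprocessed samples: inputs (N, K, 3, H, W), int labels (N,)."""

    x: np.ndarray
    y: np.ndarray
    frame_ids: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return self.x.shape[0]


def dataset_from_mapsets(
    mapsets: list[FeatureMapSet],
    resize_to: int = 256,
    crop_to: int = 224,
) -> MapDataset:
    """Stack the four preprocessed map images of each frame into a sample."""
    xs, ys, ids = [], [], []
    for fm in mapsets:
        sample = np.stack(
            [preprocess(fm.images[name], resize_to, crop_to) for name in MAP_NAMES]
        )
        xs.append(sample)
        if fm.label is None:
            raise ValueError(f"frame {fm.frame_id!r} has no label")
        ys.append(LABEL_TO_INT[fm.label])
        ids.append(fm.frame_id)
    return MapDataset(
        x=np.stack(xs).astype(np.float32),
        y=np.asarray(ys, dtype=int),
        frame_ids=ids,
    )


def cosine_lr(epoch: int, cfg: TrainConfig) -> float:
    """Half-cosine decay from lr_init (epoch 0) to lr_final (last epoch)."""
    if cfg.max_epochs == 1:
        return cfg.lr_init
    t = epoch / (cfg.max_epochs - 1)
    return cfg.lr_final + 0.5 * (cfg.lr_init - cfg.lr_final) * (
        1 + np.cos(np.pi * t)
    )


class Adam:
    """Adam optimizer over the model's named parameter tensors."""

    def __init__(self, params: dict[str, Tensor], beta1=0.9, beta2=0.999,
                 eps=1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros(p.shape, dtype=np.float32) for k, p in params.items()}
        self.v = {k: np.zeros(p.shape, dtype=np.float32) for k, p in params.items()}
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            p.data = p.data - lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


def _batch_loss(model: MSNet, x: np.ndarray, y: np.ndarray) -> float:
    loss, _ = model.loss_tensors(Tensor(x), y)
    return float(loss.data)


def train(
    model: MSNet,
    train_data: MapDataset,
    val_data: MapDataset | None,
    cfg: TrainConfig,
):
    """Train in place; returns (model, history).

    history is a list of per-epoch dicts (lr, train_loss, val_loss).  When
    validation data is supplied, training stops once the validation loss
    has not improved for ``patience`` consecutive epochs and the
    best-validation parameters are restored.
    """
    if len(np.unique(train_data.y)) < 2:
        raise ValueError("training data must contain both classes")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.params)
    history: list[dict] = []
    best_val = np.inf
    best_state = None
    stall = 0
    for epoch in range(cfg.max_epochs):
        lr = cosine_lr(epoch, cfg)
        order = rng.permutation(len(train_data))
        losses = []
        for b0 in range(0, len(order), cfg.batch_size):
            idx = order[b0 : b0 + cfg.batch_size]
            xb = train_data.x[idx]
            if cfg.augment_hflip:
                flip = rng.random(len(idx)) < 0.5
                xb = xb.copy()
                xb[flip] = xb[flip, :, :, :, ::-1]
            loss, _ = model.loss_tensors(Tensor(xb), train_data.y[idx])
            opt.zero_grad()
            loss.backward()
            opt.step(lr)
            losses.append(float(loss.data))
        rec = {"epoch": epoch, "lr": float(lr),
               "train_loss": float(np.mean(losses))}
        if val_data is not None and len(val_data) > 0:
            val_loss = _batch_loss(model, val_data.x, val_data.y)
            rec["val_loss"] = val_loss
            if val_loss < best_val - 1e-6:
                best_val = val_loss
                best_state = model.state_dict()
                stall = 0
            else:
                stall += 1
        history.append(rec)
        if val_data is not None and stall >= cfg.patience:
            break
    if best_state is not None:
        model.load_state_dict(best_state)
    return model, history


def predict(model: MSNet, data: MapDataset, batch_size: int = 8):
    """Positive-class scores and per-frame attention weights (eval mode)."""
    scores = np.empty(len(data))
    weights = np.empty((len(data), model.cfg.K))
    for b0 in range(0, len(data), batch_size):
        x = data.x[b0 : b0 + batch_size]
        prob, att = model.forward(x)
        scores[b0 : b0 + x.shape[0]] = prob
        weights[b0 : b0 + x.shape[0]] = att.a_k
    return scores, weights


def evaluate(
    model: MSNet, data: MapDataset, threshold: float = 0.5
) -> MetricsReport:
    scores, _ = predict(model, data)
    return evaluate_scores(scores, data.y, threshold)


def importance_report(model: MSNet, data: MapDataset) -> dict[str, float]:
    """Mean attention weight per map over a dataset (sums to 1)."""
    _, weights = predict(model, data)
    mean_w = weights.mean(axis=0)
    return {name: float(w) for name, w in zip(MAP_NAMES, mean_w)}
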