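"""Weight-sharing multi-map classifier with gated attention and a
cosine-similarity constraint.

The model routes K feature-map images through one shared backbone (or K
independent copies, for the ablation), producing one M-dimensional feature
vector h_k per map.  A gated attention module scores each vector,

    s_k = w^T ( tanh(V h_k) * sigm(U h_k) ),    a = softmax(s),

and fuses them into z = sum_k a_k h_k, which a linear head maps to two
class logits.  The similarity-constraint (SM) auxiliary loss pushes
L2-normalized branch embeddings toward the prototype of their own map type
and away from the other types, using a temperature-scaled softmax over
cosine similarities.  Weight sharing is what makes the four-branch model
dramatically smaller than four independent backbones; ``shared_ratio``
quantifies that claim exactly from the architecture definitions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .nn.autograd import Tensor, stack
from .nn.backbones import TinyCNN, backbone_info

__all__ = [
    "NetConfig",
    "AttentionOutput",
    "LossReport",
    "MSNet",
    "gated_attention",
    "attention_loss",
    "cosine_similarity",
    "sm_loss",
    "total_loss",
    "count_parameters",
    "shared_ratio",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NetConfig:
    """Architecture + loss configuration.

    K is the number of input maps, M the backbone feature dimension
    (resolved from the backbone when left at None), L the attention hidden
    width.  ``lambda_sm`` weights the SM loss in the total objective and
    ``tau`` is its softmax temperature.
    """

    backbone: str = "resnet50"
    K: int = 4
    M: int | None = None
    L: int = 256
    share_weights: bool = True
    use_fatt: bool = True
    use_sm: bool = True
    lambda_sm: float = 0.1
    tau: float = 0.1
    attention_bias: bool = False
    pretrained: bool = False
    n_classes: int = 2

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.lambda_sm < 0:
            raise ValueError("lambda_sm must be >= 0")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")

    def resolved_M(self) -> int:
        return self.M if self.M is not None else backbone_info(self.backbone)[1]


@dataclass
class AttentionOutput:
    """Per-map attention weights (simplex) and the fused feature vector."""

    a_k: np.ndarray
    z_dl: np.ndarray


@dataclass
class LossReport:
    loss_att: float
    loss_sm: float
    total: float
    batch_size: int


# ---------------------------------------------------------------------------
# losses as plain functions (numpy surface)
# ---------------------------------------------------------------------------


def attention_loss(
    p: np.ndarray, y: np.ndarray, negative_convention: bool = False
) -> float:
    """Mean binary cross-entropy of predicted positive-class probabilities.

    ``negative_convention=True`` reads p as the negative-class probability
    (the strictly literal form of the published loss), which simply swaps
    p for 1-p.
    """
    p = np.asarray(p, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError("p and y must share a shape")
    if np.any((p <= 0) | (p >= 1)):
        logger.warning("probabilities outside (0,1); clamping at 1e-7")
    p = np.clip(p, 1e-7, 1 - 1e-7)
    if negative_convention:
        p = 1.0 - p
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def cosine_similarity(f_i: np.ndarray, f_j: np.ndarray) -> float:
    """Cosine of the angle between two nonzero vectors."""
    f_i = np.asarray(f_i, dtype=np.float64)
    f_j = np.asarray(f_j, dtype=np.float64)
    ni, nj = np.linalg.norm(f_i), np.linalg.norm(f_j)
    if ni == 0 or nj == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(f_i, f_j) / (ni * nj))


def _sm_terms(P: np.ndarray, types: np.ndarray, type_ids: np.ndarray) -> float:
    own = P[np.arange(P.shape[0]), types]
    loss = -np.sum(np.log(np.clip(own, 1e-12, None)))
    mask = type_ids[None, :] != types[:, None]
    loss -= np.sum(np.log(np.clip(1.0 - P, 1e-12, None)) * mask)
    return float(loss)


def sm_loss(embeddings: np.ndarray, map_types, tau: float = 0.1) -> float:
    """Similarity-constraint loss over a batch of branch embeddings.

    ``embeddings`` is (n, M); ``map_types`` labels each row with its map
    type.  Each row's recognition probabilities P(j|x) form a
    temperature-tau softmax over cosine similarities to the per-type
    prototypes (re-normalized batch means).  The loss sums -log P(own type)
    plus -log(1 - P(other types)) over all rows.
    """
    f = np.asarray(embeddings, dtype=np.float64)
    if f.ndim != 2:
        raise ValueError("embeddings must be (n, M)")
    norms = np.linalg.norm(f, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero embedding vector")
    f = f / norms
    types_arr = np.asarray(map_types)
    uniq = np.unique(types_arr)
    if uniq.size < 2:
        raise ValueError("sm_loss requires at least two map types in the batch")
    protos = np.stack([f[types_arr == t].mean(axis=0) for t in uniq])
    protos /= np.linalg.norm(protos, axis=1, keepdims=True)
    sims = f @ protos.T / tau
    sims -= sims.max(axis=1, keepdims=True)
    P = np.exp(sims)
    P /= P.sum(axis=1, keepdims=True)
    type_idx = np.searchsorted(uniq, types_arr)
    return _sm_terms(P, type_idx, np.arange(uniq.size))


def total_loss(loss_att: float, loss_sm: float, cfg: NetConfig) -> LossReport:
    """Combine the classification and similarity losses per the config."""
    if not (np.isfinite(loss_att) and np.isfinite(loss_sm)):
        raise ValueError("loss components must be finite")
    tot = loss_att + (cfg.lambda_sm * loss_sm if cfg.use_sm else 0.0)
    return LossReport(
        loss_att=float(loss_att),
        loss_sm=float(loss_sm) if cfg.use_sm else 0.0,
        total=float(tot),
        batch_size=0,
    )


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------


def _init_linear(rng, out_dim: int, in_dim: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(1.0 / in_dim), size=(out_dim, in_dim))


class MSNet:
    """Four-branch weight-sharing classifier (runnable with tinycnn)."""

    def __init__(self, cfg: NetConfig, seed: int = 0):
        if cfg.backbone != "tinycnn":
            params, dim, runnable = backbone_info(cfg.backbone)
            if not runnable:
                raise NotImplementedError(
                    f"backbone {cfg.backbone!r} is registered for parameter "
                    "accounting only; use backbone='tinycnn' to train"
                )
        if cfg.pretrained:
            raise NotImplementedError(
                "no pretrained weights are bundled with this package"
            )
        self.cfg = cfg
        self.M = cfg.resolved_M()
        rng = np.random.default_rng(seed)
        n_backbones = 1 if cfg.share_weights else cfg.K
        self.backbones = [
            TinyCNN(seed=int(rng.integers(2**31))) for _ in range(n_backbones)
        ]
        self.params: dict[str, Tensor] = {}
        for i, bb in enumerate(self.backbones):
            for name, p in bb.params.items():
                self.params[f"bb{i}.{name}"] = p
        L, M = cfg.L, self.M
        self.V = Tensor(_init_linear(rng, L, M), requires_grad=True)
        self.U = Tensor(_init_linear(rng, L, M), requires_grad=True)
        self.w = Tensor(_init_linear(rng, 1, L), requires_grad=True)
        self.params.update({"att.V": self.V, "att.U": self.U, "att.w": self.w})
        if cfg.attention_bias:
            self.Vb = Tensor(np.zeros(L), requires_grad=True)
            self.Ub = Tensor(np.zeros(L), requires_grad=True)
            self.params.update({"att.Vb": self.Vb, "att.Ub": self.Ub})
        self.head_w = Tensor(
            _init_linear(rng, cfg.n_classes, M), requires_grad=True
        )
        self.head_b = Tensor(np.zeros(cfg.n_classes), requires_grad=True)
        self.params.update({"head.w": self.head_w, "head.b": self.head_b})

    # -- forward pieces ------------------------------------------------------
    def backbone_features(self, x: Tensor) -> Tensor:
        """(B, K, C, H, W) images -> (B, K, M) feature bank."""
        B, K = x.shape[0], x.shape[1]
        if K != self.cfg.K:
            raise ValueError(f"expected {self.cfg.K} branches, got {K}")
        if self.cfg.share_weights:
            flat = x.reshape(B * K, *x.shape[2:])
            h = self.backbones[0].forward(flat)
            return h.reshape(B, K, self.M)
        branches = []
        for k in range(K):
            xk = x.reshape(B, K, -1)  # slice branch via one-hot contraction
            onehot = np.zeros((K, 1), dtype=np.float32)
            onehot[k] = 1.0
            # differentiable branch selection: (B, K, F) x (K, 1) -> (B, F)
            sel = (xk * Tensor(onehot[None, :, :])).sum(axis=1)
            sel = sel.reshape(B, *x.shape[2:])
            branches.append(self.backbones[k].forward(sel))
        return stack(branches, axis=1)

    def _attention(self, H: Tensor) -> tuple[Tensor, Tensor]:
        B, K, M = H.shape
        flat = H.reshape(B * K, M)
        t = flat @ self.V.T
        g = flat @ self.U.T
        if self.cfg.attention_bias:
            t = t + self.Vb
            g = g + self.Ub
        s = (t.tanh() * g.sigmoid()) @ self.w.T  # (B*K, 1)
        s = s.reshape(B, K)
        if not self.cfg.use_fatt:
            a = Tensor(np.full((B, K), 1.0 / K, dtype=np.float32))
        else:
            a = s.softmax(axis=1)
        z = (a.reshape(B, K, 1) * H).sum(axis=1)
        return a, z

    def forward_tensors(self, x: Tensor):
        """Full differentiable forward: returns (logits, a, H, f)."""
        H = self.backbone_features(x)
        a, z = self._attention(H)
        logits = z @ self.head_w.T + self.head_b
        f = H.l2_normalize(axis=-1)
        return logits, a, H, f

    def forward(self, images: np.ndarray):
        """Eval-mode forward on one sample or a batch of K-map stacks.

        Accepts (K, C, H, W) or (B, K, C, H, W); returns positive-class
        probabilities and the attention output for interpretability.
        """
        x = np.asarray(images, dtype=np.float32)
        single = x.ndim == 4
        if single:
            x = x[None]
        if x.ndim != 5:
            raise ValueError("expected (B, K, C, H, W) or (K, C, H, W) input")
        logits, a, H, _ = self.forward_tensors(Tensor(x))
        prob = _np_softmax(logits.data)[:, 1]
        z = (a.data[:, :, None] * H.data).sum(axis=1)
        if single:
            return float(prob[0]), AttentionOutput(a_k=a.data[0], z_dl=z[0])
        return prob, AttentionOutput(a_k=a.data, z_dl=z)

    # -- training loss -------------------------------------------------------
    def loss_tensors(self, x: Tensor, y: np.ndarray):
        """Differentiable total loss for a labeled batch."""
        logits, a, H, f = self.forward_tensors(x)
        B = logits.shape[0]
        logp = logits.log_softmax(axis=1)
        onehot = np.zeros((B, self.cfg.n_classes), dtype=np.float32)
        onehot[np.arange(B), np.asarray(y, dtype=int)] = 1.0
        loss_att = -(logp * Tensor(onehot)).sum() * (1.0 / B)
        if self.cfg.use_sm and self.cfg.K >= 2:
            loss_sm = _sm_loss_tensor(f, self.cfg.tau)
            loss = loss_att + loss_sm * self.cfg.lambda_sm
        else:
            loss_sm = Tensor(0.0)
            loss = loss_att
        report = LossReport(
            loss_att=float(loss_att.data),
            loss_sm=float(loss_sm.data),
            total=float(loss.data),
            batch_size=B,
        )
        return loss, report

    def n_params(self) -> int:
        return sum(int(np.prod(p.shape)) for p in self.params.values())

    # -- (de)serialization -----------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, p in self.params.items():
            p.data = np.asarray(state[k], dtype=np.float32).reshape(p.shape)


def _np_softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    e = np.exp(x - x.max(axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


def _sm_loss_tensor(f: Tensor, tau: float) -> Tensor:
    """SM loss on normalized embeddings f (B, K, M), differentiable."""
    B, K, M = f.shape
    protos = f.mean(axis=0).l2_normalize(axis=-1)  # (K, M)
    sims = f.reshape(B * K, M) @ protos.T  # (B*K, K)
    logP = (sims * (1.0 / tau)).log_softmax(axis=1)
    P = logP.exp()
    eye = np.tile(np.eye(K, dtype=np.float32), (B, 1))
    own = -(logP * Tensor(eye)).sum()
    other = -((1.0 - P + 1e-12).log() * Tensor(1.0 - eye)).sum()
    return own + other


def gated_attention(
    bank: np.ndarray, V: np.ndarray, U: np.ndarray, w: np.ndarray
) -> AttentionOutput:
    """Stateless gated-attention pooling of a (K, M) feature bank.

    s_k = w^T(tanh(V h_k) * sigm(U h_k)); a = softmax(s); z = sum a_k h_k.
    """
    H = np.asarray(bank, dtype=np.float64)
    if H.ndim != 2:
        raise ValueError("bank must be (K, M)")
    V = np.asarray(V)
    U = np.asarray(U)
    w = np.asarray(w).reshape(-1)
    if V.shape != U.shape or V.shape[0] != w.size or V.shape[1] != H.shape[1]:
        raise ValueError("attention parameter shapes inconsistent with bank")
    s = (np.tanh(H @ V.T) * (1 / (1 + np.exp(-(H @ U.T))))) @ w
    a = _np_softmax(s)
    z = a @ H
    return AttentionOutput(a_k=a, z_dl=z)


# ---------------------------------------------------------------------------
# parameter accounting
# ---------------------------------------------------------------------------


def count_parameters(cfg: NetConfig) -> int:
    """Trainable parameters of the full model under ``cfg``.

    Uses the analytic backbone registry, so it works for the large
    backbones without instantiating them.
    """
    bb_params, M_default, _ = backbone_info(cfg.backbone)
    M = cfg.M if cfg.M is not None else M_default
    n_backbones = 1 if cfg.share_weights else cfg.K
    total = n_backbones * bb_params
    if cfg.use_fatt:
        total += 2 * cfg.L * M + cfg.L  # V, U, w
        if cfg.attention_bias:
            total += 2 * cfg.L
    total += M * cfg.n_classes + cfg.n_classes  # linear head
    return total


def shared_ratio(cfg: NetConfig) -> float:
    """100 x params(shared) / params(K independent backbones, same head)."""
    shared = count_parameters(replace(cfg, share_weights=True))
    independent = count_parameters(replace(cfg, share_weights=False))
    return 100.0 * shared / independent
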