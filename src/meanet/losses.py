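"""Training objectives: soft Dice, binary cross-entropy, joint loss.

The joint objective is L_total = alpha * L_Dice + (1 - alpha) * L_BCE
with alpha = 0.3 by default.  In the default supervision split the Dice
term supervises the edge prediction (foreground boundaries are a tiny
class, where overlap losses behave well) and the BCE term supervises
the final segmentation map; a "per_head" mode applies the full joint
loss to each head instead.

All functions operate on autodiff tensors so they can drive training,
but accept plain arrays for direct evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tensor import Tensor


@dataclass
class LossConfig:
    """alpha: Dice weight of the joint loss; eps values guard divisions/logs."""

    alpha: float = 0.3
    smooth_eps: float = 1e-6
    clip_eps: float = 1e-7
    supervision_mode: str = "split"  # "split" | "per_head"

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.smooth_eps <= 0 or self.clip_eps <= 0:
            raise ValueError("smooth_eps and clip_eps must be positive")
        if self.supervision_mode not in ("split", "per_head"):
            raise ValueError(f"unknown supervision_mode {self.supervision_mode!r}")


@dataclass
class SupervisionBundle:
    """Predictions and targets for one training batch.

    ``edge_pred``/``edge_gt`` may be None when the network runs without
    its edge module; the Dice term then falls back to the segmentation
    head so the joint objective remains defined.
    """

    seg_pred: Tensor | np.ndarray
    seg_gt: np.ndarray
    edge_pred: Tensor | np.ndarray | None = None
    edge_gt: np.ndarray | None = None


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def _check_pair(p: Tensor, g: np.ndarray) -> None:
    if p.shape != g.shape:
        raise ValueError(f"prediction shape {p.shape} != target shape {g.shape}")
    if p.data.size == 0:
        raise ValueError("empty prediction/target")


def _per_sample_flatten(t: Tensor) -> Tensor:
    """Flatten to (batch, pixels).

    Only 4-d (B, C, H, W) inputs are treated as batches; 1-d, 2-d (H, W)
    and 3-d (C, H, W) arrays are single samples.
    """
    if t.ndim == 4:
        return t.reshape(t.shape[0], -1)
    return t.reshape(1, -1)


def dice_loss(pred, target, smooth_eps: float = 1e-6) -> Tensor:
    """Soft Dice loss: 1 - 2*sum(p*g) / (sum(p^2) + sum(g^2) + eps).

    Computed per sample over flattened pixels, then averaged over the
    batch, so batch size does not rescale the loss.
    """
    p = _as_tensor(pred)
    g = np.asarray(target, dtype=p.data.dtype)
    _check_pair(p, g)
    pf = _per_sample_flatten(p)
    gf = g.reshape(pf.shape)
    inter = (pf * Tensor(gf)).sum(axis=1)
    denom = (pf * pf).sum(axis=1) + Tensor((gf * gf).sum(axis=1) + smooth_eps)
    return (1.0 - 2.0 * inter / denom).mean()


def bce_loss(pred, target, clip_eps: float = 1e-7) -> Tensor:
    """Pixel-mean binary cross-entropy with probability clipping."""
    p = _as_tensor(pred)
    g = np.asarray(target, dtype=p.data.dtype)
    _check_pair(p, g)
    pc = p.clip(clip_eps, 1.0 - clip_eps)
    gt = Tensor(g)
    ll = gt * pc.log() + Tensor(1.0 - g) * (1.0 - pc).log()
    return -ll.mean()


def joint_loss(bundle: SupervisionBundle,
               cfg: LossConfig | None = None) -> tuple[Tensor, Tensor, Tensor]:
    """Joint objective; returns (total, dice_term, bce_term).

    Default split mode: Dice on the edge head, BCE on the segmentation
    head, combined as alpha * dice + (1 - alpha) * bce.  In "per_head"
    mode each available head receives the full joint loss and the heads
    are averaged; the returned dice/bce terms are then head averages.
    """
    cfg = cfg or LossConfig()
    seg_pred = bundle.seg_pred
    if bundle.edge_pred is not None and bundle.edge_gt is None:
        raise ValueError("edge_pred given without edge_gt")
    has_edge = bundle.edge_pred is not None
    if cfg.supervision_mode == "per_head":
        heads = [(seg_pred, bundle.seg_gt)]
        if has_edge:
            heads.append((bundle.edge_pred, bundle.edge_gt))
        d_terms = [dice_loss(p, g, cfg.smooth_eps) for p, g in heads]
        b_terms = [bce_loss(p, g, cfg.clip_eps) for p, g in heads]
        dice_term = sum(d_terms[1:], d_terms[0]) * (1.0 / len(heads))
        bce_term = sum(b_terms[1:], b_terms[0]) * (1.0 / len(heads))
    else:
        edge_pred = bundle.edge_pred if has_edge else seg_pred
        edge_gt = bundle.edge_gt if has_edge else bundle.seg_gt
        dice_term = dice_loss(edge_pred, edge_gt, cfg.smooth_eps)
        bce_term = bce_loss(seg_pred, bundle.seg_gt, cfg.clip_eps)
    total = cfg.alpha * dice_term + (1.0 - cfg.alpha) * bce_term
    return total, dice_term, bce_term
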