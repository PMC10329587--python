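"""Supervised loss components and the weighted combined objective.

Focal loss (a hard-example-weighted cross-entropy), the Tversky loss (a
generalized soft Dice with separate false-negative / false-positive weights),
the negative log of the soft intersection-over-union, and an entropy
regularizer on the predicted probability map.  The combined objective adds the
contrastive-distillation term with its own weight; setting any weight to zero
removes that component exactly.

All losses accept either plain arrays (returning floats) or autodiff tensors
(returning differentiable scalars); probability maps are (C, H, W) or
(N, C, H, W) with integer {0, 1} target masks of matching spatial shape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._nn import Tensor, astensor

__all__ = [
    "LossWeights",
    "LossBreakdown",
    "focal_loss",
    "tversky_loss",
    "log_iou_loss",
    "entropy_loss",
    "combined_objective",
]

_EPS = 1e-6


@dataclass(frozen=True)
class LossWeights:
    w_cd: float = 1.0
    w_focal: float = 1.0
    w_tversky: float = 1.0
    w_logiou: float = 1.0
    # chosen so the weighted entropy term stays below 0.02 for every binary
    # map (0.028 * ln 2 ~= 0.0194)
    w_entropy: float = 0.028

    def __post_init__(self) -> None:
        vals = (self.w_cd, self.w_focal, self.w_tversky, self.w_logiou, self.w_entropy)
        if any(not np.isfinite(v) or v < 0 for v in vals):
            raise ValueError("loss weights must be finite and non-negative")


@dataclass(frozen=True)
class LossBreakdown:
    """Unweighted per-component values and the weighted total."""

    cd: float
    focal: float
    tversky: float
    logiou: float
    entropy: float
    total: float

    def recompute_total(self, weights: LossWeights) -> float:
        return (
            weights.w_cd * self.cd
            + weights.w_focal * self.focal
            + weights.w_tversky * self.tversky
            + weights.w_logiou * self.logiou
            + weights.w_entropy * self.entropy
        )


def _prep(probs, target):
    """Normalize to tensor (N, C, H, W) probs and (N, H, W) integer target."""
    p = astensor(probs)
    if p.ndim == 3:
        p = p.reshape(1, *p.shape)
    if p.ndim != 4:
        raise ValueError("probability map must be (C, H, W) or (N, C, H, W)")
    t = np.asarray(target)
    if t.ndim == 2:
        t = t[None]
    if t.shape != (p.shape[0], p.shape[2], p.shape[3]):
        raise ValueError(f"shape mismatch: target {t.shape} vs probs {p.shape}")
    t = t.astype(np.int64)
    return p, t


def _onehot(t: np.ndarray, num_classes: int) -> np.ndarray:
    return np.moveaxis(np.eye(num_classes)[t], -1, 1)  # (N, C, H, W)


def _ret(value: Tensor, tensor_in: bool):
    return value if tensor_in else float(value.data)


def focal_loss(probs, target, gamma: float = 2.0, alpha: float = 0.25):
    """Mean over pixels of -alpha * (1 - p_t)^gamma * log(p_t).

    With gamma=0, alpha=1 this reduces to plain cross-entropy.
    """
    if gamma < 0 or not 0 < alpha <= 1:
        raise ValueError("gamma must be >= 0 and alpha in (0, 1]")
    tensor_in = isinstance(probs, Tensor)
    p, t = _prep(probs, target)
    onehot = _onehot(t, p.shape[1]).astype(p.data.dtype)
    p_t = (p * Tensor(onehot)).sum(axis=1).clip(_EPS, 1.0)
    loss = -(alpha * ((1.0 - p_t) ** gamma) * p_t.log()).mean()
    return _ret(loss, tensor_in)


def tversky_loss(probs, target, alpha: float = 0.5, beta: float = 0.5):
    """1 - TP / (TP + alpha*FN + beta*FP + eps) with soft foreground counts.

    alpha = beta = 0.5 recovers the soft Dice loss.
    """
    if alpha < 0 or beta < 0 or alpha + beta == 0:
        raise ValueError("alpha, beta must be >= 0 and not both 0")
    tensor_in = isinstance(probs, Tensor)
    p, t = _prep(probs, target)
    fg = (t == 1).astype(p.data.dtype)
    p_fg = _select_channel(p, 1)
    tp = (p_fg * fg).sum()
    fn = ((1.0 - p_fg) * fg).sum()
    fp = (p_fg * (1.0 - fg)).sum()
    loss = 1.0 - tp / (tp + alpha * fn + beta * fp + _EPS)
    return _ret(loss, tensor_in)


def _select_channel(p: Tensor, c: int) -> Tensor:
    sel = np.zeros((1, p.shape[1], 1, 1), dtype=p.data.dtype)
    sel[0, c, 0, 0] = 1.0
    return (p * Tensor(sel)).sum(axis=1)


def log_iou_loss(probs, target, eps: float = _EPS):
    """-log((I + eps) / (U + eps)) with soft intersection and union."""
    tensor_in = isinstance(probs, Tensor)
    p, t = _prep(probs, target)
    fg = (t == 1).astype(p.data.dtype)
    p_fg = _select_channel(p, 1)
    inter = (p_fg * fg).sum()
    union = (p_fg + fg - p_fg * fg).sum()
    loss = -(((inter + eps) / (union + eps)).log())
    return _ret(loss, tensor_in)


def entropy_loss(probs):
    """Mean per-pixel Shannon entropy (natural log) of the probability map."""
    tensor_in = isinstance(probs, Tensor)
    p = astensor(probs)
    if p.ndim == 3:
        p = p.reshape(1, *p.shape)
    pc = p.clip(_EPS, 1.0)
    loss = -(pc * pc.log()).sum(axis=1).mean()
    return _ret(loss, tensor_in)


def combined_objective(
    probs,
    target,
    cd_value,
    weights: LossWeights,
    focal_gamma: float = 2.0,
    focal_alpha: float = 0.25,
    tversky_alpha: float = 0.5,
    tversky_beta: float = 0.5,
):
    """Evaluate every component and the weighted total.

    Returns ``(breakdown, total)``: the breakdown reports unweighted floats;
    ``total`` is a differentiable tensor when the inputs are tensors, else a
    float equal to ``breakdown.total``.  Zero-weight components still appear
    in the breakdown but contribute nothing to the total.
    """
    tensor_in = isinstance(probs, Tensor) or isinstance(cd_value, Tensor)
    f = focal_loss(probs, target, gamma=focal_gamma, alpha=focal_alpha)
    tv = tversky_loss(probs, target, alpha=tversky_alpha, beta=tversky_beta)
    li = log_iou_loss(probs, target)
    en = entropy_loss(probs)
    cd = cd_value if cd_value is not None else 0.0
    total = (
        weights.w_cd * astensor(cd)
        + weights.w_focal * astensor(f)
        + weights.w_tversky * astensor(tv)
        + weights.w_logiou * astensor(li)
        + weights.w_entropy * astensor(en)
    )

    def val(x):
        return float(x.data) if isinstance(x, Tensor) else float(x)

    breakdown = LossBreakdown(
        cd=val(cd), focal=val(f), tversky=val(tv), logiou=val(li), entropy=val(en),
        total=val(total),
    )
    return breakdown, (total if tensor_in else breakdown.total)
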