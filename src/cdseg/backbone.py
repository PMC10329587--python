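"""Frozen dense feature extractors.

The distillation teacher is a frozen feature extractor mapping a preprocessed
2D slice to a dense C x H x W feature grid with a fixed spatial stride.  Two
implementations share one contract:

* :func:`tiny_backbone` — a small randomly-initialized convolutional pyramid,
  frozen at construction.  It is the default everywhere: deterministic, CPU
  cheap, and download-free.
* :func:`vit_backbone` — an adapter for self-supervised Vision Transformer
  weights stored as an ``.npz`` checkpoint; the stride equals the patch size
  and features are the final-block patch tokens reshaped to a grid (class
  token dropped).  Strictly optional: a missing or mismatched checkpoint
  raises :class:`WeightsUnavailableError`, never a silent random init.

Frozenness is observable: ``parameter_digest`` hashes every parameter array
and must be invariant under any number of pipeline optimization steps.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._nn import Tensor, conv2d, he_init, parameter_digest, resize_bilinear

__all__ = [
    "FeatureExtractorSpec",
    "WeightsUnavailableError",
    "FeatureExtractor",
    "TinyBackbone",
    "ViTBackbone",
    "tiny_backbone",
    "vit_backbone",
    "extract_features",
    "VIT_VARIANTS",
]


class WeightsUnavailableError(RuntimeError):
    """Requested pretrained weights are missing or do not match the variant."""


@dataclass(frozen=True)
class FeatureExtractorSpec:
    name: str
    stride: int
    channels: int
    frozen: bool
    parameter_digest: str

    def __post_init__(self) -> None:
        if not self.frozen:
            raise ValueError("distillation backbones must be frozen")


class FeatureExtractor:
    """Base contract: `extract` maps (N, H, W) slices to (N, C, H/S, W/S)."""

    spec: FeatureExtractorSpec

    def _forward(self, batch: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def extract(self, slices: np.ndarray) -> np.ndarray:
        slices = np.asarray(slices)
        if slices.ndim == 2:
            return self.extract(slices[None])[0]
        if slices.ndim != 3:
            raise ValueError("expected (H, W) or (N, H, W) input")
        s = self.spec.stride
        h, w = slices.shape[1:]
        if h % s or w % s:
            raise ValueError(
                f"incompatible size {h}x{w}: spatial dims must be multiples of {s}"
            )
        return self._forward(slices)


class TinyBackbone(FeatureExtractor):
    """Random frozen conv pyramid: log2(stride) blocks of stride-2 conv + ReLU.

    The output is a low-temperature softmax over channels, so each spatial
    position carries a near-categorical "local pattern class" indicator.
    This gives the extractor the cluster-structured dense correspondences the
    distillation scheme presumes of its teacher (a semantic backbone maps
    same-tissue positions to nearly identical features); a plain linear
    random feature map would instead yield a smooth similarity continuum.
    """

    SOFTMAX_TEMPERATURE = 0.1

    def __init__(self, seed: int, channels: int = 32, stride: int = 8):
        if stride < 1 or stride & (stride - 1):
            raise ValueError("stride must be a power of two")
        n_stages = max(1, int(np.log2(stride))) if stride > 1 else 1
        rng = np.random.default_rng(seed)
        widths = np.linspace(8, channels, n_stages).round().astype(int).tolist()
        widths[-1] = channels
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        cin = 1
        for cout in widths:
            self.weights.append(he_init(rng, (cout, cin, 3, 3), cin * 9, np.float64))
            self.biases.append(rng.normal(0, 0.1, cout))
            cin = cout
        self._stride_per_stage = 2 if stride > 1 else 1
        digest = parameter_digest(self.weights + self.biases)
        self.spec = FeatureExtractorSpec(
            name=f"tiny-c{channels}-s{stride}",
            stride=stride,
            channels=channels,
            frozen=True,
            parameter_digest=digest,
        )

    def _forward(self, batch: np.ndarray) -> np.ndarray:
        x = Tensor(batch[:, None].astype(np.float64))
        for w, b in zip(self.weights, self.biases):
            x = conv2d(x, Tensor(w), Tensor(b), stride=self._stride_per_stage, pad=1)
            x = x.relu()
        z = x.data / self.SOFTMAX_TEMPERATURE
        e = np.exp(z - z.max(axis=1, keepdims=True))
        return e / e.sum(axis=1, keepdims=True)


VIT_VARIANTS = {
    "small/16": dict(patch=16, dim=384, depth=12, heads=6),
    "small/8": dict(patch=8, dim=384, depth=12, heads=6),
    "base/16": dict(patch=16, dim=768, depth=12, heads=12),
    "base/8": dict(patch=8, dim=768, depth=12, heads=12),
}


def _layer_norm(x: np.ndarray, g: np.ndarray, b: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    mu = x.mean(-1, keepdims=True)
    sd = x.var(-1, keepdims=True)
    return (x - mu) / np.sqrt(sd + eps) * g + b


def _gelu(x: np.ndarray) -> np.ndarray:
    return 0.5 * x * (1.0 + np.tanh(np.sqrt(2 / np.pi) * (x + 0.044715 * x**3)))


class ViTBackbone(FeatureExtractor):
    """Frozen ViT encoder (numpy forward) over npz weights.

    Expected arrays per block ``i``: ``blocks.{i}.norm1.{weight,bias}``,
    ``blocks.{i}.attn.qkv.{weight,bias}``, ``blocks.{i}.attn.proj.{weight,bias}``,
    ``blocks.{i}.norm2.{weight,bias}``, ``blocks.{i}.mlp.fc1.{weight,bias}``,
    ``blocks.{i}.mlp.fc2.{weight,bias}``; plus ``patch_embed.proj.weight``
    (D, Cin, P, P), ``patch_embed.proj.bias``, ``cls_token`` (1, 1, D),
    ``pos_embed`` (1, 1+G*G, D), ``norm.weight``, ``norm.bias``.
    Linear weights use the (out, in) convention.
    """

    def __init__(self, variant: str, weights_path: str | Path, feature_layer: int = -1):
        if variant not in VIT_VARIANTS:
            raise ValueError(f"unknown ViT variant {variant!r}")
        cfg = VIT_VARIANTS[variant]
        path = Path(weights_path)
        if not path.exists():
            raise WeightsUnavailableError(f"weights unavailable: {path} does not exist")
        try:
            self.w = {k: np.asarray(v, dtype=np.float64) for k, v in np.load(path).items()}
        except Exception as exc:
            raise WeightsUnavailableError(f"weights unavailable: cannot read {path}: {exc}")
        pw = self.w.get("patch_embed.proj.weight")
        if pw is None or pw.shape[0] != cfg["dim"] or pw.shape[2] != cfg["patch"]:
            raise WeightsUnavailableError(
                f"weights unavailable: checkpoint does not match variant {variant}"
            )
        self.depth = cfg["depth"]
        for i in range(self.depth):
            if f"blocks.{i}.attn.qkv.weight" not in self.w:
                raise WeightsUnavailableError(
                    f"weights unavailable: missing block {i} in checkpoint"
                )
        self.heads = cfg["heads"]
        self.feature_layer = feature_layer
        self.in_chans = int(pw.shape[1])
        self.spec = FeatureExtractorSpec(
            name=f"vit-{variant.replace('/', '-')}",
            stride=cfg["patch"],
            channels=cfg["dim"],
            frozen=True,
            parameter_digest=parameter_digest(
                [self.w[k] for k in sorted(self.w)]
            ),
        )

    def _pos_embed(self, grid: tuple[int, int]) -> np.ndarray:
        pe = self.w["pos_embed"]  # (1, 1+G*G, D)
        cls_pe, patch_pe = pe[:, :1], pe[0, 1:]
        g = int(round(np.sqrt(patch_pe.shape[0])))
        if (g, g) != grid:
            grid_pe = patch_pe.reshape(g, g, -1).transpose(2, 0, 1)
            grid_pe = np.asarray(resize_bilinear(grid_pe, grid))
            patch_pe = grid_pe.transpose(1, 2, 0).reshape(grid[0] * grid[1], -1)
        return np.concatenate([cls_pe[0], patch_pe], axis=0)

    def _forward(self, batch: np.ndarray) -> np.ndarray:
        p = self.spec.stride
        n, h, w = batch.shape
        gh, gw = h // p, w // p
        x = np.repeat(batch[:, None].astype(np.float64), self.in_chans, axis=1)
        pw = self.w["patch_embed.proj.weight"].reshape(self.spec.channels, -1)
        patches = (
            x.reshape(n, self.in_chans, gh, p, gw, p)
            .transpose(0, 2, 4, 1, 3, 5)
            .reshape(n, gh * gw, -1)
        )
        tok = patches @ pw.T + self.w["patch_embed.proj.bias"]
        cls = np.broadcast_to(self.w["cls_token"], (n, 1, self.spec.channels))
        tok = np.concatenate([cls, tok], axis=1) + self._pos_embed((gh, gw))
        n_layers = self.depth if self.feature_layer == -1 else self.feature_layer + 1
        for i in range(n_layers):
            tok = self._block(tok, i)
        tok = _layer_norm(tok, self.w["norm.weight"], self.w["norm.bias"])
        feats = tok[:, 1:].reshape(n, gh, gw, -1).transpose(0, 3, 1, 2)
        return feats

    def _block(self, x: np.ndarray, i: int) -> np.ndarray:
        w = self.w
        pre = f"blocks.{i}"
        n, t, d = x.shape
        h = self.heads
        y = _layer_norm(x, w[f"{pre}.norm1.weight"], w[f"{pre}.norm1.bias"])
        qkv = y @ w[f"{pre}.attn.qkv.weight"].T + w[f"{pre}.attn.qkv.bias"]
        qkv = qkv.reshape(n, t, 3, h, d // h).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]
        att = q @ k.transpose(0, 1, 3, 2) / np.sqrt(d // h)
        att = att - att.max(-1, keepdims=True)
        att = np.exp(att)
        att /= att.sum(-1, keepdims=True)
        y = (att @ v).transpose(0, 2, 1, 3).reshape(n, t, d)
        x = x + y @ w[f"{pre}.attn.proj.weight"].T + w[f"{pre}.attn.proj.bias"]
        y = _layer_norm(x, w[f"{pre}.norm2.weight"], w[f"{pre}.norm2.bias"])
        y = _gelu(y @ w[f"{pre}.mlp.fc1.weight"].T + w[f"{pre}.mlp.fc1.bias"])
        return x + y @ w[f"{pre}.mlp.fc2.weight"].T + w[f"{pre}.mlp.fc2.bias"]


def tiny_backbone(seed: int, channels: int = 32, stride: int = 8) -> TinyBackbone:
    """Build the frozen random conv-pyramid extractor (the default teacher)."""
    return TinyBackbone(seed=seed, channels=channels, stride=stride)


def vit_backbone(variant: str, weights_path: str | Path, feature_layer: int = -1) -> ViTBackbone:
    """Build a frozen ViT extractor from an npz checkpoint; see :class:`ViTBackbone`."""
    return ViTBackbone(variant, weights_path, feature_layer=feature_layer)


def extract_features(extractor: FeatureExtractor, slices: np.ndarray) -> np.ndarray:
    """Extract per-slice dense feature maps; no gradient reaches the extractor."""
    return extractor.extract(slices)
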