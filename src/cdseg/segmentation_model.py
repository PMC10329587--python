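"""Distillation head and learnable-upsampling decoder.

The head C is the nonlinear transformation distilled against the frozen
teacher: exactly two convolutional layers with a ReLU between them, spatial
size preserved.  The decoder follows a U-Net-style upsampling path: five
(bilinear 2x upsample, 3x3 convolution, batch norm, ReLU, dropout) stages, a
resize back to the input resolution when the five doublings overshoot the
backbone stride, a skip connection concatenating the raw preprocessed slice,
and three final convolutions (batch norm + ReLU after the first two, plain
logits from the last) producing per-pixel class scores.

The decoder consumes the head output, so distillation and segmentation share
the learned representation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._nn import (
    BatchNorm2d,
    Conv2d,
    Dropout,
    Module,
    Tensor,
    concat,
    parameter_digest,
    resize_bilinear,
)
from .backbone import FeatureExtractor

__all__ = [
    "ModelConfig",
    "DistillationHead",
    "Decoder",
    "SegmentationModel",
    "build_head",
    "build_decoder",
    "forward_slice",
    "save_checkpoint",
    "load_checkpoint",
    "CheckpointMismatchError",
]


class CheckpointMismatchError(RuntimeError):
    """Checkpoint does not match the current backbone or configuration."""


@dataclass
class ModelConfig:
    head_channels: int = 32
    decoder_channels: tuple[int, ...] = (256, 128, 64, 32, 16)
    dropout_rate: float = 0.1
    num_classes: int = 2

    def __post_init__(self) -> None:
        if len(self.decoder_channels) != 5:
            raise ValueError("decoder_channels must have exactly 5 entries")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if self.head_channels < 1 or any(c < 1 for c in self.decoder_channels):
            raise ValueError("channel counts must be positive")


class DistillationHead(Module):
    """Two convolutions with a ReLU in between; both 1x1 (per-position).

    Per-position kernels preserve the teacher's spatial correspondence
    structure — a spatial kernel would smear neighboring feature categories
    together and blur the distilled similarity clusters.  Weights start at a
    deliberately small scale (0.1x He) so the cosine geometry of the head
    output can reorganize within a short low-learning-rate schedule.
    """

    KERNELS = (1, 1)
    INIT_SCALE = 0.1

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator, dtype=np.float32):
        self.conv1 = Conv2d(in_channels, out_channels, self.KERNELS[0], rng, dtype=dtype)
        self.conv2 = Conv2d(out_channels, out_channels, self.KERNELS[1], rng, dtype=dtype)
        for p in self.parameters():
            p.data = p.data * dtype(self.INIT_SCALE)

    def __call__(self, x: Tensor) -> Tensor:
        return self.conv2(self.conv1(x).relu())

    def parameter_count(self) -> int:
        return sum(int(np.prod(p.shape)) for p in self.parameters())


class Decoder(Module):
    N_STAGES = 5

    def __init__(
        self,
        config: ModelConfig,
        in_channels: int,
        stride: int,
        rng: np.random.Generator,
        dtype=np.float32,
    ):
        if stride > 2**self.N_STAGES:
            raise ValueError(
                f"insufficient upsampling depth: stride {stride} exceeds "
                f"2^{self.N_STAGES} = {2 ** self.N_STAGES}"
            )
        self.stride = stride
        self.dropout = Dropout(config.dropout_rate)
        self.stage_convs: list[Conv2d] = []
        self.stage_norms: list[BatchNorm2d] = []
        cin = in_channels
        for cout in config.decoder_channels:
            self.stage_convs.append(Conv2d(cin, cout, 3, rng, dtype=dtype))
            self.stage_norms.append(BatchNorm2d(cout, dtype=dtype))
            cin = cout
        # skip connection: decoded map concatenated with the raw input slice
        cin = config.decoder_channels[-1] + 1
        mid = max(config.decoder_channels[-1], config.num_classes)
        self.final_convs = [
            Conv2d(cin, mid, 3, rng, dtype=dtype),
            Conv2d(mid, mid, 3, rng, dtype=dtype),
            Conv2d(mid, config.num_classes, 1, rng, dtype=dtype),
        ]
        self.final_norms = [BatchNorm2d(mid, dtype=dtype), BatchNorm2d(mid, dtype=dtype)]

    def __call__(
        self,
        features: Tensor,
        raw_input: Tensor,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        """Map head features (N, C, H/S, W/S) + raw slices (N, 1, H, W) to logits."""
        x = features
        for conv, norm in zip(self.stage_convs, self.stage_norms):
            h, w = x.shape[-2] * 2, x.shape[-1] * 2
            x = resize_bilinear(x, (h, w))
            x = norm(conv(x), training).relu()
            x = self.dropout(x, training, rng)
        target = (raw_input.shape[-2], raw_input.shape[-1])
        if (x.shape[-2], x.shape[-1]) != target:
            x = resize_bilinear(x, target)
        x = concat([x, raw_input], axis=1)
        x = self.final_norms[0](self.final_convs[0](x), training).relu()
        x = self.final_norms[1](self.final_convs[1](x), training).relu()
        return self.final_convs[2](x)


def build_head(
    config: ModelConfig, in_channels: int, seed: int = 0, dtype=np.float32
) -> DistillationHead:
    """Construct the 2-conv distillation head for a backbone with `in_channels`."""
    rng = np.random.default_rng(seed)
    return DistillationHead(in_channels, config.head_channels, rng, dtype=dtype)


def build_decoder(
    config: ModelConfig, in_channels: int, stride: int, seed: int = 0, dtype=np.float32
) -> Decoder:
    """Construct the five-stage upsampling decoder for a given backbone stride."""
    rng = np.random.default_rng(seed)
    return Decoder(config, in_channels, stride, rng, dtype=dtype)


def _softmax_channels(logits: Tensor) -> Tensor:
    shifted = logits - Tensor(logits.data.max(axis=1, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=1, keepdims=True)


class SegmentationModel:
    """Frozen backbone + distillation head + upsampling decoder."""

    def __init__(
        self,
        backbone: FeatureExtractor,
        config: ModelConfig,
        seed: int = 0,
        dtype=np.float32,
    ):
        self.backbone = backbone
        self.config = config
        self.head = build_head(config, backbone.spec.channels, seed=seed, dtype=dtype)
        self.decoder = build_decoder(
            config, config.head_channels, backbone.spec.stride, seed=seed + 1, dtype=dtype
        )
        self.training = False
        self._rng = np.random.default_rng(seed + 2)

    def train_mode(self) -> None:
        self.training = True

    def eval_mode(self) -> None:
        self.training = False

    def trainable_parameters(self):
        return self.head.parameters() + self.decoder.parameters()

    def trainable_digest(self) -> str:
        return parameter_digest([p.data for p in self.trainable_parameters()])

    def forward_batch(self, slices: np.ndarray, feats: np.ndarray | None = None) -> Tensor:
        """Per-pixel class probabilities for a batch of preprocessed slices.

        `feats` may supply precomputed (frozen) backbone features to avoid
        re-extracting them.
        """
        slices = np.asarray(slices)
        if feats is None:
            feats = self.backbone.extract(slices)
        head_out = self.head(Tensor(np.asarray(feats, dtype=np.float32)))
        raw = Tensor(slices[:, None].astype(np.float32))
        logits = self.decoder(head_out, raw, training=self.training, rng=self._rng)
        return _softmax_channels(logits)

    def logits_batch(self, slices: np.ndarray, head_out: Tensor | None = None) -> Tensor:
        slices = np.asarray(slices)
        if head_out is None:
            feats = Tensor(self.backbone.extract(slices).astype(np.float32))
            head_out = self.head(feats)
        raw = Tensor(slices[:, None].astype(np.float32))
        return self.decoder(head_out, raw, training=self.training, rng=self._rng)


def forward_slice(model: SegmentationModel, slice_2d: np.ndarray) -> np.ndarray:
    """Per-pixel class probability map (num_classes, H, W) for one slice.

    Deterministic in evaluation mode (dropout off, running batch-norm stats).
    """
    probs = model.forward_batch(np.asarray(slice_2d)[None])
    return np.asarray(probs.data[0], dtype=np.float64)


def save_checkpoint(model: SegmentationModel, path: str | Path) -> None:
    """Persist head + decoder parameters, config, and the backbone digest."""
    path = Path(path)
    arrays = {
        f"param_{i:04d}": p.data for i, p in enumerate(model.trainable_parameters())
    }
    buffers = {}
    for j, bn in enumerate(model.decoder.stage_norms + model.decoder.final_norms):
        buffers[f"bn_{j}_mean"] = bn.running_mean
        buffers[f"bn_{j}_var"] = bn.running_var
    meta = json.dumps(
        {
            "config": asdict(model.config),
            "backbone_digest": model.backbone.spec.parameter_digest,
            "backbone_name": model.backbone.spec.name,
        }
    )
    np.savez(path, _meta=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays, **buffers)


def load_checkpoint(path: str | Path, backbone: FeatureExtractor) -> SegmentationModel:
    """Rebuild a model from a checkpoint; the backbone digest must match."""
    path = Path(path)
    with np.load(path) as data:
        meta = json.loads(bytes(data["_meta"]).decode())
        if meta["backbone_digest"] != backbone.spec.parameter_digest:
            raise CheckpointMismatchError(
                f"checkpoint mismatch: trained with backbone {meta['backbone_name']} "
                f"(digest {meta['backbone_digest'][:12]}...), got {backbone.spec.name}"
            )
        cfg = meta["config"]
        cfg["decoder_channels"] = tuple(cfg["decoder_channels"])
        model = SegmentationModel(backbone, ModelConfig(**cfg))
        arrays = [data[f"param_{i:04d}"] for i in range(len(model.trainable_parameters()))]
        n_head = len(model.head.parameters())
        model.head.load_arrays(arrays[:n_head])
        model.decoder.load_arrays(arrays[n_head:])
        for j, bn in enumerate(model.decoder.stage_norms + model.decoder.final_norms):
            bn.running_mean = np.array(data[f"bn_{j}_mean"])
            bn.running_var = np.array(data[f"bn_{j}_var"])
    return model
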