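"""Training loop, slice-wise volume inference, 3D metrics, and statistics.

Training follows the optimization contract of the pipeline: RAdam (batch 8,
initial learning rate 1e-4, weight decay 1e-5), learning-rate reduction on a
monitoring-metric plateau (patience 10 epochs), up to 150 epochs, with a
5-scan-per-source held-out test set monitored via mean volume DICE.  Only the
head and decoder receive updates; the backbone stays frozen.

Metrics: DICE overlap, average and maximum symmetric surface distance (ASSD /
MSSD) in physical millimetres from the voxel spacing, plus paired t-test
comparison utilities with a zero-variance comparator fallback.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from ._nn import RAdam, Tensor, astensor
from .contrastive_core import (
    BiasConfig,
    correspondence_loss_from_features,
    sample_triplet,
)
from .imaging_io import PreprocessConfig, VolumeRecord, preprocess_slice
from .objectives import LossWeights, combined_objective
from .segmentation_model import SegmentationModel

__all__ = [
    "TrainConfig",
    "MetricReport",
    "ComparisonResult",
    "holdout_split",
    "train",
    "infer_volume",
    "evaluate_volumes",
    "dice",
    "surface_distances",
    "compare_methods",
]

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    batch_size: int = 8
    initial_lr: float = 1e-4
    weight_decay: float = 1e-5
    max_epochs: int = 150
    plateau_patience_epochs: int = 10
    lr_reduction_factor: float = 0.1
    seed: int = 0
    monitor_metric: str = "mean_test_dice"

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.initial_lr <= 0:
            raise ValueError("initial_lr must be positive")
        if not 0.0 < self.lr_reduction_factor < 1.0:
            raise ValueError("lr_reduction_factor must be in (0, 1)")


@dataclass
class MetricReport:
    """Per-volume DICE/ASSD/MSSD rows plus mean +- sd across scans."""

    per_volume: pd.DataFrame
    aggregate: dict[str, float]

    @classmethod
    def from_rows(cls, rows: list[dict]) -> "MetricReport":
        df = pd.DataFrame(rows)
        agg = {}
        for m in ("dice", "assd_mm", "mssd_mm"):
            vals = df[m].to_numpy(dtype=float)
            agg[f"{m}_mean"] = float(np.mean(vals))
            agg[f"{m}_sd"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        return cls(per_volume=df, aggregate=agg)


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------


def holdout_split(
    volumes: Mapping[str, Sequence], n_test: int = 5, seed: int = 0
) -> tuple[list, list]:
    """Reserve `n_test` volumes per source dataset as the monitoring test set.

    Datasets too small for `n_test` contribute max(1, 20%) volumes with a
    warning.  Deterministic under `seed`; the partitions are disjoint.
    """
    rng = np.random.default_rng(seed)
    train_set: list = []
    test_set: list = []
    for name in sorted(volumes):
        items = list(volumes[name])
        if not items:
            raise ValueError(f"dataset {name!r} is empty")
        k = n_test
        if len(items) <= n_test:
            k = max(1, int(round(0.2 * len(items))))
            warnings.warn(
                f"dataset {name!r} has only {len(items)} volumes; "
                f"reserving {k} for the test set instead of {n_test}"
            )
        order = rng.permutation(len(items))
        test_idx = set(order[:k].tolist())
        for idx, item in enumerate(items):
            (test_set if idx in test_idx else train_set).append(item)
    return train_set, test_set


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def dice(pred: np.ndarray, ref: np.ndarray) -> float:
    """DICE overlap 2|A^B| / (|A|+|B|); two empty masks agree perfectly (1)."""
    pred = np.asarray(pred).astype(bool)
    ref = np.asarray(ref).astype(bool)
    if pred.shape != ref.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {ref.shape}")
    a, b = int(pred.sum()), int(ref.sum())
    if a + b == 0:
        return 1.0
    return 2.0 * int((pred & ref).sum()) / (a + b)


def _surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Foreground voxels with at least one background 6-neighbor."""
    structure = ndimage.generate_binary_structure(mask.ndim, 1)
    eroded = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    return mask & ~eroded


def surface_distances(
    pred: np.ndarray, ref: np.ndarray, spacing_mm: Sequence[float]
) -> tuple[float, float]:
    """(ASSD, MSSD) in mm between two binary masks.

    ASSD averages the two directed mean surface distances; MSSD takes the
    larger of the two directed maxima.  Raises for empty masks (the distance
    is undefined, not zero).
    """
    pred = np.asarray(pred).astype(bool)
    ref = np.asarray(ref).astype(bool)
    if pred.shape != ref.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {ref.shape}")
    if not pred.any() or not ref.any():
        raise ValueError("undefined surface distance: empty mask")
    spacing = tuple(float(s) for s in spacing_mm)
    sp = _surface_voxels(pred)
    sr = _surface_voxels(ref)
    # distance from every voxel to the nearest surface voxel of the other mask
    dt_ref = ndimage.distance_transform_edt(~sr, sampling=spacing)
    dt_pred = ndimage.distance_transform_edt(~sp, sampling=spacing)
    d_pr = dt_ref[sp]
    d_rp = dt_pred[sr]
    assd = 0.5 * (float(d_pr.mean()) + float(d_rp.mean()))
    mssd = max(float(d_pr.max()), float(d_rp.max()))
    return assd, mssd


@dataclass(frozen=True)
class ComparisonResult:
    p_value: float
    t_statistic: float
    degenerate: bool


def compare_methods(
    dice_a: Sequence[float], dice_b: Sequence[float] | float
) -> ComparisonResult:
    """Paired t-test between per-volume DICE series, two-sided.

    A scalar `dice_b` is the published-mean comparator (zero standard
    deviation assumed), reducing to a one-sample t-test of ``dice_a - mean_b``.
    Zero-variance differences are flagged degenerate: p = 1 when the means
    agree, p = 0 for a constant nonzero difference.
    """
    a = np.asarray(dice_a, dtype=float)
    if a.ndim != 1 or len(a) < 2:
        raise ValueError("need at least 2 paired values")
    if np.isscalar(dice_b) or np.asarray(dice_b).ndim == 0:
        diffs = a - float(dice_b)
    else:
        b = np.asarray(dice_b, dtype=float)
        if b.shape != a.shape:
            raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
        diffs = a - b
    sd = diffs.std(ddof=1)
    if sd == 0.0:
        p = 1.0 if np.allclose(diffs.mean(), 0.0) else 0.0
        return ComparisonResult(p_value=p, t_statistic=0.0 if p == 1.0 else np.inf, degenerate=True)
    res = stats.ttest_1samp(diffs, 0.0)
    return ComparisonResult(
        p_value=float(res.pvalue), t_statistic=float(res.statistic), degenerate=False
    )


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------


def _resize_nearest(mask: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    h_in, w_in = mask.shape
    h_out, w_out = size
    if (h_in, w_in) == (h_out, w_out):
        return mask
    yi = np.minimum(((np.arange(h_out) + 0.5) * h_in / h_out).astype(np.intp), h_in - 1)
    xi = np.minimum(((np.arange(w_out) + 0.5) * w_in / w_out).astype(np.intp), w_in - 1)
    return mask[np.ix_(yi, xi)]


def infer_volume(
    model: SegmentationModel,
    record: VolumeRecord,
    preprocess: PreprocessConfig,
    chunk: int = 8,
    largest_component: bool = False,
) -> np.ndarray:
    """Slice-wise volume inference: preprocess, forward, argmax, restack.

    Returns a binary mask aligned with the input volume (native resolution,
    nearest-neighbor upsampling of the per-slice argmax).  Deterministic in
    evaluation mode.  `largest_component=True` optionally keeps only the
    largest 3D connected component (off by default: no post-processing).
    """
    model.eval_mode()
    native = record.voxels.shape[1:]
    pre = np.stack(
        [preprocess_slice(record.voxels[i], preprocess) for i in range(record.n_slices)]
    )
    out = np.zeros(record.voxels.shape, dtype=np.uint8)
    for start in range(0, len(pre), chunk):
        batch = pre[start : start + chunk]
        probs = model.forward_batch(batch).data
        labels = probs.argmax(axis=1).astype(np.uint8)
        for k in range(len(batch)):
            out[start + k] = _resize_nearest(labels[k], native)
    if largest_component and out.any():
        labels, n = ndimage.label(out, structure=np.ones((3, 3, 3), dtype=int))
        if n > 1:
            sizes = ndimage.sum(out, labels, range(1, n + 1))
            out = (labels == int(np.argmax(sizes)) + 1).astype(np.uint8)
    return out


def evaluate_volumes(
    model: SegmentationModel,
    volumes: Sequence[VolumeRecord],
    preprocess: PreprocessConfig,
) -> MetricReport:
    """Infer every volume and score it against its ground-truth mask."""
    rows = []
    for idx, rec in enumerate(volumes):
        if rec.mask is None:
            raise ValueError(f"volume {rec.volume_id or idx} has no reference mask")
        pred = infer_volume(model, rec, preprocess)
        d = dice(pred, rec.mask)
        try:
            assd, mssd = surface_distances(pred, rec.mask, rec.spacing_mm)
        except ValueError:
            assd, mssd = np.nan, np.nan
        rows.append(
            {
                "volume_id": rec.volume_id or f"volume_{idx:03d}",
                "dice": d,
                "assd_mm": assd,
                "mssd_mm": mssd,
            }
        )
    return MetricReport.from_rows(rows)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def _mask_to_target(mask_slice: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    return _resize_nearest(np.asarray(mask_slice, dtype=np.uint8), size)


def train(
    model: SegmentationModel,
    train_volumes: Sequence[VolumeRecord],
    test_volumes: Sequence[VolumeRecord],
    config: TrainConfig,
    weights: LossWeights | None = None,
    biases: BiasConfig | None = None,
    preprocess: PreprocessConfig | None = None,
    monitor_fn: Callable[[SegmentationModel], float] | None = None,
) -> pd.DataFrame:
    """Train head + decoder on labeled volumes; returns the epoch history.

    Per step a batch of anchor slices is drawn, positional triplets are built
    with :func:`sample_triplet`, and the weighted sum of the distillation and
    supervised losses on the anchors is minimized with RAdam.  Per epoch the
    monitoring metric (mean test-volume DICE unless `monitor_fn` overrides it)
    is evaluated and the learning rate is reduced after
    `plateau_patience_epochs` epochs without improvement.  Fully reproducible
    under `config.seed`.
    """
    weights = weights or LossWeights()
    biases = biases or BiasConfig()
    preprocess = preprocess or PreprocessConfig()
    if not train_volumes:
        raise ValueError("need at least one training volume")
    if any(v.mask is None for v in train_volumes):
        raise ValueError("every training volume needs a mask")
    preprocess.validate_for_stride(model.backbone.spec.stride)

    rng = np.random.default_rng(config.seed)
    model._rng = np.random.default_rng(config.seed + 1)  # dropout stream

    # cache preprocessed slices, targets and (frozen) teacher features
    vols = []
    any_contrastive = False
    for rec in train_volumes:
        pre = np.stack(
            [preprocess_slice(rec.voxels[i], preprocess) for i in range(rec.n_slices)]
        ).astype(np.float32)
        tgt = np.stack(
            [
                _mask_to_target(rec.mask[i], preprocess.target_slice_size)
                for i in range(rec.n_slices)
            ]
        )
        feats = model.backbone.extract(pre).astype(np.float32)
        vols.append({"pre": pre, "tgt": tgt, "feats": feats, "n": rec.n_slices})
        if rec.n_slices >= 4:
            any_contrastive = True
    use_cd = weights.w_cd > 0 and any_contrastive
    if weights.w_cd > 0 and not any_contrastive:
        logger.warning(
            "all training volumes have < 4 slices; contrastive term skipped globally"
        )

    index = [(vi, si) for vi, v in enumerate(vols) for si in range(v["n"])]
    optimizer = RAdam(
        model.trainable_parameters(),
        lr=config.initial_lr,
        weight_decay=config.weight_decay,
    )

    def default_monitor(m: SegmentationModel) -> float:
        if not test_volumes:
            return float("nan")
        report = evaluate_volumes(m, test_volumes, preprocess)
        return report.aggregate["dice_mean"]

    monitor = monitor_fn or default_monitor

    history_rows = []
    best = -np.inf
    plateau_counter = 0
    lr = config.initial_lr

    for epoch in range(1, config.max_epochs + 1):
        model.train_mode()
        order = rng.permutation(len(index))
        epoch_losses: list[dict] = []
        for start in range(0, len(order), config.batch_size):
            batch_ids = [index[k] for k in order[start : start + config.batch_size]]
            slices = np.stack([vols[vi]["pre"][si] for vi, si in batch_ids])
            targets = np.stack([vols[vi]["tgt"][si] for vi, si in batch_ids])

            cd_total = None
            if use_cd:
                cd_terms = []
                for vi, si in batch_ids:
                    v = vols[vi]
                    trip = sample_triplet(si, v["n"])
                    if trip.degenerate:
                        continue
                    cd_terms.append(
                        _triplet_loss(model, v["feats"], trip, biases)
                    )
                if cd_terms:
                    acc = cd_terms[0]
                    for t in cd_terms[1:]:
                        acc = acc + t
                    cd_total = acc * (1.0 / len(cd_terms))

            feats_batch = np.stack([vols[vi]["feats"][si] for vi, si in batch_ids])
            probs = model.forward_batch(slices, feats=feats_batch)
            breakdown, total = combined_objective(
                probs, targets, cd_total if cd_total is not None else 0.0, weights
            )
            optimizer.zero_grad()
            total.backward()
            optimizer.lr = lr
            optimizer.step()
            epoch_losses.append(
                {
                    "cd": breakdown.cd,
                    "focal": breakdown.focal,
                    "tversky": breakdown.tversky,
                    "logiou": breakdown.logiou,
                    "entropy": breakdown.entropy,
                    "total": breakdown.total,
                }
            )

        model.eval_mode()
        metric = monitor(model)
        if metric > best:
            best = metric
            plateau_counter = 0
        else:
            plateau_counter += 1
            if plateau_counter >= config.plateau_patience_epochs:
                lr *= config.lr_reduction_factor
                plateau_counter = 0
                logger.info("epoch %d: plateau, lr reduced to %.2e", epoch, lr)

        means = pd.DataFrame(epoch_losses).mean().to_dict()
        history_rows.append(
            {"epoch": epoch, **{k: float(v) for k, v in means.items()},
             "monitor_dice": float(metric), "lr": lr}
        )
    return pd.DataFrame(history_rows)


def _triplet_loss(model: SegmentationModel, feats: np.ndarray, trip, biases: BiasConfig):
    """Distillation loss for one anchor using cached teacher features."""
    head = model.head

    def head_out(idx: int) -> Tensor:
        h = head(Tensor(feats[idx][None]))
        return h.reshape(h.shape[1], h.shape[2], h.shape[3])

    ha = head_out(trip.anchor)
    fa = feats[trip.anchor]
    total = correspondence_loss_from_features(fa, fa, ha, ha, biases.b_self)
    if trip.positives:
        pos = [
            correspondence_loss_from_features(
                fa, feats[p], ha, head_out(p), biases.b_pos
            )
            for p in trip.positives
        ]
        acc = pos[0]
        for t in pos[1:]:
            acc = acc + t
        total = total + acc * (1.0 / len(pos))
    total = total + correspondence_loss_from_features(
        fa, feats[trip.negative], ha, head_out(trip.negative), biases.b_neg
    )
    return total
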