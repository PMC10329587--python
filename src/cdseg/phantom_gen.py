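"""Synthetic abdominal-like phantoms with ground-truth "liver" masks.

Each phantom is a smoothly deformed superellipsoid "liver" (large, connected,
high intensity) among smaller ellipsoidal distractor structures, with additive
Gaussian noise and a per-"modality" monotone intensity remapping so the same
geometry can be rendered with a cross-modality appearance shift.  Everything is
fully determined by ``(config, seed)``.

The liver mask is obtained by thresholding a perturbed anisotropic radial
field at the quantile matching a target volume fraction drawn from
``liver_fraction_range``, which pins the foreground fraction by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging_io import VolumeRecord, write_mask, write_volume

__all__ = [
    "PhantomConfig",
    "InfeasibleConfigError",
    "generate_phantom",
    "generate_dataset",
]

# noiseless intensity levels (arbitrary units, roughly [0, 1])
_BACKGROUND = 0.20
_LIVER = 0.80
_DISTRACTOR_BANDS = (0.35, 0.50, 0.65, 0.10, 0.45)


class InfeasibleConfigError(ValueError):
    """The requested liver fraction cannot be realized on the given grid."""


@dataclass
class PhantomConfig:
    shape: tuple[int, int, int] = (32, 64, 64)
    liver_fraction_range: tuple[float, float] = (0.08, 0.20)
    n_distractors: int = 3
    noise_sd: float = 0.05
    modality_style: Literal["ct_like", "mr_like"] = "ct_like"
    spacing_mm: tuple[float, float, float] = (3.0, 1.5, 1.5)

    def __post_init__(self) -> None:
        if any(s < 8 for s in self.shape):
            raise ValueError("each shape component must be >= 8")
        lo, hi = self.liver_fraction_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("liver_fraction_range must satisfy 0 < lo < hi < 1")
        if self.n_distractors < 0 or self.noise_sd < 0:
            raise ValueError("n_distractors and noise_sd must be non-negative")
        if self.modality_style not in ("ct_like", "mr_like"):
            raise ValueError(f"unknown modality_style {self.modality_style!r}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")

    def validate_feasible(self) -> None:
        total = int(np.prod(self.shape))
        lo, hi = self.liver_fraction_range
        if lo * total < 64:
            raise InfeasibleConfigError(
                f"lower fraction {lo} yields < 64 voxels on shape {self.shape}"
            )
        if hi > 0.45:
            raise InfeasibleConfigError(
                f"upper fraction {hi} too large for a connected interior organ"
            )


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int, int], coarse: int = 4) -> np.ndarray:
    """Low-frequency random field in roughly [-1, 1], zoomed from a coarse grid."""
    coarse_grid = rng.standard_normal((coarse, coarse, coarse))
    zoom = [s / coarse for s in shape]
    f = ndimage.zoom(coarse_grid, zoom, order=3, mode="nearest", grid_mode=True)
    return np.clip(f / 2.0, -1.0, 1.0)


def _radial_field(
    shape: tuple[int, int, int],
    center: np.ndarray,
    semi_axes: np.ndarray,
    power: float,
) -> np.ndarray:
    """Superellipsoid implicit function (p-norm radius), 1.0 on the surface."""
    zz, yy, xx = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape], indexing="ij")
    d = (
        np.abs((zz - center[0]) / semi_axes[0]) ** power
        + np.abs((yy - center[1]) / semi_axes[1]) ** power
        + np.abs((xx - center[2]) / semi_axes[2]) ** power
    )
    return d ** (1.0 / power)


def _liver_mask(
    config: PhantomConfig, rng: np.random.Generator, target_fraction: float
) -> np.ndarray:
    shape = config.shape
    zc = np.array(
        [
            rng.uniform(0.42, 0.58) * shape[0],
            rng.uniform(0.40, 0.60) * shape[1],
            rng.uniform(0.40, 0.60) * shape[2],
        ]
    )
    # anisotropic semi-axes; absolute size is irrelevant (quantile threshold)
    axes = np.array(
        [
            rng.uniform(0.28, 0.40) * shape[0],
            rng.uniform(0.30, 0.45) * shape[1],
            rng.uniform(0.30, 0.45) * shape[2],
        ]
    )
    power = rng.uniform(2.0, 3.0)
    r = _radial_field(shape, zc, axes, power)
    r = r * (1.0 + 0.15 * _smooth_field(rng, shape))
    thresh = np.quantile(r, target_fraction)
    mask = (r <= thresh).astype(np.uint8)
    # keep the component containing the organ center (smooth fields make
    # disconnection rare; this enforces the single-component contract)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    if n > 1:
        center_label = labels[tuple(np.round(zc).astype(int))]
        if center_label == 0:
            sizes = ndimage.sum(mask, labels, range(1, n + 1))
            center_label = int(np.argmax(sizes)) + 1
        mask = (labels == center_label).astype(np.uint8)
    return mask


def _add_distractors(
    volume: np.ndarray, liver: np.ndarray, config: PhantomConfig, rng: np.random.Generator
) -> None:
    shape = np.array(config.shape, dtype=np.float64)
    for k in range(config.n_distractors):
        center = rng.uniform(0.15, 0.85, size=3) * shape
        axes = rng.uniform(0.04, 0.12, size=3) * shape + 1.5
        r = _radial_field(config.shape, center, axes, 2.0)
        blob = (r <= 1.0) & (liver == 0)
        volume[blob] = _DISTRACTOR_BANDS[k % len(_DISTRACTOR_BANDS)]


def _modality_remap(volume: np.ndarray, style: str) -> np.ndarray:
    if style == "ct_like":
        return volume
    # monotone gamma-like compression emulating a different acquisition contrast
    v = np.clip(volume, 0.0, None)
    return v**0.55


def generate_phantom(config: PhantomConfig, seed: int) -> VolumeRecord:
    """Generate one phantom volume with its ground-truth liver mask.

    The liver's noiseless mean intensity differs from the background mean by
    well over twice ``noise_sd``; the mask foreground fraction lies inside
    ``liver_fraction_range`` by construction.
    """
    config.validate_feasible()
    rng = np.random.default_rng(seed)
    lo, hi = config.liver_fraction_range
    # keep away from the exact interval ends so quantile rounding on a finite
    # grid cannot push the realized fraction outside the range
    margin = 0.02 * (hi - lo)
    target_fraction = rng.uniform(lo + margin, hi - margin)
    mask = _liver_mask(config, rng, target_fraction)

    volume = np.full(config.shape, _BACKGROUND, dtype=np.float64)
    volume += 0.03 * _smooth_field(rng, config.shape)  # soft-tissue texture
    _add_distractors(volume, mask, config, rng)
    volume[mask == 1] = _LIVER
    volume = _modality_remap(volume, config.modality_style)
    if config.noise_sd > 0:
        volume = volume + rng.normal(0.0, config.noise_sd, size=config.shape)

    sz, sy, sx = config.spacing_mm
    affine = np.diag([sx, sy, sz, 1.0])
    return VolumeRecord(
        voxels=volume.astype(np.float32),
        spacing_mm=config.spacing_mm,
        affine=affine,
        modality_tag=config.modality_style,
        mask=mask,
    )


def derive_seed(master_seed: int, index: int) -> int:
    """Deterministic, well-separated per-volume seed below 2**31."""
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_dataset(
    n: int,
    config: PhantomConfig,
    seed: int,
    out_dir: str | Path,
) -> pd.DataFrame:
    """Write ``n`` phantom volume+mask NIfTI pairs plus a CSV manifest.

    Per-volume seeds derive deterministically from the master seed, so the
    same call regenerates identical files and manifest.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(n):
        s = derive_seed(seed, i)
        rec = generate_phantom(config, s)
        vol_path = out_dir / f"phantom_{i:03d}.nii.gz"
        mask_path = out_dir / f"phantom_{i:03d}_mask.nii.gz"
        write_volume(rec, vol_path)
        write_mask(rec, rec.mask, mask_path)
        rows.append(
            {
                "path": vol_path.name,
                "mask_path": mask_path.name,
                "seed": s,
                "modality_style": config.modality_style,
                "liver_fraction": float(rec.mask.mean()),
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
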