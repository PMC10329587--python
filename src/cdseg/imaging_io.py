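"""NIfTI volume I/O, canonical axial slicing, and slice preprocessing.

Volumes are held as ``(z, y, x)`` grids where ``z`` is the cranio-caudal axis
after reorientation to the RAS-closest canonical frame, so "slice i" means the
same anatomical direction for every file.  Preprocessing (intensity window,
resize, per-slice normalization) is deterministic and configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import nibabel as nib
import numpy as np

from ._nn import resize_bilinear

__all__ = [
    "VolumeRecord",
    "PreprocessConfig",
    "InvalidVolumeError",
    "read_volume",
    "write_volume",
    "write_mask",
    "extract_axial_slices",
    "preprocess_slice",
]


class InvalidVolumeError(ValueError):
    """Raised for unparseable files or degenerate headers (e.g. zero spacing)."""


@dataclass
class VolumeRecord:
    """A 3D scan in canonical orientation with spacing metadata.

    Attributes
    ----------
    voxels : ndarray
        Scalar grid indexed ``(z, y, x)``; z is cranio-caudal.
    spacing_mm : tuple of float
        Voxel spacing in mm, ordered ``(z, y, x)``; all positive.
    affine : ndarray
        4x4 voxel-to-world matrix of the canonical orientation.
    modality_tag : str
        Free-form modality label (e.g. ``"ct_like"``).
    mask : ndarray or None
        Binary grid of the same shape, values in {0, 1}.
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    affine: np.ndarray
    modality_tag: str = ""
    mask: np.ndarray | None = None
    volume_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise InvalidVolumeError("voxel grid must be 3D")
        if any(s <= 0 for s in self.spacing_mm):
            raise InvalidVolumeError(f"non-positive spacing {self.spacing_mm}")
        if self.mask is not None:
            self.mask = np.asarray(self.mask)
            if self.mask.shape != self.voxels.shape:
                raise ValueError(
                    f"shape mismatch: mask {self.mask.shape} vs voxels {self.voxels.shape}"
                )
            self.mask = (self.mask > 0.5).astype(np.uint8)

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]


@dataclass
class PreprocessConfig:
    """Slice preprocessing: window -> resize -> normalize.

    Defaults are conventional liver-CT choices: a (-100, 400) HU window, a
    per-slice z-score, and no resizing (the caller picks a target compatible
    with the backbone stride).
    """

    target_slice_size: tuple[int, int] = (64, 64)
    intensity_window: tuple[float, float] | None = (-100.0, 400.0)
    normalization: Literal["zscore", "minmax", "none"] = "zscore"

    def __post_init__(self) -> None:
        h, w = self.target_slice_size
        if h < 1 or w < 1:
            raise ValueError("target slice size must be positive")
        if self.intensity_window is not None:
            lo, hi = self.intensity_window
            if not lo < hi:
                raise ValueError(f"window low must be < high, got {self.intensity_window}")
        if self.normalization not in ("zscore", "minmax", "none"):
            raise ValueError(f"unknown normalization {self.normalization!r}")

    def validate_for_stride(self, stride: int) -> None:
        h, w = self.target_slice_size
        if h % stride or w % stride:
            raise ValueError(
                f"target slice size {self.target_slice_size} must be a multiple of "
                f"the backbone stride {stride}"
            )


def _to_canonical(img: nib.Nifti1Image) -> nib.Nifti1Image:
    return nib.as_closest_canonical(img)


def read_volume(
    path: str | Path,
    mask_path: str | Path | None = None,
    modality_tag: str = "",
) -> VolumeRecord:
    """Read a NIfTI volume (and optionally its mask) into canonical (z, y, x) order.

    The file is reoriented to the RAS-closest frame; data axes are then
    transposed from nibabel's (x, y, z) to (z, y, x) so index 0 runs along the
    cranio-caudal axis.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume not found: {path}")
    try:
        img = _to_canonical(nib.load(path))
        data = np.asarray(img.dataobj)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise InvalidVolumeError(f"invalid volume {path}: {exc}") from exc
    if data.ndim != 3:
        raise InvalidVolumeError(f"invalid volume {path}: expected 3D, got {data.ndim}D")
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise InvalidVolumeError(f"invalid volume {path}: degenerate spacing {zooms}")
    voxels = np.transpose(data, (2, 1, 0))
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    mask = None
    if mask_path is not None:
        mrec = read_volume(mask_path)
        mask = mrec.voxels
    return VolumeRecord(
        voxels=voxels,
        spacing_mm=spacing,
        affine=np.asarray(img.affine),
        modality_tag=modality_tag,
        mask=mask,
        volume_id=path.name.split(".")[0],
    )


def _save_nifti(data_zyx: np.ndarray, record: VolumeRecord, path: str | Path) -> None:
    data_xyz = np.transpose(data_zyx, (2, 1, 0))
    img = nib.Nifti1Image(data_xyz, record.affine)
    img.header.set_zooms(tuple(reversed(record.spacing_mm)))
    nib.save(img, str(path))


def write_volume(record: VolumeRecord, path: str | Path) -> None:
    """Write the record's voxel grid as NIfTI, preserving affine and spacing."""
    _save_nifti(np.asarray(record.voxels, dtype=np.float32), record, path)


def write_mask(record: VolumeRecord, mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask aligned with `record` as integer-typed NIfTI."""
    mask = np.asarray(mask)
    if mask.shape != record.voxels.shape:
        raise ValueError(
            f"shape mismatch: mask {mask.shape} vs volume {record.voxels.shape}"
        )
    _save_nifti((mask > 0.5).astype(np.uint8), record, path)


def extract_axial_slices(
    record: VolumeRecord,
) -> list[np.ndarray] | list[tuple[np.ndarray, np.ndarray]]:
    """Return the axial slices of a volume, ordered along the cranio-caudal axis.

    With a mask present, returns aligned ``(image, mask)`` pairs instead.
    """
    if record.mask is None:
        return [record.voxels[i] for i in range(record.n_slices)]
    return [(record.voxels[i], record.mask[i]) for i in range(record.n_slices)]


def preprocess_slice(slice_2d: np.ndarray, config: PreprocessConfig) -> np.ndarray:
    """Window, resize (bilinear, pixel-center sampling) and normalize one slice.

    Deterministic; a constant slice under z-score maps to all zeros instead of
    dividing by a vanishing standard deviation.
    """
    out = np.asarray(slice_2d, dtype=np.float64)
    if out.ndim != 2:
        raise ValueError("expected a 2D slice")
    if config.intensity_window is not None:
        lo, hi = config.intensity_window
        out = np.clip(out, lo, hi)
    out = np.asarray(resize_bilinear(out, config.target_slice_size))
    if config.normalization == "zscore":
        sd = out.std()
        out = np.zeros_like(out) if sd < 1e-12 else (out - out.mean()) / sd
    elif config.normalization == "minmax":
        lo, hi = out.min(), out.max()
        out = np.zeros_like(out) if hi - lo < 1e-12 else (out - lo) / (hi - lo)
    return out


def stack_slices(slices: Sequence[np.ndarray]) -> np.ndarray:
    """Inverse of `extract_axial_slices` for image-only slice lists."""
    return np.stack(list(slices), axis=0)
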