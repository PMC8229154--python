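"""Masked NIfTI input/output.

A 4D BOLD series is held in memory as a ``voxels x time`` matrix bound to an
explicit list of in-mask voxel coordinates, the image affine and the repetition
time.  The voxel ordering is the canonical row-major linearisation of the mask:
coordinates sorted ascending by x, then y, then z (exactly what
``numpy.argwhere`` produces on the boolean mask).  The ordering is part of the
on-disk contract — every stage downstream indexes voxels this way.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import ShapeError, ValidationError

__all__ = ["MaskedBold", "load_bold_masked", "save_map", "save_bold", "mask_coordinates"]

AFFINE_ATOL = 1e-4


def mask_coordinates(mask: np.ndarray) -> np.ndarray:
    """Canonical (sorted x, y, z ascending) integer coordinates of a boolean mask."""
    return np.argwhere(np.asarray(mask, dtype=bool))


@dataclass
class MaskedBold:
    """One subject's BOLD data as a voxels x time matrix under a fixed mask."""

    data: np.ndarray            # (n_voxels, n_timepoints)
    mask_index: np.ndarray      # (n_voxels, 3) int coordinates, canonical order
    affine: np.ndarray          # (4, 4)
    tr_seconds: float
    zero_variance: np.ndarray = field(default=None, repr=False)  # bool flags per voxel

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask_index = np.asarray(self.mask_index)
        if self.data.ndim != 2:
            raise ShapeError("BOLD data must be a 2-D voxels x time matrix")
        if self.mask_index.shape != (self.data.shape[0], 3):
            raise ShapeError(
                f"mask_index shape {self.mask_index.shape} does not match "
                f"{self.data.shape[0]} voxels"
            )
        if self.tr_seconds <= 0:
            raise ValidationError("tr_seconds must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("BOLD data contains non-finite values")
        if self.zero_variance is None:
            self.zero_variance = self.data.std(axis=1) == 0.0

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


def _check_same_grid(img, mask_img) -> None:
    if img.ndim != 4:
        raise ShapeError(f"expected a 4-D image, got {img.ndim}-D")
    if mask_img.ndim != 3:
        raise ShapeError(f"expected a 3-D mask, got {mask_img.ndim}-D")
    if img.shape[:3] != mask_img.shape:
        raise ShapeError(
            f"image grid {img.shape[:3]} does not match mask grid {mask_img.shape}"
        )
    if not np.allclose(img.affine, mask_img.affine, atol=AFFINE_ATOL):
        raise ShapeError("image and mask affines differ beyond tolerance 1e-4")


def load_bold_masked(image_path, mask_path, tr_seconds: float | None = None) -> MaskedBold:
    """Load a 4D image under a 3D mask into a :class:`MaskedBold`.

    Parameters
    ----------
    image_path, mask_path:
        NIfTI-1 files on the same grid with matching affines (per-element
        tolerance 1e-4).
    tr_seconds:
        Repetition time override; by default read from the image header's
        fourth zoom.
    """
    img = nib.load(str(image_path))
    mask_img = nib.load(str(mask_path))
    _check_same_grid(img, mask_img)
    mask = np.asarray(mask_img.dataobj) > 0
    if not mask.any():
        raise ValidationError("mask is empty")
    idx = mask_coordinates(mask)
    data = np.asarray(img.dataobj, dtype=float)[mask]
    if tr_seconds is None:
        zooms = img.header.get_zooms()
        tr_seconds = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    return MaskedBold(data=data, mask_index=idx, affine=img.affine, tr_seconds=tr_seconds)


def _volume_from_masked(values: np.ndarray, mask_index: np.ndarray,
                        grid_shape: tuple[int, int, int] | None) -> np.ndarray:
    values = np.asarray(values, dtype=np.float32)
    mask_index = np.asarray(mask_index)
    if values.shape[0] != mask_index.shape[0]:
        raise ShapeError(
            f"{values.shape[0]} values for {mask_index.shape[0]} mask voxels"
        )
    if grid_shape is None:
        grid_shape = tuple(int(m) + 1 for m in mask_index.max(axis=0))
    vol = np.zeros(grid_shape + values.shape[1:], dtype=np.float32)
    vol[tuple(mask_index.T)] = values
    return vol


def save_map(values, mask_index, affine, path, grid_shape=None) -> Path:
    """Write a per-voxel statistic vector as a 3D NIfTI map (out-of-mask = 0)."""
    vol = _volume_from_masked(np.asarray(values, dtype=np.float32), mask_index, grid_shape)
    nib.save(nib.Nifti1Image(vol, np.asarray(affine, dtype=float)), str(path))
    return Path(path)


def save_bold(data, mask_index, affine, tr_seconds, path, grid_shape=None) -> Path:
    """Write a voxels x time matrix as a 4D NIfTI series (out-of-mask = 0)."""
    vol = _volume_from_masked(np.asarray(data, dtype=np.float32), mask_index, grid_shape)
    img = nib.Nifti1Image(vol, np.asarray(affine, dtype=float))
    zooms = list(img.header.get_zooms())
    zooms[3] = tr_seconds
    img.header.set_zooms(zooms)
    nib.save(img, str(path))
    return Path(path)
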