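"""NIfTI-backed containers for grey volumes, label maps and probability fields.

The segmentation pipeline works on a finite 3-D lattice
``R = {(x, y, z) : 0 <= x < X, 0 <= y < Y, 0 <= z < Z}`` carrying integer grey
values in ``Q = {0, ..., Q-1}`` and region labels in ``L = {0, 1, 2, 3}``
(0 = background, 1 = CSF, 2 = GM, 3 = WM).  Voxel indexing is 0-based (x, y, z);
world coordinates live only in the NIfTI affine and are never used by the
algorithms themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

#: fixed label codes used throughout the package
BACKGROUND, CSF, GM, WM = 0, 1, 2, 3
TISSUE_LABELS = (CSF, GM, WM)
N_LABELS = 4  # including background
LABEL_NAMES = {BACKGROUND: "background", CSF: "CSF", GM: "GM", WM: "WM"}


class VolumeError(ValueError):
    """Raised when a volume or label map violates its contract."""


def _default_affine(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


@dataclass
class Volume:
    """A 3-D integer grey-scale image on the lattice R.

    Parameters
    ----------
    values : ndarray of int, shape (X, Y, Z)
        Grey levels in ``[0, Q-1]``.
    spacing : tuple of float
        Voxel size in mm per axis.
    affine : ndarray (4, 4), optional
        Voxel-to-world matrix; defaults to a diagonal built from ``spacing``.
    Q : int
        Number of grey levels (default 256).
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None
    Q: int = 256

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise VolumeError(f"expected a 3-D volume, got ndim={self.values.ndim}")
        if not np.issubdtype(self.values.dtype, np.integer):
            raise VolumeError("volume values must be integers; quantize first")
        if self.Q < 2:
            raise VolumeError("Q must be >= 2")
        vmin, vmax = int(self.values.min()), int(self.values.max())
        if vmin < 0 or vmax > self.Q - 1:
            raise VolumeError(
                f"grey values outside [0, {self.Q - 1}]: observed range [{vmin}, {vmax}]"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def copy(self) -> "Volume":
        return Volume(self.values.copy(), self.spacing, self.affine.copy(), self.Q)

    def with_values(self, values: np.ndarray) -> "Volume":
        """Same lattice metadata, new voxel data."""
        return Volume(values, self.spacing, self.affine.copy(), self.Q)


@dataclass
class LabelMap:
    """A 3-D map of region labels over {0..3} sharing a Volume's lattice."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise VolumeError(f"expected a 3-D label map, got ndim={self.values.ndim}")
        if not np.issubdtype(self.values.dtype, np.integer):
            raise VolumeError("label values must be integers")
        bad = np.setdiff1d(np.unique(self.values), np.arange(N_LABELS))
        if bad.size:
            raise VolumeError(f"unknown label {int(bad[0])}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def copy(self) -> "LabelMap":
        return LabelMap(self.values.copy(), self.spacing, self.affine.copy())

    def with_values(self, values: np.ndarray) -> "LabelMap":
        return LabelMap(values, self.spacing, self.affine.copy())


def check_same_lattice(a, b) -> None:
    """Raise if two images do not share shape and spacing."""
    if a.shape != b.shape:
        raise VolumeError(f"lattice mismatch: {a.shape} vs {b.shape}")
    if not np.allclose(a.spacing, b.spacing):
        raise VolumeError(f"spacing mismatch: {a.spacing} vs {b.spacing}")


def _load(path) -> tuple[np.ndarray, np.ndarray, tuple[float, ...]]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, np.asarray(img.affine, dtype=float), spacing


def read_volume(path, Q: int = 256, quantize: bool = False) -> Volume:
    """Read a 3-D grey volume from a NIfTI file.

    Float-valued files are accepted only if their values are integral, or if
    ``quantize`` is set, in which case they are rounded and clipped to
    ``[0, Q-1]``.
    """
    data, affine, spacing = _load(path)
    if data.ndim != 3:
        raise VolumeError(f"expected 3-D NIfTI, got ndim={data.ndim} in {path}")
    if not np.issubdtype(data.dtype, np.integer):
        if quantize:
            data = np.clip(np.rint(data), 0, Q - 1)
        elif not np.all(data == np.rint(data)):
            raise VolumeError(
                f"{path} contains fractional intensities "
                f"(range [{data.min():.3g}, {data.max():.3g}]); pass quantize=True"
            )
        data = data.astype(np.int32)
    return Volume(data.astype(np.int32), spacing, affine, Q)


def write_volume(vol: Volume, path) -> None:
    """Write a Volume as NIfTI (int16 payload, metadata preserved)."""
    img = nib.Nifti1Image(vol.values.astype(np.int16), vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def read_labelmap(path) -> LabelMap:
    data, affine, spacing = _load(path)
    if data.ndim != 3:
        raise VolumeError(f"expected 3-D NIfTI label map, got ndim={data.ndim}")
    if not np.issubdtype(data.dtype, np.integer):
        if not np.all(data == np.rint(data)):
            raise VolumeError(f"{path} contains fractional label values")
        data = np.rint(data)
    return LabelMap(data.astype(np.int16), spacing, affine)


def write_labelmap(m: LabelMap, path) -> None:
    img = nib.Nifti1Image(m.values.astype(np.uint8), m.affine)
    img.header.set_zooms(m.spacing)
    nib.save(img, str(path))


def write_prior(probs: np.ndarray, affine: np.ndarray, path) -> None:
    """Export a 4-D (X, Y, Z, L+1) probability field; 4th axis = label code."""
    probs = np.asarray(probs, dtype=np.float32)
    if probs.ndim != 4:
        raise VolumeError("prior field must be 4-D (x, y, z, label)")
    nib.save(nib.Nifti1Image(probs, np.asarray(affine, dtype=float)), str(path))


def read_prior(path) -> np.ndarray:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float32)
    if data.ndim != 4:
        raise VolumeError("prior field file must be 4-D")
    return data
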