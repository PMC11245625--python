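"""Lightweight 3-D volume containers.

Volumes couple a voxel array with its physical voxel spacing in millimetres.
All reconstruction and statistics code works in physical coordinates, so the
spacing travels with the data rather than being an implicit convention.
Voxel indices are 0-based; axis order is (x, y, z) and matches the NIfTI
on-disk order used by :mod:`helmept.io`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ComplexVolume", "LabelVolume", "ScalarVolume", "check_aligned"]


def _validate_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 or not np.isfinite(s) for s in spacing):
        raise ValueError(f"spacing must be three positive finite values, got {spacing}")
    return spacing


@dataclass
class ComplexVolume:
    """A 3-D complex-valued signal volume with voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D array, got shape {self.data.shape}")
        if not np.iscomplexobj(self.data):
            self.data = self.data.astype(np.complex128)
        self.spacing = _validate_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def copy(self) -> "ComplexVolume":
        return ComplexVolume(self.data.copy(), self.spacing)


@dataclass
class LabelVolume:
    """A 3-D integer segmentation volume; label 0 is background."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D array, got shape {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.integer):
            if not np.all(self.data == np.round(self.data)):
                raise ValueError("label volume must contain integers")
            self.data = self.data.astype(np.int32)
        if self.data.min() < 0:
            raise ValueError("labels must be non-negative (0 = background)")
        self.spacing = _validate_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def labels(self) -> np.ndarray:
        """Sorted nonzero labels present in the volume."""
        present = np.unique(self.data)
        return present[present > 0]

    def mask(self, label: int) -> np.ndarray:
        return self.data == label

    def foreground(self) -> np.ndarray:
        return self.data > 0


@dataclass
class ScalarVolume:
    """A 3-D real-valued volume (magnitude images, conductivity maps)."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D array, got shape {self.data.shape}")
        self.spacing = _validate_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def copy(self) -> "ScalarVolume":
        return ScalarVolume(self.data.copy(), self.spacing)


def check_aligned(a, b, what: str = "volumes") -> None:
    """Raise if two volumes disagree on grid shape or voxel spacing."""
    if a.shape != b.shape:
        raise ValueError(f"{what} have mismatched shapes: {a.shape} vs {b.shape}")
    if not np.allclose(a.spacing, b.spacing, rtol=1e-6):
        raise ValueError(f"{what} have mismatched spacing: {a.spacing} vs {b.spacing}")
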