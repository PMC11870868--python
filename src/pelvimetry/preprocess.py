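"""Volume container, voxel<->physical transforms, resampling, normalization.

Clinical sagittal T2 volumes arrive with heterogeneous, strongly
anisotropic voxel sizes. Everything downstream assumes a common
reference grid (default 0.67 x 0.67 x 4.3 mm, the dataset-mean spacing)
and a normalized intensity range, so this module owns:

* :class:`VolumeGrid` -- a 3D intensity array plus spacing/origin/direction,
  i.e. the minimal affine metadata needed to map voxel indices to mm;
* trilinear resampling onto the reference spacing;
* percentile-based intensity normalization.

Conventions: voxel indices are 0-based and refer to voxel *centers*;
the canonical axis order is (in-plane row, in-plane column, slice),
with the slice axis carrying the thick (~4.3 mm) spacing.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import ndimage

from .errors import InvalidMetadataError, ConfigError


@dataclass
class VolumeGrid:
    """A 3D image grid with physical-space metadata.

    ``physical = origin + direction @ (spacing * index)`` with the index
    at the voxel center.
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = None  # type: ignore[assignment]
    direction: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3 or min(self.data.shape) < 2:
            raise InvalidMetadataError(
                f"volume must be 3D with every axis >= 2, got shape {self.data.shape}"
            )
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.spacing)) or np.any(self.spacing <= 0):
            raise InvalidMetadataError(f"spacing must be positive: {self.spacing}")
        self.origin = (
            np.zeros(3) if self.origin is None else np.asarray(self.origin, dtype=float).reshape(3)
        )
        self.direction = (
            np.eye(3) if self.direction is None else np.asarray(self.direction, dtype=float).reshape(3, 3)
        )

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> physical-mm affine (voxel centers)."""
        A = np.eye(4)
        A[:3, :3] = self.direction * self.spacing[np.newaxis, :]
        A[:3, 3] = self.origin
        return A

    def physical_extent(self) -> np.ndarray:
        """Edge-to-edge physical size of the grid per axis, in mm."""
        return np.asarray(self.shape) * self.spacing

    def with_data(self, data: np.ndarray) -> "VolumeGrid":
        return VolumeGrid(data=data, spacing=self.spacing.copy(),
                          origin=self.origin.copy(), direction=self.direction.copy())


@dataclass(frozen=True)
class PreprocessConfig:
    """Reference grid + intensity-normalization parameters.

    ``reference_spacing`` defaults to the dataset-mean clinical voxel
    size. Percentile bounds are per-volume; clipping to [0, 1] is the
    default but can be disabled when relative intensities above the
    high percentile carry information.
    """

    reference_spacing: Tuple[float, float, float] = (0.67, 0.67, 4.3)
    low_percentile: float = 1.0
    high_percentile: float = 99.0
    clip: bool = True

    def __post_init__(self):
        lo, hi = self.low_percentile, self.high_percentile
        if not (0.0 <= lo < hi <= 100.0):
            raise ConfigError(f"percentiles must satisfy 0 <= low < high <= 100: {lo}, {hi}")
        if any(s <= 0 for s in self.reference_spacing):
            raise ConfigError(f"reference spacing must be positive: {self.reference_spacing}")


def voxel_to_physical(index, volume: VolumeGrid) -> np.ndarray:
    """Map (possibly fractional) voxel indices to physical mm points."""
    idx = np.asarray(index, dtype=float)
    return (volume.direction @ (volume.spacing * idx).T).T + volume.origin


def physical_to_voxel(point, volume: VolumeGrid) -> np.ndarray:
    """Map physical mm points to continuous voxel coordinates (inverse of above)."""
    p = np.asarray(point, dtype=float)
    return (volume.direction.T @ (p - volume.origin).T).T / volume.spacing


def is_inside(point, volume: VolumeGrid) -> bool:
    """True when a physical point falls inside the grid's voxel-center hull."""
    v = physical_to_voxel(point, volume)
    return bool(np.all(v >= 0) and np.all(v <= np.asarray(volume.shape) - 1))


def resample_to_reference(volume: VolumeGrid, config: PreprocessConfig) -> VolumeGrid:
    """Trilinearly resample a volume onto the reference spacing.

    The output grid keeps the input's origin and orientation; its shape
    is ``round(shape * spacing / reference_spacing)`` (minimum 2), which
    preserves the physical extent to within one output voxel. Physical
    positions of features are preserved exactly by construction of the
    index mapping.
    """
    ref = np.asarray(config.reference_spacing, dtype=float)
    out_shape = np.maximum(
        2, np.round(np.asarray(volume.shape) * volume.spacing / ref).astype(int)
    )
    out = VolumeGrid(
        data=np.zeros(tuple(out_shape), dtype=np.float32),
        spacing=ref,
        origin=volume.origin.copy(),
        direction=volume.direction.copy(),
    )
    # index map: out voxel -> physical -> in voxel; shared origin/direction
    # reduces it to a per-axis scale in index space.
    scale = ref / volume.spacing
    grids = np.meshgrid(*[np.arange(n) * s for n, s in zip(out_shape, scale)], indexing="ij")
    coords = np.stack([g.ravel() for g in grids])
    sampled = ndimage.map_coordinates(
        volume.data.astype(np.float64), coords, order=1, mode="nearest"
    )
    out.data = sampled.reshape(tuple(out_shape)).astype(np.float32)
    return out


def normalize_percentile(volume: VolumeGrid, config: PreprocessConfig) -> VolumeGrid:
    """Affinely map the low/high intensity percentiles to 0/1.

    Degenerate volumes (equal percentiles) come back all-zero. With
    ``clip`` set, output is clipped to [0, 1]; without it, values
    outside the percentile window keep their relative scale.
    """
    lo, hi = np.percentile(volume.data, [config.low_percentile, config.high_percentile])
    if hi <= lo:
        return volume.with_data(np.zeros_like(volume.data))
    out = (volume.data - lo) / (hi - lo)
    if config.clip:
        out = np.clip(out, 0.0, 1.0)
    return volume.with_data(out.astype(np.float32))


def preprocess_volume(volume: VolumeGrid, config: PreprocessConfig) -> VolumeGrid:
    """Resample onto the reference grid, then normalize intensities."""
    return normalize_percentile(resample_to_reference(volume, config), config)
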