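"""Gaussian heatmap targets and argmax decoding.

Instead of regressing coordinates directly, each landmark is
represented by a probability-like volume whose peak marks the landmark
("heatmap regression"). Targets are isotropic Gaussians in voxel index
space (default sigma 5 voxels on the resampled grid); predictions are
decoded by taking the per-channel argmax and converting that voxel to
physical mm. The per-channel peak value doubles as a cheap confidence
score: imaging failures (e.g. a banding artifact hiding the os pubis)
show up as flat, low-peak heatmaps.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np

from .errors import ConfigError, InvalidInputError
from .geometry import LANDMARK_LABELS, LandmarkSet
from .preprocess import VolumeGrid, physical_to_voxel, voxel_to_physical


@dataclass(frozen=True)
class HeatmapConfig:
    """Gaussian target parameters.

    ``sigma_voxels`` follows the training convention of an isotropic
    sigma in *index* space on the resampled grid (hence physically
    anisotropic). Set ``sigma_in_mm`` to interpret the value in mm
    instead. ``peak_normalized`` scales each channel to a maximum of 1.
    """

    sigma_voxels: float = 5.0
    peak_normalized: bool = True
    sigma_in_mm: bool = False

    def __post_init__(self):
        if not (self.sigma_voxels > 0):
            raise ConfigError(f"sigma must be positive: {self.sigma_voxels}")


@dataclass
class HeatmapStack:
    """Five per-landmark heatmaps aligned to one VolumeGrid.

    ``data`` has shape (5, nx, ny, nz) in the fixed label order A-E.
    ``out_of_bounds`` flags channels whose landmark fell outside the
    grid (those channels are all-zero).
    """

    data: np.ndarray
    out_of_bounds: Tuple[bool, ...] = (False,) * 5

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 4 or self.data.shape[0] != len(LANDMARK_LABELS):
            raise InvalidInputError(
                f"heatmap stack must be (5, nx, ny, nz), got {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise InvalidInputError("heatmap stack contains non-finite values")

    def channel(self, label: str) -> np.ndarray:
        return self.data[LANDMARK_LABELS.index(label)]


def make_heatmap_targets(
    landmarks: LandmarkSet, volume: VolumeGrid, config: HeatmapConfig
) -> HeatmapStack:
    """Build the five Gaussian target channels for one volume.

    Each present, in-bounds landmark yields a closed-form Gaussian bump
    centered at its continuous voxel coordinate (separable outer
    product, no filtering pass). Missing or out-of-bounds landmarks
    yield all-zero channels, the latter flagged.
    """
    shape = volume.shape
    stack = np.zeros((len(LANDMARK_LABELS),) + shape, dtype=np.float32)
    oob = [False] * len(LANDMARK_LABELS)
    if config.sigma_in_mm:
        sigmas = config.sigma_voxels / volume.spacing  # mm -> per-axis voxels
    else:
        sigmas = np.full(3, float(config.sigma_voxels))
    for ci, label in enumerate(LANDMARK_LABELS):
        p = landmarks.get(label)
        if p is None:
            continue
        c = physical_to_voxel(p, volume)
        if np.any(c < 0) or np.any(c > np.asarray(shape) - 1):
            oob[ci] = True
            continue
        axes = [
            np.exp(-((np.arange(n) - cj) ** 2) / (2.0 * sj**2))
            for n, cj, sj in zip(shape, c, sigmas)
        ]
        g = axes[0][:, None, None] * axes[1][None, :, None] * axes[2][None, None, :]
        if config.peak_normalized:
            m = g.max()
            if m > 0:
                g = g / m
        stack[ci] = g
    return HeatmapStack(data=stack, out_of_bounds=tuple(oob))


def peak_confidence(stack: HeatmapStack) -> np.ndarray:
    """Per-channel maximum value, in label order A-E."""
    return stack.data.reshape(stack.data.shape[0], -1).max(axis=1)


def decode_heatmaps(
    stack: HeatmapStack,
    volume: VolumeGrid,
    floor: float = 0.0,
) -> Tuple[LandmarkSet, Dict[str, float], Dict[str, bool]]:
    """Argmax-decode a heatmap stack into physical landmark coordinates.

    Per channel, the voxel index of the maximum value is converted to
    physical mm. Ties break deterministically to the lowest
    lexicographic index (C-order argmax) and are flagged low-confidence.
    Channels whose peak is <= ``floor`` (default 0 = only all-zero /
    non-positive channels) decode as missing.

    Returns ``(landmarks, confidences, low_confidence_flags)``.
    """
    if stack.data.shape[1:] != volume.shape:
        raise InvalidInputError(
            f"stack shape {stack.data.shape[1:]} does not match volume {volume.shape}"
        )
    points: Dict[str, Optional[np.ndarray]] = {}
    confidences: Dict[str, float] = {}
    flags: Dict[str, bool] = {}
    for ci, label in enumerate(LANDMARK_LABELS):
        ch = stack.data[ci]
        peak = float(ch.max())
        confidences[label] = peak
        if peak <= floor:
            points[label] = None
            flags[label] = True
            continue
        flat = int(np.argmax(ch))  # C-order -> lowest lexicographic index on ties
        idx = np.unravel_index(flat, ch.shape)
        ties = int(np.count_nonzero(ch == peak))
        flags[label] = ties > 1
        points[label] = voxel_to_physical(np.asarray(idx, dtype=float), volume)
    return LandmarkSet(points), confidences, flags
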