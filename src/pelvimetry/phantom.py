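"""Synthetic pelvis phantoms with known landmark ground truth.

Real sagittal T2 volumes are not redistributable, so every other module
is exercised on phantoms: anisotropic grids containing five bright
Gaussian blobs arranged like the sagittal pelvic landmarks, with
configurable geometry ranges, background noise, a multi-institute
cohort structure, a simulated second observer, and an optional dark
banding slab emulating the MR artifact that can occlude the os pubis.

The five blobs carry distinct intensities so a channel-ordering bug in
the localizer is observable as a systematic landmark swap.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import json
import numpy as np

from .errors import ConfigError, DataError, PlacementError
from .geometry import LANDMARK_LABELS, LandmarkSet, compute_dimensions
from .preprocess import VolumeGrid, is_inside
from .evaluation import CohortTable, PatientRecord
from . import io as pio


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry ranges, rendering and artifact parameters for phantoms.

    The default grid (96 x 96 x 16 at 1.5 x 1.5 x 4.3 mm) is coarser
    in-plane than the clinical reference spacing so CPU training stays
    fast; :meth:`paper_like` matches the clinical voxel size.
    Dimension ranges (mm / degrees) bracket adult pelvic anatomy.
    """

    shape: Tuple[int, int, int] = (96, 96, 16)
    spacing: Tuple[float, float, float] = (1.5, 1.5, 4.3)
    inlet_range: Tuple[float, float] = (100.0, 140.0)
    depth_range: Tuple[float, float] = (90.0, 130.0)
    outlet_range: Tuple[float, float] = (70.0, 110.0)
    angle_range: Tuple[float, float] = (140.0, 175.0)
    blob_radius_mm: float = 6.0
    #: per-landmark radius multipliers (A-E); distinct spatial scales give
    #: the localizer a conv-friendly channel-identity cue alongside intensity.
    #: radius runs opposite to contrast so the dimmest blob is the sharpest,
    #: equalizing peak-localization precision across channels
    radius_profile: Tuple[float, ...] = (2.0, 1.75, 1.5, 1.25, 1.0)
    blob_contrast: float = 1.0
    #: per-landmark intensity multipliers (A-E), deliberately distinct
    contrast_profile: Tuple[float, ...] = (1.6, 1.3, 1.0, 0.75, 0.5)
    noise_sd: float = 0.05
    #: per-phantom global blob-amplitude scale (uniform range) and
    #: per-landmark multiplicative contrast jitter (lognormal-ish, SD),
    #: emulating scanner/protocol variability across a multi-center cohort
    amplitude_scale_range: Tuple[float, float] = (0.8, 1.25)
    contrast_jitter_sd: float = 0.05
    #: per-landmark multiplicative blob-size jitter (lognormal SD),
    #: emulating anatomical size variation between patients
    radius_jitter_sd: float = 0.04
    #: in-plane log-stretch SD of each blob's axes (random orientation),
    #: emulating non-spherical bony landmarks; off by default
    asymmetry_sd: float = 0.0
    out_of_plane_jitter_mm: float = 1.0
    banding_artifact: bool = False
    band_axis: int = 1
    band_center_mm: Optional[float] = None  # None -> centered on D/E
    band_width_mm: float = 25.0
    band_attenuation: float = 0.1

    def __post_init__(self):
        for name in ("inlet_range", "depth_range", "outlet_range", "angle_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ConfigError(f"{name} must be non-degenerate: ({lo}, {hi})")
        if self.blob_radius_mm < max(self.spacing):
            raise ConfigError(
                f"blob radius {self.blob_radius_mm} mm under one voxel at spacing {self.spacing}"
            )
        if len(self.contrast_profile) != len(LANDMARK_LABELS):
            raise ConfigError("contrast profile needs one value per landmark")
        if len(self.radius_profile) != len(LANDMARK_LABELS):
            raise ConfigError("radius profile needs one value per landmark")

    def blob_radii_mm(self) -> Tuple[float, ...]:
        return tuple(self.blob_radius_mm * r for r in self.radius_profile)

    @classmethod
    def paper_like(cls, **overrides) -> "PhantomConfig":
        """Preset at the clinical reference voxel size (fidelity runs)."""
        kwargs = dict(shape=(215, 215, 16), spacing=(0.67, 0.67, 4.3))
        kwargs.update(overrides)
        return cls(**kwargs)


def _rot2(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def sample_landmark_geometry(
    config: PhantomConfig, rng: np.random.Generator, max_tries: int = 100
) -> LandmarkSet:
    """Draw a pelvis-like landmark arrangement with dimensions in range.

    Points are constructed in the sagittal (in-plane) plane -- sacral
    curve A-B-C, pubic points D/E anterior -- then jittered slightly out
    of plane and translated to fit the grid with a blob-sized margin.
    Draws violating the configured ranges after jitter are rejected;
    infeasible configs raise :class:`ConfigError` after ``max_tries``.
    """
    shape = np.asarray(config.shape)
    spacing = np.asarray(config.spacing)
    margin = config.blob_radius_mm + 2.0  # blob centers may sit nearer the edge than the largest tail
    usable = (shape[:2] - 1) * spacing[:2] - 2 * margin
    if np.any(usable <= 0):
        raise ConfigError("grid too small for blob margin")
    z_mid = (shape[2] - 1) * spacing[2] / 2.0

    for _ in range(max_tries):
        inlet = rng.uniform(*config.inlet_range)
        depth = rng.uniform(*config.depth_range)
        outlet = rng.uniform(*config.outlet_range)
        angle = rng.uniform(*config.angle_range)

        theta_ac = np.radians(rng.uniform(245.0, 255.0))
        d_ac = np.array([np.cos(theta_ac), np.sin(theta_ac)])
        A2 = np.zeros(2)
        C2 = A2 + depth * d_ac
        normal = np.array([-d_ac[1], d_ac[0]])
        if normal[0] > 0:  # keep B on the posterior side
            normal = -normal
        h = (depth / 2.0) / np.tan(np.radians(angle) / 2.0)
        B2 = (A2 + C2) / 2.0 + h * normal
        delta = np.radians(rng.uniform(45.0, 60.0))
        E2 = A2 + inlet * (_rot2(delta) @ d_ac)
        w = E2 - C2
        w = w / np.linalg.norm(w)
        # rotate D a little off the C->E line so the two pubic blobs stay resolvable
        phi = np.radians(rng.uniform(-12.0, 12.0))
        D2 = C2 + outlet * (_rot2(phi) @ w)
        if np.linalg.norm(E2 - D2) < 20.0:
            continue

        pts2 = np.stack([A2, B2, C2, D2, E2])
        bbox_min, bbox_max = pts2.min(axis=0), pts2.max(axis=0)
        size = bbox_max - bbox_min
        if np.any(size > usable):
            continue
        slack = usable - size
        offset = margin - bbox_min + slack * rng.uniform(0.3, 0.7, size=2)
        pts2 = pts2 + offset

        z = z_mid + rng.normal(0.0, config.out_of_plane_jitter_mm, size=5)
        pts = np.column_stack([pts2, z])
        lm = LandmarkSet(dict(zip(LANDMARK_LABELS, pts)))
        dims = compute_dimensions(lm)
        ok = (
            config.inlet_range[0] <= dims.inlet_mm <= config.inlet_range[1]
            and config.depth_range[0] <= dims.depth_mm <= config.depth_range[1]
            and config.outlet_range[0] <= dims.outlet_mm <= config.outlet_range[1]
            and config.angle_range[0] <= dims.sacral_angle_deg <= config.angle_range[1]
        )
        if ok:
            return lm
    raise ConfigError("could not sample a feasible landmark geometry")


def render_phantom(
    landmarks: LandmarkSet, config: PhantomConfig, rng: np.random.Generator
) -> VolumeGrid:
    """Render a phantom volume: noise background + five Gaussian blobs.

    Blob profiles are isotropic in mm (hence anisotropic in voxels);
    each landmark is a local intensity maximum in the artifact-free
    image. With ``banding_artifact`` set, a slab perpendicular to
    ``band_axis`` is attenuated, by default centered between D and E.
    """
    shape = config.shape
    spacing = np.asarray(config.spacing)
    vol = VolumeGrid(data=np.zeros(shape, dtype=np.float32), spacing=spacing)
    for label in LANDMARK_LABELS:
        p = landmarks.get(label)
        if p is not None and not is_inside(p, vol):
            raise PlacementError(f"landmark {label} at {p} outside grid extent")

    data = (
        rng.normal(0.0, config.noise_sd, size=shape)
        if config.noise_sd > 0
        else np.zeros(shape)
    )
    axes_mm = [np.arange(n) * s for n, s in zip(shape, spacing)]
    radii = config.blob_radii_mm()
    scale = rng.uniform(*config.amplitude_scale_range)
    jitter = np.exp(rng.normal(0.0, config.contrast_jitter_sd, size=len(LANDMARK_LABELS)))
    rjitter = np.exp(rng.normal(0.0, config.radius_jitter_sd, size=len(LANDMARK_LABELS)))
    stretch = np.exp(rng.normal(0.0, config.asymmetry_sd, size=len(LANDMARK_LABELS)))
    phis = rng.uniform(0.0, np.pi, size=len(LANDMARK_LABELS))
    for ci, label in enumerate(LANDMARK_LABELS):
        p = landmarks.get(label)
        if p is None:
            continue
        r = radii[ci] * rjitter[ci]
        # in-plane elliptical cross-section: principal radii r*stretch, r/stretch
        # at a random orientation; the landmark stays the intensity maximum
        cphi, sphi = np.cos(phis[ci]), np.sin(phis[ci])
        du = (axes_mm[0] - p[0])[:, None] * cphi + (axes_mm[1] - p[1])[None, :] * sphi
        dv = -(axes_mm[0] - p[0])[:, None] * sphi + (axes_mm[1] - p[1])[None, :] * cphi
        g2d = np.exp(
            -(du**2) / (2.0 * (r * stretch[ci]) ** 2)
            - (dv**2) / (2.0 * (r / stretch[ci]) ** 2)
        )
        gz = np.exp(-((axes_mm[2] - p[2]) ** 2) / (2.0 * r**2))
        amp = scale * jitter[ci] * config.blob_contrast * config.contrast_profile[ci]
        data = data + amp * g2d[:, :, None] * gz[None, None, :]

    if config.banding_artifact:
        ax = config.band_axis
        center = config.band_center_mm
        if center is None:
            d, e = landmarks.get("D"), landmarks.get("E")
            if d is None or e is None:
                raise PlacementError("auto band placement needs landmarks D and E")
            center = float((d[ax] + e[ax]) / 2.0)
        coord = axes_mm[ax]
        mask = np.abs(coord - center) <= config.band_width_mm / 2.0
        sl = [slice(None)] * 3
        sl[ax] = mask
        data[tuple(sl)] *= config.band_attenuation

    vol.data = data.astype(np.float32)
    return vol


def simulate_second_observer(
    landmarks: LandmarkSet, noise_sd_mm: float, rng: np.random.Generator
) -> LandmarkSet:
    """Jitter every present landmark by isotropic Gaussian noise (mm)."""
    pts = {}
    for label in LANDMARK_LABELS:
        p = landmarks.get(label)
        pts[label] = None if p is None else p + rng.normal(0.0, noise_sd_mm, size=3)
    return LandmarkSet(pts)


def generate_cohort(
    n: int,
    institute_profile: Optional[Sequence[int]] = None,
    config: Optional[PhantomConfig] = None,
    seed: int = 0,
    observer_noise_sd: Optional[float] = None,
    out_dir=None,
) -> CohortTable:
    """Generate a seeded multi-institute phantom cohort.

    ``institute_profile`` gives per-institute patient counts (summing to
    ``n``; default one institute). Each patient gets an independent
    sub-seeded geometry and rendering; ``observer_noise_sd`` (mm)
    additionally simulates a blinded second observer (0.0 duplicates
    the reference exactly). With ``out_dir`` set, volumes, landmark
    files and a manifest are written to disk.
    """
    if n < 1:
        raise DataError("cohort size must be >= 1")
    config = config or PhantomConfig()
    profile = list(institute_profile) if institute_profile is not None else [n]
    if sum(profile) != n:
        raise DataError(f"institute profile {profile} does not sum to n={n}")
    institutes: List[str] = []
    for ii, count in enumerate(profile, start=1):
        institutes.extend([f"institute-{ii}"] * count)

    records: List[PatientRecord] = []
    for idx in range(n):
        rng = np.random.default_rng([seed, idx])
        lm = sample_landmark_geometry(config, rng)
        vol = render_phantom(lm, config, rng)
        obs2 = None
        if observer_noise_sd is not None:
            obs2 = simulate_second_observer(
                lm, observer_noise_sd, np.random.default_rng([seed, idx, 1])
            )
        records.append(
            PatientRecord(
                volume_id=f"phantom-{idx:04d}",
                institute_id=institutes[idx],
                reference=lm,
                volume=vol,
                observer2=obs2,
            )
        )
    cohort = CohortTable(records=records)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        entries = {}
        manifest = {"seed": seed, "n": n, "patients": []}
        for rec in cohort:
            vol_path = out / f"{rec.volume_id}.nii.gz"
            pio.save_volume(vol_path, rec.volume)
            entries[rec.volume_id] = (rec.institute_id, rec.reference)
            manifest["patients"].append(
                {
                    "volume_id": rec.volume_id,
                    "institute_id": rec.institute_id,
                    "volume_file": vol_path.name,
                }
            )
        pio.save_landmarks_json(out / "landmarks.json", entries)
        pio.save_landmarks_csv(out / "landmarks.csv", entries)
        if observer_noise_sd is not None:
            pio.save_landmarks_json(
                out / "landmarks_observer2.json",
                {r.volume_id: (r.institute_id, r.observer2) for r in cohort},
            )
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return cohort
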