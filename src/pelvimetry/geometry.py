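"""Pelvic landmarks and the dimensions derived from them.

Five anatomic landmarks on the sagittal view of the bony pelvis --
promontorium (A), S3 vertebra (B), coccyx (C), dorsal os pubis (D) and
cranial os pubis (E) -- define four clinically predictive dimensions:

* pelvic inlet  = |A - E|  (mm)
* pelvic outlet = |C - D|  (mm)
* pelvic depth  = |A - C|  (mm)
* sacral angulation = angle at B between rays B->A and B->C  (degrees)

All geometry lives in physical millimetre space; voxel-to-mm conversion
happens upstream (see :mod:`pelvimetry.preprocess`) because clinical
voxels are strongly anisotropic.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterator, Mapping, Optional, Sequence, Tuple

import numpy as np

from .errors import DataError, DegenerateGeometryError, InvalidInputError

#: Canonical landmark labels, in fixed order.
LANDMARK_LABELS: Tuple[str, ...] = ("A", "B", "C", "D", "E")

#: Human-readable anatomical names.
LANDMARK_NAMES: Dict[str, str] = {
    "A": "promontorium",
    "B": "S3-vertebra",
    "C": "coccyx",
    "D": "dorsal os pubis",
    "E": "cranial os pubis",
}

#: dimension name -> landmark labels required to measure it
DIMENSION_LANDMARKS: Dict[str, Tuple[str, ...]] = {
    "inlet_mm": ("A", "E"),
    "outlet_mm": ("C", "D"),
    "depth_mm": ("A", "C"),
    "sacral_angle_deg": ("A", "B", "C"),
}


def _as_point(p) -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    if arr.shape != (3,):
        raise InvalidInputError(f"expected a 3D point, got shape {arr.shape}")
    return arr


class LandmarkSet:
    """The five pelvic landmarks as 3D points in physical mm.

    Any subset of landmarks may be missing (``None``); downstream
    dimensions that depend on a missing landmark are flagged
    unmeasurable rather than raising.
    """

    __slots__ = ("_points",)

    def __init__(self, points: Mapping[str, Optional[Sequence[float]]]):
        unknown = set(points) - set(LANDMARK_LABELS)
        if unknown:
            raise InvalidInputError(f"unknown landmark labels: {sorted(unknown)}")
        self._points: Dict[str, Optional[np.ndarray]] = {}
        for label in LANDMARK_LABELS:
            p = points.get(label)
            if p is None:
                self._points[label] = None
            else:
                arr = _as_point(p)
                if not np.all(np.isfinite(arr)):
                    raise InvalidInputError(
                        f"landmark {label} has non-finite coordinates: {arr}"
                    )
                self._points[label] = arr

    @classmethod
    def from_points(cls, A=None, B=None, C=None, D=None, E=None) -> "LandmarkSet":
        return cls({"A": A, "B": B, "C": C, "D": D, "E": E})

    def __getitem__(self, label: str) -> np.ndarray:
        p = self._points[label]
        if p is None:
            raise KeyError(f"landmark {label} is missing")
        return p

    def get(self, label: str) -> Optional[np.ndarray]:
        return self._points[label]

    def is_missing(self, label: str) -> bool:
        return self._points[label] is None

    @property
    def present_labels(self) -> Tuple[str, ...]:
        return tuple(l for l in LANDMARK_LABELS if self._points[l] is not None)

    def __iter__(self) -> Iterator[str]:
        return iter(LANDMARK_LABELS)

    def __eq__(self, other) -> bool:
        if not isinstance(other, LandmarkSet):
            return NotImplemented
        for l in LANDMARK_LABELS:
            a, b = self._points[l], other._points[l]
            if (a is None) != (b is None):
                return False
            if a is not None and not np.array_equal(a, b):
                return False
        return True

    def __repr__(self) -> str:
        parts = ", ".join(
            f"{l}={'missing' if p is None else np.round(p, 2).tolist()}"
            for l, p in self._points.items()
        )
        return f"LandmarkSet({parts})"

    def as_dict(self) -> Dict[str, Optional[Tuple[float, float, float]]]:
        return {
            l: None if p is None else tuple(float(x) for x in p)
            for l, p in self._points.items()
        }

    def transformed(self, rotation: np.ndarray, translation: Sequence[float]) -> "LandmarkSet":
        """Apply a rigid transform ``x -> R x + t`` to every present landmark."""
        R = np.asarray(rotation, dtype=float)
        t = _as_point(translation)
        return LandmarkSet(
            {l: None if p is None else R @ p + t for l, p in self._points.items()}
        )


@dataclass(frozen=True)
class PelvicDimensions:
    """The four pelvic dimensions; ``None`` marks an unmeasurable value."""

    inlet_mm: Optional[float] = None
    outlet_mm: Optional[float] = None
    depth_mm: Optional[float] = None
    sacral_angle_deg: Optional[float] = None

    def as_dict(self) -> Dict[str, Optional[float]]:
        return {
            "inlet_mm": self.inlet_mm,
            "outlet_mm": self.outlet_mm,
            "depth_mm": self.depth_mm,
            "sacral_angle_deg": self.sacral_angle_deg,
        }

    def __post_init__(self):
        for name, value in self.as_dict().items():
            if value is None:
                continue
            if not np.isfinite(value):
                raise InvalidInputError(f"{name} is non-finite: {value}")
            if name != "sacral_angle_deg" and value < 0:
                raise InvalidInputError(f"{name} must be non-negative: {value}")
        if self.sacral_angle_deg is not None and not (
            0.0 <= self.sacral_angle_deg <= 180.0
        ):
            raise InvalidInputError(
                f"sacral angle must lie in [0, 180] degrees: {self.sacral_angle_deg}"
            )


def euclidean_distance(p, q) -> float:
    """Euclidean distance in mm between two 3D physical points."""
    pa, qa = _as_point(p), _as_point(q)
    if not (np.all(np.isfinite(pa)) and np.all(np.isfinite(qa))):
        raise InvalidInputError("distance requires finite coordinates")
    return float(np.linalg.norm(pa - qa))


def angle_at_vertex(a, b, c) -> float:
    """Angle in degrees at vertex ``b`` between rays b->a and b->c.

    The cosine is clamped to [-1, 1] before arccos so that collinear
    configurations do not fall outside the domain through rounding.
    """
    aa, ba, ca = _as_point(a), _as_point(b), _as_point(c)
    u = aa - ba
    v = ca - ba
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise DegenerateGeometryError("angle undefined: zero-length ray at vertex")
    cosang = float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))


def compute_dimensions(landmarks: LandmarkSet) -> PelvicDimensions:
    """Derive the four pelvic dimensions from a (possibly partial) LandmarkSet.

    Dimensions whose required landmarks are missing come back as ``None``;
    a fully missing LandmarkSet raises :class:`DataError`.
    """
    if not landmarks.present_labels:
        raise DataError("all landmarks missing: no dimension is measurable")

    def have(*labels: str) -> bool:
        return all(not landmarks.is_missing(l) for l in labels)

    inlet = euclidean_distance(landmarks["A"], landmarks["E"]) if have("A", "E") else None
    outlet = euclidean_distance(landmarks["C"], landmarks["D"]) if have("C", "D") else None
    depth = euclidean_distance(landmarks["A"], landmarks["C"]) if have("A", "C") else None
    angle = None
    if have("A", "B", "C"):
        try:
            angle = angle_at_vertex(landmarks["A"], landmarks["B"], landmarks["C"])
        except DegenerateGeometryError:
            # coincident predicted points: unmeasurable, not an error
            angle = None
    return PelvicDimensions(
        inlet_mm=inlet, outlet_mm=outlet, depth_mm=depth, sacral_angle_deg=angle
    )


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3D rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
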