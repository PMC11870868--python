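"""File formats: NIfTI volumes, landmark JSON/CSV, cohort manifests.

Landmark files carry physical-mm coordinates, one record per volume:
JSON as ``{"volume_id", "institute_id", "landmarks": {label: {x_mm, y_mm,
z_mm} | null}}`` and CSV as flat rows (volume_id, institute, landmark,
x_mm, y_mm, z_mm) with missing landmarks omitted. Floats survive the
round trip bit-exactly (shortest-repr serialization).
"""
from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Dict, Tuple

import nibabel as nib
import numpy as np

from .errors import InvalidMetadataError
from .geometry import LANDMARK_LABELS, LandmarkSet
from .heatmap import HeatmapStack
from .preprocess import VolumeGrid


# -- NIfTI -----------------------------------------------------------------

def save_volume(path, volume: VolumeGrid) -> None:
    """Write a VolumeGrid as NIfTI, spacing/origin/direction in the affine."""
    img = nib.Nifti1Image(volume.data.astype(np.float32), volume.affine)
    nib.save(img, str(path))


def load_volume(path) -> VolumeGrid:
    """Read a NIfTI file into a VolumeGrid, decomposing its affine."""
    img = nib.load(str(path))
    affine = np.asarray(img.affine, dtype=float)
    lin = affine[:3, :3]
    spacing = np.linalg.norm(lin, axis=0)
    if np.any(spacing <= 0) or not np.all(np.isfinite(spacing)):
        raise InvalidMetadataError(f"unusable affine in {path}: spacing {spacing}")
    direction = lin / spacing[np.newaxis, :]
    data = np.asanyarray(img.dataobj).astype(np.float32)
    if data.ndim != 3:
        raise InvalidMetadataError(f"{path}: expected a 3D volume, got shape {data.shape}")
    return VolumeGrid(data=data, spacing=spacing, origin=affine[:3, 3], direction=direction)


def save_heatmap_stack(path, stack: HeatmapStack, volume: VolumeGrid) -> None:
    """Write the five heatmaps as a 4D NIfTI (channel as 4th axis)."""
    data = np.moveaxis(stack.data, 0, -1).astype(np.float32)
    nib.save(nib.Nifti1Image(data, volume.affine), str(path))


# -- landmark files --------------------------------------------------------

def _landmark_record(volume_id: str, institute_id: str, landmarks: LandmarkSet) -> dict:
    lm = {}
    for label in LANDMARK_LABELS:
        p = landmarks.get(label)
        lm[label] = (
            None
            if p is None
            else {"x_mm": float(p[0]), "y_mm": float(p[1]), "z_mm": float(p[2])}
        )
    return {"volume_id": volume_id, "institute_id": institute_id, "landmarks": lm}


def save_landmarks_json(path, entries: Dict[str, Tuple[str, LandmarkSet]]) -> None:
    """``entries``: volume_id -> (institute_id, LandmarkSet)."""
    records = [
        _landmark_record(vid, inst, lm) for vid, (inst, lm) in sorted(entries.items())
    ]
    Path(path).write_text(json.dumps(records, indent=1))


def load_landmarks_json(path) -> Dict[str, Tuple[str, LandmarkSet]]:
    records = json.loads(Path(path).read_text())
    out: Dict[str, Tuple[str, LandmarkSet]] = {}
    for rec in records:
        pts = {}
        for label, v in rec["landmarks"].items():
            pts[label] = None if v is None else (v["x_mm"], v["y_mm"], v["z_mm"])
        out[rec["volume_id"]] = (rec["institute_id"], LandmarkSet(pts))
    return out


def load_cohort_dir(path) -> "CohortTable":
    """Load a simulated cohort directory (manifest + volumes + landmarks)."""
    from .evaluation import CohortTable, PatientRecord

    root = Path(path)
    manifest = json.loads((root / "manifest.json").read_text())
    landmarks = load_landmarks_json(root / "landmarks.json")
    obs2_path = root / "landmarks_observer2.json"
    observer2 = load_landmarks_json(obs2_path) if obs2_path.exists() else {}
    records = []
    for entry in manifest["patients"]:
        vid = entry["volume_id"]
        inst, ref = landmarks[vid]
        records.append(
            PatientRecord(
                volume_id=vid,
                institute_id=inst,
                reference=ref,
                volume=load_volume(root / entry["volume_file"]),
                observer2=observer2.get(vid, (None, None))[1],
            )
        )
    return CohortTable(records=records)


CSV_COLUMNS = ["volume_id", "institute", "landmark", "x_mm", "y_mm", "z_mm"]


def save_landmarks_csv(path, entries: Dict[str, Tuple[str, LandmarkSet]]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(CSV_COLUMNS)
        for vid, (inst, lm) in sorted(entries.items()):
            for label in LANDMARK_LABELS:
                p = lm.get(label)
                if p is None:
                    continue
                w.writerow([vid, inst, label, repr(float(p[0])), repr(float(p[1])), repr(float(p[2]))])


def load_landmarks_csv(path) -> Dict[str, Tuple[str, LandmarkSet]]:
    by_volume: Dict[str, Tuple[str, Dict[str, tuple]]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            inst, pts = by_volume.setdefault(row["volume_id"], (row["institute"], {}))
            pts[row["landmark"]] = (
                float(row["x_mm"]),
                float(row["y_mm"]),
                float(row["z_mm"]),
            )
    return {vid: (inst, LandmarkSet(pts)) for vid, (inst, pts) in by_volume.items()}
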