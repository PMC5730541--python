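"""Landmark and mesh file I/O.

Landmark files carry millimetre coordinates in the package's fixed frame
(right-handed; +x subject-left, +y anterior, +z superior), either as

* JSON: ``{"subject": id, "cranial": {"Cg": [x,y,z], "Lo_right": ...,
  "Lo_left": ...}, "left": {landmark: [x,y,z], ...}, "right": {...}}``, or
* flat CSV with columns ``subject, side, landmark, x, y, z`` where the
  cranial landmarks use side ``cranial``.

Meshes are read and written through trimesh (STL binary/ASCII, PLY, OBJ).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .geometry import LandmarkSet

__all__ = [
    "SubjectLandmarks",
    "read_landmarks_json",
    "write_landmarks_json",
    "read_landmarks_csv",
    "write_landmarks_csv",
    "load_mesh",
    "save_mesh",
]

CRANIAL_NAMES = ("Cg", "Lo_right", "Lo_left")


@dataclass
class SubjectLandmarks:
    """All landmarks of one subject: both hemimandibles plus the cranial
    midline landmarks."""

    subject_id: str
    left: LandmarkSet
    right: LandmarkSet
    cranial: dict

    def __post_init__(self) -> None:
        missing = set(CRANIAL_NAMES) - set(self.cranial)
        if missing:
            raise ValueError(f"missing cranial landmarks: {sorted(missing)}")
        self.cranial = {k: np.asarray(v, dtype=float) for k, v in self.cranial.items()}
        if not np.allclose(self.left["Me"], self.right["Me"], atol=1e-6):
            raise ValueError("Me must be identical on both sides (midline landmark)")


def _landmarks_to_lists(lm: LandmarkSet) -> dict:
    return {k: [float(c) for c in v] for k, v in lm.points.items()}


def write_landmarks_json(subject: SubjectLandmarks, path) -> None:
    doc = {
        "subject": subject.subject_id,
        "units": "mm",
        "frame": "+x subject-left, +y anterior, +z superior",
        "cranial": {k: [float(c) for c in v] for k, v in subject.cranial.items()},
        "left": _landmarks_to_lists(subject.left),
        "right": _landmarks_to_lists(subject.right),
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def read_landmarks_json(path) -> SubjectLandmarks:
    doc = json.loads(Path(path).read_text())
    return SubjectLandmarks(
        subject_id=str(doc["subject"]),
        left=LandmarkSet("left", doc["left"]),
        right=LandmarkSet("right", doc["right"]),
        cranial=doc["cranial"],
    )


def write_landmarks_csv(subjects: list[SubjectLandmarks], path) -> None:
    rows = []
    for s in subjects:
        for side, lm in (("left", s.left), ("right", s.right)):
            for name, p in lm.points.items():
                rows.append((s.subject_id, side, name, p[0], p[1], p[2]))
        for name, p in s.cranial.items():
            rows.append((s.subject_id, "cranial", name, p[0], p[1], p[2]))
    pd.DataFrame(rows, columns=["subject", "side", "landmark", "x", "y", "z"]).to_csv(
        path, index=False
    )


def read_landmarks_csv(path) -> list[SubjectLandmarks]:
    df = pd.read_csv(path)
    out = []
    for sid, g in df.groupby("subject", sort=False):
        per_side: dict = {}
        for side, sg in g.groupby("side"):
            per_side[side] = {
                r.landmark: np.array([r.x, r.y, r.z]) for r in sg.itertuples()
            }
        out.append(
            SubjectLandmarks(
                subject_id=str(sid),
                left=LandmarkSet("left", per_side["left"]),
                right=LandmarkSet("right", per_side["right"]),
                cranial=per_side["cranial"],
            )
        )
    return out


def load_mesh(path) -> trimesh.Trimesh:
    # process=True merges the per-facet duplicate vertices of STL files,
    # restoring shared-edge topology for the watertightness checks
    mesh = trimesh.load(str(path), force="mesh", process=True)
    if not isinstance(mesh, trimesh.Trimesh):
        raise ValueError(f"{path} did not contain a triangle mesh")
    return mesh


def save_mesh(mesh: trimesh.Trimesh, path) -> None:
    mesh.export(str(path))
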