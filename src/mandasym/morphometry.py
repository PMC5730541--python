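"""Per-subject morphometry: the six per-side measurements, bilateral
differences/ratios, menton deviation and FA/NA classification.

Per side, the measurements are

* body length      |Go_mid - Me|                             (mm)
* ramal height     |Cd - Go_mid|                             (mm)
* condylar height  |Cd - P|, P = intersection of the Cd-Go_mid
                   line with the condylar base plane          (mm)
* inferior ramal height  |P - Go_mid|                         (mm)
* gonial angle     angle Cd_post-Go_mid-Me                    (degrees)
* condylar volume  mesh volume superior to the base plane     (mm^3)

Condylar and inferior ramal height partition the ramal span, so their sum
equals ramal height exactly.  A subject is classified FA (facial asymmetry)
when |menton deviation| >= 4 mm, NA otherwise; the deviated side is the
side the menton deviates toward.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
import trimesh

from .geometry import LandmarkSet, condylar_base_plane, angle_at_vertex, _unit
from .mesh_volume import AnatomicalInconsistencyError, condylar_volume
from .reference import DEVIATION_THRESHOLD_MM, MEASUREMENTS

__all__ = [
    "SideMeasurements",
    "SubjectRecord",
    "BilateralVector",
    "measure_side",
    "bilateral",
    "classify",
    "records_to_frame",
]

log = logging.getLogger(__name__)

#: additivity tolerance for condylar + inferior ramal = ramal height (mm)
ADDITIVITY_TOL = 1e-6


@dataclass(frozen=True)
class SideMeasurements:
    """The six measurements of one hemimandible."""

    body_length: float
    ramal_height: float
    condylar_height: float
    inferior_ramal_height: float
    condylar_volume: float
    gonial_angle: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = float(getattr(self, f.name))
            object.__setattr__(self, f.name, v)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{f.name} must be positive and finite, got {v}")
        if abs(self.condylar_height + self.inferior_ramal_height - self.ramal_height) > ADDITIVITY_TOL:
            raise ValueError(
                "condylar_height + inferior_ramal_height must equal ramal_height "
                f"({self.condylar_height} + {self.inferior_ramal_height} != {self.ramal_height})"
            )

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in MEASUREMENTS}


@dataclass
class SubjectRecord:
    """Both sides of one subject plus the asymmetry bookkeeping."""

    subject_id: str
    left: SideMeasurements
    right: SideMeasurements
    menton_deviation: float
    deviated_side: str
    group: str

    def __post_init__(self) -> None:
        expect_group, expect_side = classify(self.menton_deviation)
        if self.group != expect_group:
            raise ValueError(
                f"group {self.group!r} inconsistent with deviation "
                f"{self.menton_deviation} mm (expected {expect_group})"
            )
        if self.deviated_side != expect_side and self.menton_deviation != 0.0:
            raise ValueError(
                f"deviated_side {self.deviated_side!r} contradicts the sign of "
                f"the menton deviation ({self.menton_deviation:+.2f} mm)"
            )

    @property
    def deviated(self) -> SideMeasurements:
        return self.left if self.deviated_side == "left" else self.right

    @property
    def nondeviated(self) -> SideMeasurements:
        return self.right if self.deviated_side == "left" else self.left


@dataclass(frozen=True)
class BilateralVector:
    """Per-measurement bilateral contrast: difference (nondeviated -
    deviated) and ratio (deviated / nondeviated)."""

    differences: dict
    ratios: dict

    def __post_init__(self) -> None:
        for m in MEASUREMENTS:
            r = self.ratios[m]
            d = self.differences[m]
            if r <= 0:
                raise ValueError(f"ratio for {m} must be positive, got {r}")
            if (r < 1) != (d > 0) and d != 0:
                raise ValueError(f"ratio/difference direction mismatch for {m}")


def classify(menton_deviation: float, threshold_mm: float = DEVIATION_THRESHOLD_MM) -> tuple[str, str]:
    """FA/NA group and deviated side from the signed menton deviation.

    |deviation| >= threshold (default 4 mm, boundary inclusive) -> FA.
    Positive deviation is toward the subject's left.  An exactly-zero
    deviation is assigned to the left side with a logged warning.
    """
    d = float(menton_deviation)
    if not np.isfinite(d):
        raise ValueError("menton deviation must be finite")
    group = "FA" if abs(d) >= threshold_mm else "NA"
    if d == 0.0:
        log.warning("menton deviation exactly 0; breaking side tie to 'left'")
        return group, "left"
    return group, ("left" if d > 0 else "right")


def measure_side(landmarks: LandmarkSet, mesh: trimesh.Trimesh) -> SideMeasurements:
    """All six measurements of one hemimandible.

    The condylar base plane is built from Cd, F and Cd_neck; condylar and
    inferior ramal height are measured along the Cd-Go_mid line on either
    side of its intersection P with that plane.  Raises
    :class:`AnatomicalInconsistencyError` if P falls outside the Cd-Go_mid
    segment (the plane does not cut the ramal span).
    """
    cd, go_mid, me = landmarks["Cd"], landmarks["Go_mid"], landmarks["Me"]
    ramal_height = float(np.linalg.norm(cd - go_mid))
    body_length = float(np.linalg.norm(go_mid - me))

    plane = condylar_base_plane(cd, landmarks["F"], landmarks["Cd_neck"])
    u = _unit(go_mid - cd, "Cd-Go_mid line")
    # parametric intersection along the Cd->Go_mid direction
    denom = float(u @ plane.normal)
    if abs(denom) <= 1e-9:
        raise AnatomicalInconsistencyError("Cd-Go_mid line parallel to the condylar base plane")
    t = (plane.offset - float(cd @ plane.normal)) / denom
    if t < -1e-9 or t > ramal_height + 1e-9:
        raise AnatomicalInconsistencyError(
            f"condylar base plane cuts the Cd-Go_mid line outside the ramal span (t={t:.3f} mm)"
        )
    p = cd + t * u
    condylar_height = float(np.linalg.norm(cd - p))
    inferior_ramal_height = float(np.linalg.norm(p - go_mid))
    # the two heights partition the ramal span; remove the rounding residue
    inferior_ramal_height = ramal_height - condylar_height

    gonial_angle = angle_at_vertex(landmarks["Cd_post"], go_mid, me)
    volume = condylar_volume(mesh, cd, landmarks["F"], landmarks["Cd_neck"]).volume

    return SideMeasurements(
        body_length=body_length,
        ramal_height=ramal_height,
        condylar_height=condylar_height,
        inferior_ramal_height=inferior_ramal_height,
        condylar_volume=volume,
        gonial_angle=gonial_angle,
    )


def bilateral(subject: SubjectRecord) -> BilateralVector:
    """Bilateral contrasts: difference = nondeviated - deviated, ratio =
    deviated / nondeviated, per measurement."""
    nd = subject.nondeviated.as_dict()
    dv = subject.deviated.as_dict()
    diffs = {m: nd[m] - dv[m] for m in MEASUREMENTS}
    ratios = {m: dv[m] / nd[m] for m in MEASUREMENTS}
    return BilateralVector(differences=diffs, ratios=ratios)


def records_to_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    """Wide per-subject table: the pipeline's canonical intermediate.

    One row per subject with per-side measurements, bilateral differences
    and ratios, the signed menton deviation, deviated side and group.
    """
    rows = []
    for rec in records:
        row: dict = {
            "subject": rec.subject_id,
            "group": rec.group,
            "menton_deviation": rec.menton_deviation,
            "deviated_side": rec.deviated_side,
        }
        for side_name, side in (("left", rec.left), ("right", rec.right)):
            for m, v in side.as_dict().items():
                row[f"{side_name}_{m}"] = v
        bil = bilateral(rec)
        for m in MEASUREMENTS:
            row[f"diff_{m}"] = bil.differences[m]
            row[f"ratio_{m}"] = bil.ratios[m]
        rows.append(row)
    return pd.DataFrame(rows)
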