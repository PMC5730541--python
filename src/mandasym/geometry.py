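"""Pure 3D/2D geometric constructions for mandibular morphometry.

Coordinate frame (fixed for the whole package): right-handed, millimetres,
``+x`` = subject's anatomical left, ``+y`` = anterior, ``+z`` = superior.

The constructions mirror how a clinician works on a 3D mandible model:

* the **ramal axis** joins the most superior point of the condylar head (Cd)
  to the most inferior point of the mandibular foramen (F);
* the **condylar base plane** is perpendicular to that axis and passes
  through the most depressed point of the lateral condylar neck (Cd_neck);
  everything superior to it is the condyle;
* the **midline** of the frontal (posteroanterior) view passes through the
  crista galli (Cg), perpendicular to the line joining the left and right
  latero-orbitale points (Lo); the lateral distance of menton (Me) from it
  quantifies facial asymmetry.

The frontal projection is orthographic: 3D points are projected onto the
x-z plane by dropping y.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "GEOMETRIC_TOL",
    "LANDMARK_TOL",
    "MANDIBULAR_LANDMARKS",
    "GeometryError",
    "DegenerateGeometryError",
    "NoIntersectionError",
    "AmbiguousIntersectionError",
    "Line3",
    "Plane",
    "Midline2",
    "LandmarkSet",
    "ramal_axis",
    "condylar_base_plane",
    "intersect_line_plane",
    "angle_at_vertex",
    "pa_midline",
    "menton_deviation",
]

#: tolerance for geometric identities (mm)
GEOMETRIC_TOL = 1e-9
#: tolerance for landmark-set invariants (mm) — allows file round-trip noise
LANDMARK_TOL = 1e-6

#: the eight per-side mandibular landmarks
MANDIBULAR_LANDMARKS = (
    "Cd", "Cd_neck", "Cd_post", "Me", "F", "Go_inf", "Go_post", "Go_mid",
)


class GeometryError(ValueError):
    """Base class for geometric construction failures."""


class DegenerateGeometryError(GeometryError):
    """Coincident points or zero-length vectors where a direction is needed."""


class NoIntersectionError(GeometryError):
    """A line parallel to (and outside) a plane has no intersection."""


class AmbiguousIntersectionError(GeometryError):
    """A line lying inside a plane intersects it everywhere."""


def _as_point(p, name: str = "point") -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if a.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} has non-finite coordinates: {a}")
    return a


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n < GEOMETRIC_TOL:
        raise DegenerateGeometryError(f"{what}: zero-length direction")
    return v / n


@dataclass(frozen=True)
class Line3:
    """An oriented infinite line: ``origin + t * direction``, direction unit-norm."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", _as_point(self.origin, "origin"))
        d = _as_point(self.direction, "direction")
        if abs(np.linalg.norm(d) - 1.0) > GEOMETRIC_TOL:
            raise ValueError("Line3 direction must be unit-norm")
        object.__setattr__(self, "direction", d)

    def point_at(self, t: float) -> np.ndarray:
        return self.origin + t * self.direction


@dataclass(frozen=True)
class Plane:
    """Oriented infinite plane ``{p : normal . p = offset}`` with unit normal."""

    normal: np.ndarray
    offset: float

    def __post_init__(self) -> None:
        n = _as_point(self.normal, "normal")
        if abs(np.linalg.norm(n) - 1.0) > GEOMETRIC_TOL:
            raise ValueError("Plane normal must be unit-norm")
        object.__setattr__(self, "normal", n)
        object.__setattr__(self, "offset", float(self.offset))

    def signed_distance(self, points) -> np.ndarray | float:
        """Signed distance, positive on the side the normal points to."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.normal - self.offset

    def flipped(self) -> "Plane":
        return Plane(-self.normal, -self.offset)


@dataclass(frozen=True)
class Midline2:
    """A 2D line in the frontal (x, z) projection: point + t * direction."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.point, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        if p.shape != (2,) or d.shape != (2,):
            raise ValueError("Midline2 needs 2D point and direction")
        if abs(np.linalg.norm(d) - 1.0) > GEOMETRIC_TOL:
            raise ValueError("Midline2 direction must be unit-norm")
        object.__setattr__(self, "point", p)
        object.__setattr__(self, "direction", d)


@dataclass
class LandmarkSet:
    """The eight mandibular landmarks of one hemimandible.

    ``side`` is the anatomical side ("left" or "right"); ``points`` maps
    landmark names to 3D coordinates in mm.  Construction validates the
    anatomical invariants: Go_mid is the midpoint of Go_post and Go_inf,
    and Cd lies superior to F.
    """

    side: str
    points: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        pts = {k: _as_point(v, k) for k, v in dict(self.points).items()}
        missing = set(MANDIBULAR_LANDMARKS) - set(pts)
        if missing:
            raise ValueError(f"missing landmarks: {sorted(missing)}")
        mid = 0.5 * (pts["Go_post"] + pts["Go_inf"])
        if np.max(np.abs(mid - pts["Go_mid"])) > LANDMARK_TOL:
            raise ValueError("Go_mid is not the midpoint of Go_post and Go_inf")
        if not pts["Cd"][2] > pts["F"][2]:
            raise ValueError("Cd must lie superior (larger z) to F")
        self.points = pts

    def __getitem__(self, name: str) -> np.ndarray:
        return self.points[name]

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "LandmarkSet":
        """Apply ``p -> R p + t`` to every landmark."""
        R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
        t = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
        return LandmarkSet(self.side, {k: R @ v + t for k, v in self.points.items()})


def ramal_axis(cd, f) -> Line3:
    """Axis of the mandibular ramus, from F oriented superiorly toward Cd."""
    cd = _as_point(cd, "Cd")
    f = _as_point(f, "F")
    if np.linalg.norm(cd - f) < GEOMETRIC_TOL:
        raise DegenerateGeometryError("Cd and F coincide; ramal axis undefined")
    return Line3(f, _unit(cd - f, "ramal axis"))


def condylar_base_plane(cd, f, cd_neck) -> Plane:
    """Plane perpendicular to the Cd-F axis through Cd_neck.

    The normal points toward Cd (superiorly along the axis), so the condyle
    is the positive half-space.  Only the projection of Cd_neck onto the
    axis matters: displacing Cd_neck parallel to the plane leaves the plane
    unchanged.
    """
    axis = ramal_axis(cd, f)
    neck = _as_point(cd_neck, "Cd_neck")
    return Plane(axis.direction, float(axis.direction @ neck))


def intersect_line_plane(line: Line3, plane: Plane) -> np.ndarray:
    """The unique point on both the line and the plane.

    Raises :class:`NoIntersectionError` for a parallel line and
    :class:`AmbiguousIntersectionError` for a line lying in the plane.
    """
    denom = float(line.direction @ plane.normal)
    if abs(denom) <= GEOMETRIC_TOL:
        if abs(plane.signed_distance(line.origin)) <= GEOMETRIC_TOL:
            raise AmbiguousIntersectionError("line lies in the plane")
        raise NoIntersectionError("line is parallel to the plane")
    t = (plane.offset - float(line.origin @ plane.normal)) / denom
    return line.point_at(t)


def angle_at_vertex(a, v, b) -> float:
    """Angle in degrees at vertex ``v`` between the 3D vectors v->a and v->b.

    Always in [0, 180]; used for the gonial angle Cd_post-Go_mid-Me.
    """
    a = _as_point(a, "a")
    v = _as_point(v, "v")
    b = _as_point(b, "b")
    u1 = _unit(a - v, "first arm")
    u2 = _unit(b - v, "second arm")
    cosang = float(np.clip(u1 @ u2, -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))


def _project_frontal(p: np.ndarray) -> np.ndarray:
    """Orthographic posteroanterior projection: (x, y, z) -> (x, z)."""
    return np.array([p[0], p[2]], dtype=float)


def pa_midline(cg, lo_right, lo_left) -> Midline2:
    """Facial midline in the frontal projection.

    Passes through the projected crista galli, perpendicular to the
    projected Lo-Lo' interorbital segment.  The direction is normalised to
    point superiorly (positive z component; ties broken toward +x).
    """
    cg2 = _project_frontal(_as_point(cg, "Cg"))
    lr = _project_frontal(_as_point(lo_right, "Lo_right"))
    ll = _project_frontal(_as_point(lo_left, "Lo_left"))
    sep = ll - lr
    if np.linalg.norm(sep) < GEOMETRIC_TOL:
        raise DegenerateGeometryError("projected Lo points coincide")
    t = sep / np.linalg.norm(sep)
    d = np.array([-t[1], t[0]])  # perpendicular in 2D
    if d[1] < 0 or (d[1] == 0 and d[0] < 0):
        d = -d
    return Midline2(cg2, d)


def menton_deviation(me, midline: Midline2) -> float:
    """Signed perpendicular distance of the projected menton from the midline.

    Positive values mean deviation toward the subject's anatomical left
    (the +x half-plane); classification downstream uses the magnitude.
    """
    me2 = _project_frontal(_as_point(me, "Me"))
    d = midline.direction
    n = np.array([d[1], -d[0]])  # perpendicular of the (superior-pointing) direction
    if n[0] < 0 or (n[0] == 0 and n[1] < 0):
        n = -n
    return float(n @ (me2 - midline.point))
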