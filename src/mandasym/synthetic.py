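"""Synthetic mandible generator.

Builds per-subject landmark sets and condylar meshes that *exactly* realise
requested measurement vectors, and samples whole FA/NA cohorts whose
per-side measurement distributions follow published group means/SDs for
mandibular-prognathism patients.

The statistical model is deliberately simple.  Published data give only
per-side marginal means/SDs and the signs of the deviation-ratio
correlations, so the generator uses

* a shared per-measurement size factor coupling the two sides
  (``cross_side_corr``),
* a single **asymmetry coupling**: the deviated side's standardised score
  is depressed proportionally to the subject's standardised menton
  deviation, which induces negative correlations between |deviation| and
  every deviated/nondeviated ratio,
* a common within-side correlation between condylar and inferior ramal
  height (they partition the ramal span, whose SD the published tables
  report separately).

Geometry realisation is constructive: each hemimandible is built in a
canonical frame (ramus vertical, units mm), the right side is the mirror
image, and both sides are translated so they share the menton, which is
placed at the subject's signed deviation from the x = 0 facial midline.
The condyle is an axis-aligned ellipsoid solid whose lateral semi-axes are
calibrated so the mesh volume above the condylar base plane equals the
requested condylar volume exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import trimesh
from scipy import stats as sps

from .mesh_volume import clip_mesh_above_plane, mesh_volume
from .geometry import LandmarkSet, Plane, condylar_base_plane
from .morphometry import SideMeasurements, classify
from .reference import (
    DEVIATION_THRESHOLD_MM,
    GROUP_SIZE,
    MEASUREMENTS,
    MENTON_DEVIATION_STATS,
    SIDE_STATS,
)

__all__ = [
    "GeneratorParams",
    "SyntheticSubject",
    "InfeasibleMeasurementsError",
    "landmarks_from_measurements",
    "condyle_mesh_for_volume",
    "draw_cohort_measurements",
    "generate_cohort",
    "CRANIAL_LANDMARKS",
]

#: the five directly sampled measurements (ramal height = condylar +
#: inferior ramal height is derived)
_BASE = ("body_length", "condylar_height", "inferior_ramal_height",
         "condylar_volume", "gonial_angle")

#: fixed cranial landmarks defining the x = 0 facial midline (mm)
CRANIAL_LANDMARKS = {
    "Cg": np.array([0.0, 10.0, 80.0]),
    "Lo_right": np.array([-40.0, 0.0, 60.0]),
    "Lo_left": np.array([40.0, 0.0, 60.0]),
}

#: global menton position template; x is replaced by the signed deviation
_ME_ANCHOR = np.array([0.0, -80.0, -55.0])

#: retry cap when resampling infeasible measurement vectors
_MAX_RETRIES = 200


class InfeasibleMeasurementsError(ValueError):
    """Requested measurements cannot be realised as a hemimandible."""


@dataclass
class GeneratorParams:
    """Cohort-sampling parameters.

    ``side_stats`` maps (group, side) -> measurement -> (mean, SD); the
    defaults are the published reference cohort values.  ``deviation_stats``
    gives the |menton deviation| (mean, SD) per group.  ``asymmetry_coupling``
    is the standardised depression of the deviated side per SD of menton
    deviation; ``cross_side_corr`` the shared-size correlation between
    sides.  Sampling is deterministic under a fixed ``seed``.
    """

    side_stats: dict = field(default_factory=lambda: {k: dict(v) for k, v in SIDE_STATS.items()})
    deviation_stats: dict = field(default_factory=lambda: dict(MENTON_DEVIATION_STATS))
    n_fa: int = GROUP_SIZE
    n_na: int = GROUP_SIZE
    asymmetry_coupling: float = 0.65
    cross_side_corr: float = 0.5
    #: within-side correlation of condylar vs inferior ramal height per group
    height_corr: dict = field(default_factory=lambda: {"FA": 0.44, "NA": -0.17})
    threshold_mm: float = DEVIATION_THRESHOLD_MM
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fa < 0 or self.n_na < 0:
            raise ValueError("group sizes must be non-negative")
        lam = self.cross_side_corr
        a = self.asymmetry_coupling
        if lam < 0 or a < 0 or lam + a**2 > 1.0:
            raise ValueError("need cross_side_corr + asymmetry_coupling^2 <= 1")
        for key, stats in self.side_stats.items():
            for m, (mu, sd) in stats.items():
                if sd < 0:
                    raise ValueError(f"negative SD for {key}/{m}")


@dataclass
class SyntheticSubject:
    """One generated subject: landmark sets and condylar meshes for both
    sides, the shared cranial landmarks, and the ground-truth measurements
    the geometry realises."""

    subject_id: str
    group: str
    menton_deviation: float
    deviated_side: str
    landmarks: dict  # side -> LandmarkSet
    cranial: dict  # Cg / Lo_left / Lo_right -> (3,) array
    meshes: dict  # side -> trimesh.Trimesh
    truth: dict  # side -> SideMeasurements


# ---------------------------------------------------------------------------
# constructive geometry


def _canonical_left_landmarks(m: SideMeasurements, anchor: np.ndarray) -> dict:
    """Landmarks of a left hemimandible realising ``m``, Go_mid at ``anchor``.

    The ramus runs straight up (+z) from Go_mid; the Cd-F axis is tilted
    anteriorly by placing F off the ramal line, and Cd_neck is offset
    laterally within the base plane, so none of the downstream geometry is
    axis-aligned by accident.
    """
    rh, ch = m.ramal_height, m.condylar_height
    if ch >= rh:
        raise InfeasibleMeasurementsError(
            f"condylar height ({ch}) must be smaller than ramal height ({rh})"
        )
    u = np.array([0.0, 0.0, 1.0])  # ramal direction
    go_mid = np.asarray(anchor, dtype=float)
    cd = go_mid + rh * u
    f = go_mid + 0.35 * rh * u + np.array([0.0, 6.0, 0.0])  # anterior to the ramal line
    axis = cd - f
    axis = axis / np.linalg.norm(axis)
    p = cd - ch * u  # where the base plane must cut the Cd-Go_mid line
    # lateral (subject-left, +x) direction projected into the base plane
    lat = np.array([1.0, 0.0, 0.0])
    lat = lat - (lat @ axis) * axis
    lat = lat / np.linalg.norm(lat)
    cd_neck = p + 4.0 * lat

    cd_post = go_mid + 0.8 * rh * u + np.array([0.0, -4.0, 0.0])  # posterior border
    e1 = cd_post - go_mid
    e1 = e1 / np.linalg.norm(e1)
    # medial-anterior-inferior reference spanning the gonial-angle plane
    ref = np.array([-0.45, 1.0, -0.25])
    e2 = ref - (ref @ e1) * e1
    e2 = e2 / np.linalg.norm(e2)
    g = np.radians(m.gonial_angle)
    me = go_mid + m.body_length * (np.cos(g) * e1 + np.sin(g) * e2)

    w = np.array([0.0, -2.5, 2.5])  # Go_post posterior-superior of Go_mid
    return {
        "Cd": cd,
        "Cd_neck": cd_neck,
        "Cd_post": cd_post,
        "Me": me,
        "F": f,
        "Go_inf": go_mid - w,
        "Go_post": go_mid + w,
        "Go_mid": go_mid,
    }


_MIRROR = np.diag([-1.0, 1.0, 1.0])


def landmarks_from_measurements(
    m: SideMeasurements, side: str, anchor=None
) -> LandmarkSet:
    """Hemimandible landmark set realising the measurement vector ``m``.

    The left side is built in the canonical frame with Go_mid at ``anchor``
    (default (45, 0, 0) mm); the right side is its mirror image through the
    midsagittal plane.  Distances and the (unsigned) gonial angle are
    mirror-invariant, so ``measure_side`` recovers ``m`` on either side.
    """
    if anchor is None:
        anchor = np.array([45.0, 0.0, 0.0])
    pts = _canonical_left_landmarks(m, np.asarray(anchor, dtype=float))
    if side == "right":
        pts = {k: _MIRROR @ v for k, v in pts.items()}
    elif side != "left":
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    return LandmarkSet(side, pts)


def condyle_mesh_for_volume(
    v: float, plane: Plane, cd, sections: int = 24
) -> trimesh.Trimesh:
    """Watertight ellipsoid condyle with apex at Cd whose mesh volume above
    ``plane`` equals ``v`` exactly.

    The ellipsoid's polar axis is the plane normal (the ramal axis); its
    vertical semi-axis is 3/4 of Cd's height above the plane, so the solid
    dips below the plane like a condylar neck.  The lateral semi-axes are
    seeded from the analytic ellipsoidal-cap volume and then rescaled by
    the exact ratio of the requested to the discretised clipped volume —
    in-plane scaling leaves the plane and the clip combinatorics untouched
    and scales the clipped volume quadratically, making the calibration
    exact in one step.
    """
    if v <= 0:
        raise ValueError(f"condylar volume must be positive, got {v}")
    cd = np.asarray(cd, dtype=float)
    h = float(plane.signed_distance(cd))
    if h <= 0:
        raise ValueError("Cd must lie strictly above the condylar base plane")
    n = plane.normal
    c = 0.75 * h  # vertical semi-axis; centre sits h - c above the plane
    # analytic cap volume of the spheroid gives the starting lateral radius
    cap = np.pi * h**2 * (3 * c - h) / (3 * c**2)
    a0 = float(np.sqrt(v / cap))

    # orthonormal frame with n as the pole
    ref = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = ref - (ref @ n) * n
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)

    sphere = trimesh.creation.uv_sphere(radius=1.0, count=(sections, sections))
    sv = np.asarray(sphere.vertices)
    centre = cd - c * n
    verts = (
        centre
        + np.outer(sv[:, 0] * a0, e1)
        + np.outer(sv[:, 1] * a0, e2)
        + np.outer(sv[:, 2] * c, n)
    )
    mesh = trimesh.Trimesh(vertices=verts, faces=sphere.faces, process=False)

    v0 = mesh_volume(clip_mesh_above_plane(mesh, plane))
    s = float(np.sqrt(v / v0))
    # rescale the components perpendicular to the axis through the centre
    rel = np.asarray(mesh.vertices) - centre
    axial = np.outer(rel @ n, n)
    mesh = trimesh.Trimesh(
        vertices=centre + axial + s * (rel - axial), faces=sphere.faces, process=False
    )
    return mesh


def _realise_subject(
    subject_id: str,
    group: str,
    deviation: float,
    per_side: dict,
    mesh_sections: int = 24,
) -> SyntheticSubject:
    """Turn drawn measurement vectors into landmarks + meshes sharing Me."""
    _, dev_side = classify(deviation)
    sides = {"left", "right"}
    me_global = _ME_ANCHOR.copy()
    me_global[0] = deviation

    landmarks: dict = {}
    meshes: dict = {}
    truth: dict = {}
    for side in sorted(sides):
        m = per_side[side]
        lm = landmarks_from_measurements(m, side)
        shift = me_global - lm["Me"]
        lm = lm.transformed(translation=shift)
        plane = condylar_base_plane(lm["Cd"], lm["F"], lm["Cd_neck"])
        mesh = condyle_mesh_for_volume(
            m.condylar_volume, plane, lm["Cd"], sections=mesh_sections
        )
        landmarks[side] = lm
        meshes[side] = mesh
        truth[side] = m

    return SyntheticSubject(
        subject_id=subject_id,
        group=group,
        menton_deviation=deviation,
        deviated_side=dev_side,
        landmarks=landmarks,
        cranial={k: v.copy() for k, v in CRANIAL_LANDMARKS.items()},
        meshes=meshes,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# cohort sampling


@lru_cache(maxsize=None)
def _truncated_moments(mu: float, sd: float, lo: float, hi: float) -> tuple[float, float]:
    """Mean and SD of N(mu, sd) truncated to [lo, hi]."""
    a, b = (lo - mu) / sd, (hi - mu) / sd
    m, v = sps.truncnorm.stats(a, b, loc=mu, scale=sd, moments="mv")
    return float(m), float(np.sqrt(v))


def _draw_deviation(group: str, params: GeneratorParams, rng: np.random.Generator) -> tuple[float, float]:
    """(signed deviation mm, deviation score standardised within the group band).

    Standardising by the truncated distribution's own moments keeps the
    asymmetry coupling mean-zero / unit-variance, so the configured side
    means and SDs are the exact marginal expectations.
    """
    mu, sd = params.deviation_stats[group]
    thr = params.threshold_mm
    lo, hi = (thr, np.inf) if group == "FA" else (0.0, thr)
    for _ in range(_MAX_RETRIES):
        mag = rng.normal(mu, sd)
        if lo < mag < hi or (group == "FA" and mag == thr):
            sign = 1.0 if rng.random() < 0.5 else -1.0
            if sd > 0:
                m_t, s_t = _truncated_moments(mu, sd, lo, hi if np.isfinite(hi) else 1e9)
                return sign * mag, (mag - m_t) / s_t
            return sign * mag, 0.0
    raise RuntimeError(f"could not draw a {group} menton deviation within the group band")


def _pair_chol(rho: float) -> np.ndarray:
    return np.array([[1.0, 0.0], [rho, np.sqrt(1.0 - rho**2)]])


def _draw_scores(group: str, params: GeneratorParams, u: float, rng: np.random.Generator) -> dict:
    """Standardised per-side scores for the five base measurements."""
    lam = params.cross_side_corr
    a = params.asymmetry_coupling
    resid = np.sqrt(max(0.0, 1.0 - lam - a**2))
    t = params.height_corr[group]
    chol = _pair_chol(t)

    def correlated_draw() -> dict:
        g = {m: rng.standard_normal() for m in _BASE}
        pair = chol @ np.array([g["condylar_height"], g["inferior_ramal_height"]])
        g["condylar_height"], g["inferior_ramal_height"] = pair
        return g

    common = correlated_draw()
    e_nd = correlated_draw()
    e_dev = correlated_draw()
    scores: dict = {"nondeviated": {}, "deviated": {}}
    for m in _BASE:
        scores["nondeviated"][m] = np.sqrt(lam) * common[m] + np.sqrt(1.0 - lam) * e_nd[m]
        scores["deviated"][m] = np.sqrt(lam) * common[m] + resid * e_dev[m] - a * u
    return scores


def _measurements_from_scores(group: str, side_role: str, scores: dict, params: GeneratorParams) -> SideMeasurements | None:
    stats = params.side_stats[(group, side_role)]
    vals = {}
    for m in _BASE:
        mu, sd = stats[m]
        vals[m] = mu + sd * scores[m]
    vals["ramal_height"] = vals["condylar_height"] + vals["inferior_ramal_height"]
    if any(v <= 0 for v in vals.values()) or not (0 < vals["gonial_angle"] < 180):
        return None
    if vals["condylar_height"] >= vals["ramal_height"]:
        return None
    return SideMeasurements(**vals)


def draw_cohort_measurements(params: GeneratorParams, rng: np.random.Generator | None = None):
    """Sample the numeric stage of a cohort (no geometry realisation).

    Returns a list of dicts with subject id, group, signed deviation, and a
    SideMeasurements per anatomical side.  Infeasible draws (non-positive
    measurements) are rejected and redrawn, keeping distributions smooth.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    out = []
    for group, n in (("FA", params.n_fa), ("NA", params.n_na)):
        for i in range(n):
            for _ in range(_MAX_RETRIES):
                deviation, u = _draw_deviation(group, params, rng)
                scores = _draw_scores(group, params, u, rng)
                nd = _measurements_from_scores(group, "nondeviated", scores["nondeviated"], params)
                dv = _measurements_from_scores(group, "deviated", scores["deviated"], params)
                if nd is not None and dv is not None:
                    break
            else:
                raise RuntimeError("exceeded resampling retries for a feasible subject")
            _, dev_side = classify(deviation)
            per_side = {
                dev_side: dv,
                ("right" if dev_side == "left" else "left"): nd,
            }
            out.append(
                {
                    "subject_id": f"{group}{i + 1:03d}",
                    "group": group,
                    "menton_deviation": deviation,
                    "deviated_side": dev_side,
                    "per_side": per_side,
                }
            )
    return out


def generate_cohort(params: GeneratorParams, mesh_sections: int = 24) -> list[SyntheticSubject]:
    """Sample and geometrically realise a full FA/NA cohort.

    Deterministic under a fixed ``params.seed``; every FA subject has
    |menton deviation| >= the 4-mm threshold by construction and every NA
    subject falls below it.
    """
    rng = np.random.default_rng(params.seed)
    drawn = draw_cohort_measurements(params, rng)
    return [
        _realise_subject(
            d["subject_id"], d["group"], d["menton_deviation"], d["per_side"],
            mesh_sections=mesh_sections,
        )
        for d in drawn
    ]
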