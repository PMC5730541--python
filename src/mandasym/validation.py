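"""Reference-consistency utilities.

Builds a deterministic fixture cohort whose per-side measurements equal
the published group means exactly, realised through the full geometric
pipeline (landmarks + condylar meshes, then measured back).  Feeding it to
the table builder must reproduce the published bilateral-difference means
by linearity of the mean — the package's primary cross-table consistency
check.

One subtlety: the published ramal-height means are printed to 0.1 mm and
are rounding-inconsistent with their own partition (condylar + inferior
ramal height); the geometry enforces the partition exactly, so the fixture
takes the two partial heights as exact and derives ramal height from them
(58.7 instead of the printed 58.6 for the FA deviated side, 62.2 instead
of 62.1 for the NA nondeviated side).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .geometry import condylar_base_plane
from .io import SubjectLandmarks
from .morphometry import SideMeasurements, SubjectRecord, classify, measure_side
from .reference import MEASUREMENTS, MENTON_DEVIATION_STATS, SIDE_STATS
from .synthetic import (
    GeneratorParams,
    condyle_mesh_for_volume,
    draw_cohort_measurements,
    landmarks_from_measurements,
)

__all__ = [
    "reference_mean_measurements",
    "reference_mean_cohort",
    "measure_generated_cohort",
    "sign_recovery_rate",
]


def reference_mean_measurements(group: str, role: str) -> SideMeasurements:
    """Published mean measurement vector of one group-side, with ramal
    height derived from its partition."""
    stats = SIDE_STATS[(group, role)]
    ch = stats["condylar_height"][0]
    irh = stats["inferior_ramal_height"][0]
    return SideMeasurements(
        body_length=stats["body_length"][0],
        ramal_height=ch + irh,
        condylar_height=ch,
        inferior_ramal_height=irh,
        condylar_volume=stats["condylar_volume"][0],
        gonial_angle=stats["gonial_angle"][0],
    )


def reference_mean_cohort(n_per_group: int = 14) -> list[SubjectRecord]:
    """Fixture cohort: every subject of a group carries exactly the group's
    published side means, realised geometrically and measured back.

    Each subject deviates toward the left by the group's mean |menton
    deviation| (8.9 mm FA, 1.6 mm NA), so left = deviated side.
    """
    records = []
    for group in ("FA", "NA"):
        deviation = MENTON_DEVIATION_STATS[group][0]
        per_side = {
            "left": reference_mean_measurements(group, "deviated"),
            "right": reference_mean_measurements(group, "nondeviated"),
        }
        measured = {}
        for side, m in per_side.items():
            lm = landmarks_from_measurements(m, side)
            plane = condylar_base_plane(lm["Cd"], lm["F"], lm["Cd_neck"])
            mesh = condyle_mesh_for_volume(m.condylar_volume, plane, lm["Cd"])
            measured[side] = measure_side(lm, mesh)
        grp, dev_side = classify(deviation)
        assert grp == group and dev_side == "left"
        for i in range(n_per_group):
            records.append(
                SubjectRecord(
                    subject_id=f"{group}-mean-{i + 1:02d}",
                    left=measured["left"],
                    right=measured["right"],
                    menton_deviation=deviation,
                    deviated_side="left",
                    group=group,
                )
            )
    return records


def measure_generated_cohort(subjects) -> pd.DataFrame:
    """Run the measurement pipeline over generated subjects and return the
    canonical per-subject frame."""
    from .morphometry import records_to_frame
    from .pipeline import measure_subject

    records = []
    for s in subjects:
        lms = SubjectLandmarks(
            s.subject_id, s.landmarks["left"], s.landmarks["right"], s.cranial
        )
        records.append(measure_subject(lms, s.meshes))
    return records_to_frame(records)


def sign_recovery_rate(replicates: int, seed: int, n: int = 14) -> float:
    """Fraction of size-n FA cohorts in which the Spearman correlation of
    |menton deviation| with every deviated/nondeviated ratio is negative.

    Uses the generator's numeric stage (measurement vectors only), which
    the geometric realisation reproduces exactly up to mesh tolerance.
    """
    rng = np.random.default_rng(seed)
    params = GeneratorParams(n_fa=n, n_na=0)
    hits = 0
    for _ in range(replicates):
        drawn = draw_cohort_measurements(params, rng)
        dev = np.array([abs(d["menton_deviation"]) for d in drawn])
        all_neg = True
        for m in MEASUREMENTS:
            ratios = np.array(
                [
                    getattr(d["per_side"][d["deviated_side"]], m)
                    / getattr(
                        d["per_side"][
                            "right" if d["deviated_side"] == "left" else "left"
                        ],
                        m,
                    )
                    for d in drawn
                ]
            )
            if sps.spearmanr(dev, ratios).statistic >= 0:
                all_neg = False
                break
        hits += all_neg
    return hits / replicates
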