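"""Published reference statistics for mandibular-prognathism cohorts.

Group summary statistics (mean, SD) from a surgical cohort of 28 Japanese
mandibular-prognathism patients, 14 with facial asymmetry (FA: menton
deviation >= 4 mm from the facial midline) and 14 without (NA: < 4 mm).
Each side of each subject carries six measurements; "deviated" is the side
the menton deviates toward, "nondeviated" its contralateral side.

These numbers are the default parameters of the synthetic cohort generator
and the fixture for the cross-table consistency checks.
"""

from __future__ import annotations

#: the six per-side measurements, in canonical order
MEASUREMENTS = (
    "body_length",
    "ramal_height",
    "condylar_height",
    "inferior_ramal_height",
    "condylar_volume",
    "gonial_angle",
)

#: units per measurement (mm, mm^3 or degrees)
UNITS = {
    "body_length": "mm",
    "ramal_height": "mm",
    "condylar_height": "mm",
    "inferior_ramal_height": "mm",
    "condylar_volume": "mm^3",
    "gonial_angle": "deg",
}

#: per-group, per-side (mean, SD) of the six measurements
SIDE_STATS = {
    ("FA", "deviated"): {
        "body_length": (89.1, 5.4),
        "ramal_height": (58.6, 8.4),
        "condylar_height": (13.9, 2.7),
        "inferior_ramal_height": (44.8, 6.4),
        "condylar_volume": (1413.1, 614.1),
        "gonial_angle": (125.2, 5.4),
    },
    ("FA", "nondeviated"): {
        "body_length": (94.0, 4.2),
        "ramal_height": (63.0, 6.0),
        "condylar_height": (16.2, 2.2),
        "inferior_ramal_height": (46.8, 5.1),
        "condylar_volume": (1943.2, 708.2),
        "gonial_angle": (127.1, 5.4),
    },
    ("NA", "deviated"): {
        "body_length": (87.7, 5.6),
        "ramal_height": (61.9, 5.0),
        "condylar_height": (15.5, 2.3),
        "inferior_ramal_height": (46.4, 4.7),
        "condylar_volume": (1693.5, 443.1),
        "gonial_angle": (131.0, 13.7),
    },
    ("NA", "nondeviated"): {
        "body_length": (88.6, 6.5),
        "ramal_height": (62.1, 4.7),
        "condylar_height": (15.1, 1.5),
        "inferior_ramal_height": (47.1, 4.8),
        "condylar_volume": (1629.7, 403.0),
        "gonial_angle": (130.5, 13.2),
    },
}

#: published group (mean, SD) of bilateral differences (nondeviated - deviated)
DIFFERENCE_STATS = {
    "FA": {
        "body_length": (4.9, 2.7),
        "ramal_height": (4.3, 5.5),
        "condylar_height": (2.3, 1.6),
        "inferior_ramal_height": (2.0, 4.3),
        "condylar_volume": (530.2, 261.8),
        "gonial_angle": (1.9, 1.7),
    },
    "NA": {
        "body_length": (0.9, 2.8),
        "ramal_height": (0.2, 3.8),
        "condylar_height": (-0.4, 2.0),
        "inferior_ramal_height": (0.7, 3.9),
        "condylar_volume": (-63.5, 193.7),
        "gonial_angle": (-0.5, 6.7),
    },
}

#: published (mean, SD) of |menton deviation| in mm per group
MENTON_DEVIATION_STATS = {"FA": (8.9, 4.3), "NA": (1.6, 0.8)}

#: menton-deviation threshold (mm) separating the FA and NA groups
DEVIATION_THRESHOLD_MM = 4.0

#: group size per arm of the reference cohort
GROUP_SIZE = 14

#: published Spearman correlations of |menton deviation| with the
#: deviated/nondeviated ratios in the FA group (all negative)
DEVIATION_RATIO_CORRELATIONS = {
    "body_length": -0.545,
    "ramal_height": -0.627,
    "condylar_height": -0.600,
    "inferior_ramal_height": -0.629,
    "condylar_volume": -0.660,
    "gonial_angle": -0.501,
}
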