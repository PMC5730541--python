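"""Measure every subject of the generated cohort.

Reads results/cohort/ (landmark JSON + STL meshes), measures the six
per-side quantities, the menton deviation and the FA/NA classification of
each subject, and writes the canonical per-subject wide table to
results/subjects.csv.
"""

from pathlib import Path

from mandasym.morphometry import records_to_frame
from mandasym.pipeline import load_cohort_files, measure_subject

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    records = [
        measure_subject(lms, meshes) for lms, meshes in load_cohort_files(ROOT / "cohort")
    ]
    frame = records_to_frame(records)
    out = ROOT / "subjects.csv"
    frame.to_csv(out, index=False)
    print(f"measured {len(frame)} subjects -> {out}")
    by_group = frame.groupby("group")["diff_condylar_volume"].mean().round(1)
    print("mean condylar-volume difference (nondeviated - deviated side):")
    print(by_group.to_string())


if __name__ == "__main__":
    main()
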