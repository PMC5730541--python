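"""Pipeline orchestration: generate → measure → analyse → report.

A run either samples a synthetic cohort or reads landmark + mesh files
from disk, measures every subject, writes the canonical per-subject wide
CSV, builds the four asymmetry tables (CSV + JSON) and records a manifest
(config, seed, package versions) sufficient to reproduce the run exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .asym_stats import ResultTables, build_tables, dahlberg_error
from .geometry import menton_deviation, pa_midline
from .io import SubjectLandmarks, load_mesh, save_mesh, write_landmarks_json
from .morphometry import SubjectRecord, classify, measure_side, records_to_frame
from .reference import DEVIATION_THRESHOLD_MM, MEASUREMENTS
from .synthetic import GeneratorParams, SyntheticSubject, generate_cohort

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "measure_subject",
           "reliability_report", "write_cohort_files", "load_cohort_files",
           "read_subjects_csv"]


def read_subjects_csv(path) -> pd.DataFrame:
    """Read the canonical per-subject CSV.

    The group label "NA" (no asymmetry) must not be parsed as missing, so
    default NA detection is disabled; empty cells still become NaN.
    """
    return pd.read_csv(path, keep_default_na=False, na_values=[""])

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    output_dir: str = "results/run"
    seed: int = 0
    #: sample a synthetic cohort when True, else read from input_dir
    generate: bool = True
    n_fa: int = 14
    n_na: int = 14
    input_dir: str | None = None
    threshold_mm: float = DEVIATION_THRESHOLD_MM
    side_comparison_mode: str = "matched"  # or "pooled"
    write_geometry: bool = False  # also write landmark JSON + STL per subject

    def __post_init__(self) -> None:
        if self.threshold_mm <= 0:
            raise ValueError("threshold_mm must be positive")


@dataclass
class PipelineResult:
    cohort: pd.DataFrame
    tables: ResultTables
    skipped: list = field(default_factory=list)


def measure_subject(
    landmarks: SubjectLandmarks, meshes: dict, threshold_mm: float = DEVIATION_THRESHOLD_MM
) -> SubjectRecord:
    """Measure both sides of one subject and classify it.

    ``meshes`` maps side -> hemimandible (or condylar) mesh.  The menton
    deviation is measured from the PA midline built from the cranial
    landmarks.
    """
    midline = pa_midline(
        landmarks.cranial["Cg"], landmarks.cranial["Lo_right"], landmarks.cranial["Lo_left"]
    )
    deviation = menton_deviation(landmarks.left["Me"], midline)
    group, dev_side = classify(deviation, threshold_mm)
    return SubjectRecord(
        subject_id=landmarks.subject_id,
        left=measure_side(landmarks.left, meshes["left"]),
        right=measure_side(landmarks.right, meshes["right"]),
        menton_deviation=deviation,
        deviated_side=dev_side,
        group=group,
    )


def write_cohort_files(subjects: list[SyntheticSubject], out_dir) -> None:
    """Write per-subject landmark JSON and per-side condylar STL meshes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in subjects:
        write_landmarks_json(
            SubjectLandmarks(s.subject_id, s.landmarks["left"], s.landmarks["right"], s.cranial),
            out / f"{s.subject_id}_landmarks.json",
        )
        for side, mesh in s.meshes.items():
            save_mesh(mesh, out / f"{s.subject_id}_{side}_condyle.stl")


def load_cohort_files(in_dir) -> list[tuple[SubjectLandmarks, dict]]:
    """Read every ``*_landmarks.json`` with its two side meshes."""
    in_path = Path(in_dir)
    out = []
    for lm_file in sorted(in_path.glob("*_landmarks.json")):
        from .io import read_landmarks_json

        lms = read_landmarks_json(lm_file)
        meshes = {}
        for side in ("left", "right"):
            mesh_file = in_path / f"{lms.subject_id}_{side}_condyle.stl"
            if not mesh_file.exists():
                raise FileNotFoundError(mesh_file)
            meshes[side] = load_mesh(mesh_file)
        out.append((lms, meshes))
    return out


def _write_tables(tables: ResultTables, out: Path) -> None:
    tables.differences.to_csv(out / "bilateral_differences.csv", index=False)
    tables.sides.to_csv(out / "side_summaries.csv", index=False)
    tables.side_comparisons.to_csv(out / "fa_vs_na_sides.csv", index=False)
    tables.correlation_rho.to_csv(out / "fa_ratio_correlations_rho.csv")
    tables.correlation_p.to_csv(out / "fa_ratio_correlations_p.csv")
    (out / "tables.json").write_text(json.dumps(tables.as_dict(), indent=1, default=float) + "\n")


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute a full run and write the result bundle to ``output_dir``."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    records: list[SubjectRecord] = []
    skipped: list = []
    if config.generate:
        params = GeneratorParams(
            n_fa=config.n_fa, n_na=config.n_na,
            threshold_mm=config.threshold_mm, seed=config.seed,
        )
        subjects = generate_cohort(params)
        if config.write_geometry:
            write_cohort_files(subjects, out / "cohort")
        for s in subjects:
            lms = SubjectLandmarks(
                s.subject_id, s.landmarks["left"], s.landmarks["right"], s.cranial
            )
            records.append(measure_subject(lms, s.meshes, config.threshold_mm))
    else:
        if config.input_dir is None:
            raise ValueError("input_dir required when generate=False")
        for lms, meshes in load_cohort_files(config.input_dir):
            try:
                records.append(measure_subject(lms, meshes, config.threshold_mm))
            except (ValueError, FileNotFoundError) as exc:
                log.warning("skipping subject %s: %s", lms.subject_id, exc)
                skipped.append((lms.subject_id, str(exc)))
        if not records:
            raise RuntimeError("no subject could be measured")

    cohort = records_to_frame(records)
    cohort.to_csv(out / "subjects.csv", index=False)
    tables = build_tables(cohort, side_comparison_mode=config.side_comparison_mode)
    _write_tables(tables, out)

    manifest = {
        "config": dataclasses.asdict(config),
        "package": {"name": "mandasym", "version": __version__},
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
        "n_subjects": len(records),
        "n_skipped": len(skipped),
    }
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    return PipelineResult(cohort=cohort, tables=tables, skipped=skipped)


def reliability_report(repeats: pd.DataFrame) -> pd.DataFrame:
    """Dahlberg duplicate-measurement error per rater and measurement.

    ``repeats`` needs columns ``rater, subject, replicate, <measurement>``
    with replicate values 1 and 2; one Se row is emitted per rater and
    measurement, plus an inter-rater row comparing the rater-mean series.
    """
    meas = [c for c in repeats.columns if c in MEASUREMENTS]
    if not meas:
        raise ValueError("no measurement columns found")
    rows = []
    for rater, g in repeats.groupby("rater"):
        wide = g.pivot(index="subject", columns="replicate", values=meas)
        for m in meas:
            rows.append(
                {
                    "rater": str(rater),
                    "measurement": m,
                    "se": dahlberg_error(wide[(m, 1)].to_numpy(), wide[(m, 2)].to_numpy()),
                    "n": len(wide),
                }
            )
    raters = sorted(repeats["rater"].unique())
    if len(raters) >= 2:
        means = repeats.groupby(["rater", "subject"])[meas].mean()
        for i in range(len(raters)):
            for j in range(i + 1, len(raters)):
                a, b = means.loc[raters[i]], means.loc[raters[j]]
                common = a.index.intersection(b.index)
                for m in meas:
                    rows.append(
                        {
                            "rater": f"{raters[i]} vs {raters[j]}",
                            "measurement": m,
                            "se": dahlberg_error(
                                a.loc[common, m].to_numpy(), b.loc[common, m].to_numpy()
                            ),
                            "n": len(common),
                        }
                    )
    return pd.DataFrame(rows)
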