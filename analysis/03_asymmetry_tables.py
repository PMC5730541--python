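"""Build the four bilateral-asymmetry tables for the measured cohort.

From results/subjects.csv: (1) FA-vs-NA comparison of bilateral
differences (Mann-Whitney), (2) per-group side summaries with
deviated-vs-nondeviated Wilcoxon tests, (3) FA sides vs NA sides
(Mann-Whitney, matched sides), (4) the Spearman matrix of |menton
deviation| and the six deviated/nondeviated ratios within the FA group.
Writes CSVs + tables.json under results/tables/.
"""

from pathlib import Path

from mandasym.asym_stats import build_tables
from mandasym.pipeline import _write_tables, read_subjects_csv

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = read_subjects_csv(ROOT / "subjects.csv")
    tables = build_tables(cohort)
    out = ROOT / "tables"
    out.mkdir(parents=True, exist_ok=True)
    _write_tables(tables, out)
    print(f"tables -> {out}\n")
    print("bilateral differences (FA vs NA):")
    print(
        tables.differences[["measurement", "FA_mean", "NA_mean", "p_value", "significance"]]
        .round(3)
        .to_string(index=False)
    )
    print("\nFA-group correlations of |menton deviation| with the side ratios:")
    print(tables.correlation_rho["menton_deviation"].drop("menton_deviation").round(3).to_string())


if __name__ == "__main__":
    main()
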