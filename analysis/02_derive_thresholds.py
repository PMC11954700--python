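"""Phase 1: distribution summaries, normality, threshold derivation.

Reads the simulated derivation cohort, summarizes the mediolateral laxity
sums and differences in extension and flexion, assesses their normality
(Lilliefors-KS + Shapiro-Wilk), derives the SD-based category limits from
the normally distributed differences, and tabulates the initial phenotype
distribution. Run 01_simulate_cohorts.py first.
"""

import csv
from pathlib import Path

from real_laxity import run_phase1
from real_laxity.io import read_cohort, write_report

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = read_cohort(RESULTS / "cohort_phase1.csv")
    report = run_phase1(cohort)

    with (RESULTS / "phase1_summaries.csv").open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["channel", "n", "mean_mm", "sd_mm", "outliers",
                         "ks_stat", "ks_p", "sw_stat", "sw_p", "normal"])
        for key, s in report.summaries.items():
            nr = report.normality[key]
            writer.writerow([key, s.n, f"{s.mean:.3f}", f"{s.sd:.3f}", s.outlier_count,
                             f"{nr.ks_statistic:.3f}", f"{nr.ks_p:.3f}",
                             f"{nr.sw_statistic:.3f}", f"{nr.sw_p:.3f}", nr.is_normal])
    write_report(report, RESULTS / "phase1_report.json", fmt="json")
    write_report(report, RESULTS / "phase1_distribution.csv", fmt="csv")

    print("per-channel summaries (mm):")
    for key, s in report.summaries.items():
        verdict = "normal" if report.normality[key].is_normal else "NOT normal"
        print(f"  {key:<21} mean {s.mean:6.2f}  sd {s.sd:5.2f}  "
              f"outliers {s.outlier_count}  ({verdict})")
    print(f"scheme derived from {', '.join(report.derived_from)}: "
          f"limits {report.scheme.limit1_mm:.1f} / {report.scheme.limit2_mm:.1f} mm")
    top = max(report.distribution.percentages.items(), key=lambda kv: kv[1])
    print(f"most common initial phenotype: {top[0]} ({top[1]:.1f}%)")


if __name__ == "__main__":
    main()
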