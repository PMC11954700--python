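"""Phase 2: validation under the frozen 2.5/5.0 mm scheme.

Classifies the simulated validation cohort at the start and end of surgery,
tabulates both distributions and the 9x9 transition table, and reports the
percentage of knees ending inside the balanced area (1A balanced; 1B, 2A
almost balanced). Run 01_simulate_cohorts.py first.
"""

import csv
from pathlib import Path

from real_laxity import ThresholdScheme, run_phase2
from real_laxity.core import PHENOTYPE_LABELS
from real_laxity.io import read_cohort, write_report

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = read_cohort(RESULTS / "cohort_phase2.csv")
    report = run_phase2(cohort, scheme=ThresholdScheme(2.5, 5.0))

    write_report(report, RESULTS / "phase2_report.json", fmt="json")
    write_report(report, RESULTS / "phase2_distributions.csv", fmt="csv")
    with (RESULTS / "phase2_transitions.csv").open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["initial\\final", *PHENOTYPE_LABELS])
        for ini in PHENOTYPE_LABELS:
            row = report.transitions.counts[ini]
            writer.writerow([ini, *(row[fin] or "-" for fin in PHENOTYPE_LABELS)])

    print(f"validation cohort: {len(cohort)} knees, frozen limits "
          f"{report.scheme.limit1_mm:.1f}/{report.scheme.limit2_mm:.1f} mm")
    for name, dist in (("initial", report.initial_distribution),
                       ("final", report.final_distribution)):
        nonzero = {k: v for k, v in dist.counts.items() if v}
        print(f"  {name:<7} distribution: {nonzero}")
    moved = len(cohort) - sum(
        report.transitions.counts[l][l] for l in PHENOTYPE_LABELS
    )
    print(f"  {moved} knees changed phenotype during surgery")
    print(f"  balanced area (1A+1B+2A) at end of surgery: "
          f"{report.balanced_percentage:.1f}%")


if __name__ == "__main__":
    main()
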