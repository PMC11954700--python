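"""Generate the synthetic derivation and validation cohorts.

Writes a 120-knee phase-1 cohort (initial laxities only) and a 102-knee
phase-2 cohort (initial and end-of-surgery laxities) to results/, using the
study's published distributional parameters.
"""

from pathlib import Path

from real_laxity.io import write_cohort
from real_laxity.synthetic import default_phase1_params, default_phase2_params, generate_cohort

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 20240122


def main() -> None:
    RESULTS.mkdir(exist_ok=True)

    phase1 = generate_cohort(default_phase1_params(seed=SEED))
    p1_path = write_cohort(phase1, RESULTS / "cohort_phase1.csv")
    print(f"phase 1: wrote {len(phase1)} knees (initial laxities) to {p1_path}")

    phase2 = generate_cohort(default_phase2_params(seed=SEED + 1), timepoints="both")
    p2_path = write_cohort(phase2, RESULTS / "cohort_phase2.csv")
    print(f"phase 2: wrote {len(phase2)} knees (initial + final laxities) to {p2_path}")


if __name__ == "__main__":
    main()
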