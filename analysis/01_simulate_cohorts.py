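"""Simulate the synthetic co-clinical cohorts.

Generates (i) 40 preclinical test-retest pairs, (ii) a 29-subject
baseline/on-treatment therapy cohort with latent response labels, and
(iii) a 20-subject clinical-style binary cohort. Images and masks are
written as NIfTI under scratch/cohorts/ (large, regenerable); manifests,
labels, and caliper tables go under results/.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from radsig.io import write_cohort
from radsig.phantoms import (
    PhantomConfig,
    generate_longitudinal_cohort,
    generate_test_retest_pair,
)

SEED = 1
SCRATCH = ROOT / "scratch" / "cohorts"
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)

    retest_cfg = PhantomConfig(n_subjects=40, seed=SEED)
    pairs = [generate_test_retest_pair(retest_cfg, f"tr{i:03d}") for i in range(40)]
    day1 = [p[0] for p in pairs]
    day2 = [p[1] for p in pairs]
    write_cohort(day1, SCRATCH / "retest_day1")
    write_cohort(day2, SCRATCH / "retest_day2")
    print(f"test-retest: {len(pairs)} pairs at jitter {retest_cfg.retest_jitter}")

    therapy_cfg = PhantomConfig(n_subjects=29, seed=SEED)
    therapy = generate_longitudinal_cohort(therapy_cfg)
    write_cohort(therapy.scans, SCRATCH / "therapy", therapy.labels)
    therapy.labels.rename_axis("subject_id").to_csv(RESULTS / "therapy_labels.csv")
    therapy.caliper.to_csv(RESULTS / "therapy_caliper.csv")
    print("therapy cohort:", therapy.labels.value_counts().to_dict())

    clinical_cfg = PhantomConfig(n_subjects=20, seed=SEED, arm="clinical")
    clinical = generate_longitudinal_cohort(clinical_cfg, binary=True)
    write_cohort(clinical.scans, SCRATCH / "clinical", clinical.labels)
    clinical.labels.rename_axis("subject_id").to_csv(
        RESULTS / "clinical_labels.csv"
    )
    print("clinical cohort:", clinical.labels.value_counts().to_dict())


if __name__ == "__main__":
    main()
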