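"""Extract the 131-feature panel for every simulated cohort.

One identical pipeline for both arms: first-order features on the raw SUV
grid, texture families on the resampled Ng=64 equal-probability quantized
grid.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from radsig.features import default_manifest, extract_table
from radsig.io import read_cohort

RESULTS = ROOT / "results"
COHORTS = ROOT / "scratch" / "cohorts"


def main() -> None:
    manifest = default_manifest()
    manifest.to_json(RESULTS / "feature_manifest.json")
    for name in ("retest_day1", "retest_day2", "therapy", "clinical"):
        scans, _ = read_cohort(COHORTS / name / "manifest.csv")
        table = extract_table(scans, manifest)
        table.to_csv(RESULTS / f"features_{name}.csv")
        print(f"{name}: {table.shape[0]} scans x {table.shape[1]} features")


if __name__ == "__main__":
    main()
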