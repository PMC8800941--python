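"""Rank robust features by ReliefF and assemble the RadSig signatures.

Prediction uses baseline features; assessment uses on-treatment minus
baseline differences. Features above the relevance threshold tau = 0.05
form the shortlist; the top 4 make up RadSig per task.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

import json

import pandas as pd

from radsig.relieff import RelieffConfig, delta_table, select_radsig

RESULTS = ROOT / "results"
SEED = 1


def main() -> None:
    therapy = pd.read_csv(RESULTS / "features_therapy.csv", index_col=[0, 1])
    labels = pd.read_csv(RESULTS / "therapy_labels.csv", index_col=0)["label"]
    robust = list(
        pd.read_csv(RESULTS / "robustness_report.csv", index_col=0)
        .query("robust")
        .index
    )
    bl = therapy.xs("BL", level="timepoint")[robust]
    ontx = therapy.xs("ONTX", level="timepoint")[robust]
    cfg = RelieffConfig(seed=SEED)

    out = {}
    for task, table in (
        ("prediction", bl),
        ("assessment", delta_table(bl, ontx)),
    ):
        sig = select_radsig(table, labels, task, cfg)
        sig.weights.sort_values(ascending=False).to_csv(
            RESULTS / f"relieff_weights_{task}.csv"
        )
        out[task] = {f: round(sig.weights[f], 4) for f in sig.features}
        print(f"{task} RadSig: {', '.join(sig.features)}")
    (RESULTS / "radsig.json").write_text(json.dumps(out, indent=1))


if __name__ == "__main__":
    main()
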