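"""Evaluate CART / SVM-RBF / Gaussian NB on RadSig vs SUV comparators.

Stratified 10-fold cross-validation with fold-internal standardization;
out-of-fold predictions pooled into one confusion matrix per model/task.
Also traces pooled accuracy against the number of ranked features.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

import json
import warnings

import pandas as pd

from radsig.models import (
    MODEL_KINDS,
    ModelSpec,
    accuracy_vs_feature_count,
    evaluate_predictors,
    saturation_point,
)
from radsig.relieff import delta_table

RESULTS = ROOT / "results"
SEED = 1


def main() -> None:
    warnings.filterwarnings("ignore")
    therapy = pd.read_csv(RESULTS / "features_therapy.csv", index_col=[0, 1])
    labels = pd.read_csv(RESULTS / "therapy_labels.csv", index_col=0)["label"]
    radsig = json.loads((RESULTS / "radsig.json").read_text())
    bl = therapy.xs("BL", level="timepoint")
    delta = delta_table(bl, therapy.xs("ONTX", level="timepoint"))

    frames = []
    for task, table in (("prediction", bl), ("assessment", delta)):
        sig_feats = list(radsig[task])
        for kind in MODEL_KINDS:
            comp = evaluate_predictors(
                {
                    "radsig": table[sig_feats],
                    "suv_mean": table[["suv_mean"]],
                    "suv_max": table[["suv_max"]],
                    "sul_peak": table[["sul_peak"]],
                },
                labels, ModelSpec(kind=kind, seed=SEED), folds=10, seed=SEED,
                task=task,
            )
            comp.insert(0, "model", kind)
            comp.insert(1, "task", task)
            frames.append(comp.reset_index())
    perf = pd.concat(frames, ignore_index=True)
    perf.to_csv(RESULTS / "performance.csv", index=False)

    nb = perf.query("model == 'gaussian_nb' and predictor == 'radsig'")
    for _, row in nb.iterrows():
        print(
            f"NB-RadSig {row['task']}: accuracy {row['accuracy']:.1f}%, "
            f"F {row['f_score']:.1f}%"
        )

    weights = pd.read_csv(
        RESULTS / "relieff_weights_prediction.csv", index_col=0
    ).iloc[:, 0]
    ranked = list(weights.index[:10])
    curve = accuracy_vs_feature_count(
        bl, labels, ranked, folds=10, seed=SEED
    )
    curve.to_csv(RESULTS / "accuracy_vs_features.csv")
    sats = {m: saturation_point(curve[m]) for m in curve.columns}
    print("accuracy saturates at:", sats)


if __name__ == "__main__":
    main()
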