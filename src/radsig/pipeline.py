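"""End-to-end orchestration: simulate -> metrics -> extract -> screen ->
select -> train -> cohort-stats.

Every stage is a pure function of (inputs, config, seed); a run directory
collects the artifacts, each stamped with the config hash.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as clinical
from .features import default_manifest, extract_table
from .models import (
    MODEL_KINDS,
    ModelSpec,
    accuracy_vs_feature_count,
    cross_validate,
    evaluate_predictors,
    saturation_point,
)
from .pet_metrics import suv_summary
from .phantoms import (
    PhantomConfig,
    generate_longitudinal_cohort,
    generate_test_retest_pair,
)
from .relieff import RelieffConfig, delta_table, select_radsig
from .robustness import run_robustness_screen


@dataclass
class PipelineConfig:
    """Thresholds and study sizes of one reproducible run."""

    seed: int = 0
    arm: str = "preclinical"
    n_retest_pairs: int = 40
    n_therapy_subjects: int = 29
    lcc_threshold: float = 0.7
    rho_threshold: float = 0.9
    p_threshold: float = 0.001
    tau: float = 0.05
    radsig_size: int = 4
    folds: int = 10
    response_cutoff_pct: float = 20.0
    phantom: dict = field(default_factory=dict)  # PhantomConfig overrides

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def phantom_config(self, **overrides) -> PhantomConfig:
        kwargs = {"arm": self.arm, "seed": self.seed}
        kwargs.update(self.phantom)
        kwargs.update(overrides)
        return PhantomConfig(**kwargs)


def run_pipeline(config: PipelineConfig, out_dir: Path | str) -> dict:
    """Execute every stage on synthetic cohorts plus the packaged clinical
    fixture; artifacts land in ``out_dir`` and a summary dict is returned."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    summary: dict = {"config_hash": chash, "seed": config.seed, "stages": {}}
    manifest = default_manifest()
    manifest.to_json(out / "feature_manifest.json")

    def stage(name):
        t0 = time.perf_counter()

        def done(**info):
            summary["stages"][name] = {
                "seconds": round(time.perf_counter() - t0, 2), **info
            }

        return done

    # --- test-retest cohort and reproducibility screen inputs
    done = stage("simulate_retest")
    retest_cfg = config.phantom_config(n_subjects=config.n_retest_pairs)
    pairs = [
        generate_test_retest_pair(retest_cfg, f"tr{i:03d}")
        for i in range(config.n_retest_pairs)
    ]
    done(n_pairs=len(pairs))

    done = stage("extract_retest")
    day1 = extract_table([p[0] for p in pairs], manifest)
    day2 = extract_table([p[1] for p in pairs], manifest)
    day1.to_csv(out / "features_day1.csv")
    day2.to_csv(out / "features_day2.csv")
    done(n_features=day1.shape[1])

    # --- therapy cohort
    done = stage("simulate_therapy")
    therapy_cfg = config.phantom_config(n_subjects=config.n_therapy_subjects)
    longi = generate_longitudinal_cohort(therapy_cfg)
    longi.caliper.to_csv(out / "caliper.csv")
    done(n_subjects=config.n_therapy_subjects,
         classes=longi.labels.value_counts().to_dict())

    done = stage("metrics")
    suv_rows = {
        (s.subject_id, s.timepoint): suv_summary(s).as_dict()
        for s in longi.scans
    }
    suv_df = pd.DataFrame(suv_rows).T
    suv_df.index.names = ["subject_id", "timepoint"]
    suv_df.to_csv(out / "suv_metrics.csv")
    done(n_scans=len(suv_df))

    done = stage("extract_therapy")
    bl = extract_table(longi.at("BL"), manifest)
    ontx = extract_table(longi.at("ONTX"), manifest)
    bl.to_csv(out / "features_bl.csv")
    ontx.to_csv(out / "features_ontx.csv")
    done(n_scans=len(bl) + len(ontx))

    # --- robustness screen on the 129 screened features
    done = stage("screen")
    screened = manifest.screened_names
    volumes = bl["tumor_volume_ml"].copy()
    volumes.index = volumes.index.get_level_values("subject_id")
    report = run_robustness_screen(
        day1[screened], day2[screened], bl[screened], volumes,
        config.lcc_threshold, config.rho_threshold, config.p_threshold,
    )
    report.table.to_csv(out / "robustness_report.csv")
    done(**report.counts)

    # --- RadSig per task
    done = stage("select")
    robust = report.robust_features
    labels = longi.labels
    rcfg = RelieffConfig(seed=config.seed, relevance_threshold=config.tau)
    bl_sub = bl[robust]
    bl_sub.index = bl_sub.index.get_level_values("subject_id")
    radsig_pred = select_radsig(
        bl_sub, labels, "prediction", rcfg, config.tau, size=config.radsig_size
    )
    delta_full = delta_table(bl, ontx)
    delta = delta_full[robust]
    radsig_assess = select_radsig(
        delta, labels, "assessment", rcfg, config.tau, size=config.radsig_size
    )
    with open(out / "radsig.json", "w") as fh:
        json.dump(
            {
                "config_hash": chash,
                "prediction": {
                    f: radsig_pred.weights[f] for f in radsig_pred.features
                },
                "assessment": {
                    f: radsig_assess.weights[f] for f in radsig_assess.features
                },
            },
            fh, indent=1,
        )
    done(prediction=radsig_pred.features, assessment=radsig_assess.features)

    # --- models: RadSig vs SUV comparators, both tasks
    done = stage("train")
    spec = ModelSpec(kind="gaussian_nb", seed=config.seed)
    suv_single = ["suv_mean", "suv_max", "sul_peak"]
    task_tables = {"prediction": bl_sub, "assessment": delta}
    radsigs = {"prediction": radsig_pred, "assessment": radsig_assess}
    perf_rows = []
    for task, tbl in task_tables.items():
        predictors = {"radsig": tbl[radsigs[task].features]}
        for m in suv_single:
            src = bl if task == "prediction" else delta_full
            col = src[[m]].copy()
            if isinstance(col.index, pd.MultiIndex):
                col.index = col.index.get_level_values("subject_id")
            predictors[m] = col
        comp = evaluate_predictors(
            predictors, labels, spec, config.folds, config.seed, task
        )
        comp["task"] = task
        perf_rows.append(comp.reset_index())
        for kind in MODEL_KINDS:
            rep = cross_validate(
                tbl[radsigs[task].features], labels,
                ModelSpec(kind=kind, seed=config.seed),
                config.folds, config.seed, task,
            )
            perf_rows.append(
                pd.DataFrame([{"predictor": f"radsig[{kind}]", "task": task,
                               **rep.metrics()}])
            )
    perf = pd.concat(perf_rows, ignore_index=True)
    perf.to_csv(out / "performance.csv", index=False)
    done(n_rows=len(perf))

    # --- accuracy vs feature count (prediction task)
    done = stage("accuracy_curve")
    from .relieff import rank_importance, relieff_rank

    weights = relieff_rank(bl_sub, labels, rcfg)
    shortlist = rank_importance(weights, config.tau, top_n=15)
    curve = accuracy_vs_feature_count(
        bl_sub, labels, shortlist, folds=config.folds, seed=config.seed,
        max_n=min(10, len(shortlist)),
    )
    curve.to_csv(out / "accuracy_vs_features.csv")
    sat = {m: saturation_point(curve[m]) for m in curve.columns}
    done(saturation=sat)

    # --- clinical fixture statistics
    done = stage("cohort_stats")
    stats = clinical.all_group_stats()
    stats.to_csv(out / "clinical_group_stats.csv")
    done(pcr_patients=clinical.pcr_patient_count())

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=str)
    return summary
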