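"""NIfTI and manifest-CSV round-tripping of scan cohorts."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .types import ScanRecord, SuvImage

MANIFEST_COLUMNS = [
    "subject_id", "arm", "timepoint", "image", "mask",
    "injected_dose_bq", "body_weight_g", "sex", "height_cm", "label",
]


def write_scan(scan: ScanRecord, out_dir: Path, stem: str | None = None):
    """Write image and mask NIfTI pairs; returns their paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = stem or f"{scan.subject_id}_{scan.timepoint}"
    affine = np.diag(list(scan.image.spacing_mm) + [1.0])
    img_path = out_dir / f"{stem}_pet.nii.gz"
    mask_path = out_dir / f"{stem}_mask.nii.gz"
    nib.save(nib.Nifti1Image(scan.image.values, affine), img_path)
    nib.save(nib.Nifti1Image(scan.mask.astype(np.uint8), affine), mask_path)
    return img_path, mask_path


def write_cohort(
    scans: list[ScanRecord], out_dir: Path, labels: pd.Series | None = None
) -> Path:
    """Write all scans plus a manifest CSV; returns the manifest path."""
    out_dir = Path(out_dir)
    rows = []
    for scan in scans:
        img_path, mask_path = write_scan(scan, out_dir)
        label = ""
        if labels is not None and scan.subject_id in labels.index:
            label = labels.loc[scan.subject_id]
        rows.append({
            "subject_id": scan.subject_id,
            "arm": scan.arm,
            "timepoint": scan.timepoint,
            "image": img_path.name,
            "mask": mask_path.name,
            "injected_dose_bq": scan.injected_dose_bq,
            "body_weight_g": scan.body_weight_g,
            "sex": scan.sex,
            "height_cm": scan.height_cm if scan.height_cm is not None else "",
            "label": label,
        })
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    return manifest


def read_cohort(manifest_path: Path) -> tuple[list[ScanRecord], pd.Series]:
    """Load scans and subject labels back from a manifest CSV."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    df = pd.read_csv(manifest_path)
    scans = []
    labels = {}
    for _, row in df.iterrows():
        img = nib.load(base / row["image"])
        msk = nib.load(base / row["mask"])
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        height = row.get("height_cm")
        scans.append(
            ScanRecord(
                subject_id=str(row["subject_id"]),
                arm=row["arm"],
                timepoint=row["timepoint"],
                image=SuvImage(np.asarray(img.dataobj, dtype=np.float64), spacing),
                mask=np.asarray(msk.dataobj) > 0,
                injected_dose_bq=float(row["injected_dose_bq"]),
                body_weight_g=float(row["body_weight_g"]),
                sex=row.get("sex", "unknown"),
                height_cm=float(height) if pd.notna(height) and height != "" else None,
            )
        )
        if pd.notna(row.get("label")) and row.get("label") != "":
            labels[str(row["subject_id"])] = row["label"]
    return scans, pd.Series(labels, name="label", dtype=object)
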