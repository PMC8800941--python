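"""Panel extraction: one identical pipeline for preclinical and clinical
scans.

First-order features and SUV metrics come from the raw (native-spacing) SUV
grid; texture families are computed on the isotropically resampled,
equal-probability quantized (Ng = 64) grid.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ..pet_metrics import suv_summary
from ..types import ScanRecord
from .first_order import first_order_features
from .manifest import FeatureManifest, default_manifest
from .preprocess import equalize_quantize, resample_isotropic
from . import texture

#: Default resampling target per arm: the native spacing of that arm.
DEFAULT_TARGET_SPACING = {"preclinical": 0.8, "clinical": 2.0}

_FAMILY_FUNCS = (
    texture.glcm_features,
    texture.glrlm_features,
    texture.glszm_features,
    texture.gldzm_features,
    texture.ngtdm_features,
    texture.gldm_features,
)


def extract_all(
    scan: ScanRecord,
    manifest: FeatureManifest | None = None,
    n_levels: int = 64,
    target_spacing_mm: float | None = None,
    max_na_fraction: float = 0.10,
) -> dict[str, float]:
    """Extract the full 131-feature panel of one scan.

    A family that fails on a degenerate mask yields NA values for its
    features; more than ``max_na_fraction`` missing raises.
    """
    if manifest is None:
        manifest = default_manifest()
    if target_spacing_mm is None:
        target_spacing_mm = min(
            DEFAULT_TARGET_SPACING.get(scan.arm, 1.0), min(scan.image.spacing_mm)
        )
    scan = scan.as_suv()
    out: dict[str, float] = {}

    out.update(first_order_features(scan, n_levels))

    img, msk, iso = resample_isotropic(
        scan.image.values, scan.mask, scan.image.spacing_mm, target_spacing_mm
    )
    q = equalize_quantize(img, msk, n_levels, iso)
    for fn in _FAMILY_FUNCS:
        try:
            out.update(fn(q))
        except ValueError as err:
            warnings.warn(f"{fn.__name__} failed: {err}; features set to NA")

    summ = suv_summary(scan)
    out.update(summ.as_dict())

    vec = {name: out.get(name, np.nan) for name in manifest.names}
    n_na = sum(1 for v in vec.values() if not np.isfinite(v))
    if n_na > max_na_fraction * len(vec):
        raise ValueError(f"{n_na}/{len(vec)} features failed to extract")
    return vec


def extract_table(
    scans: list[ScanRecord],
    manifest: FeatureManifest | None = None,
    n_levels: int = 64,
    target_spacing_mm: float | None = None,
) -> pd.DataFrame:
    """Scans x features table; the index is (subject_id, timepoint)."""
    if manifest is None:
        manifest = default_manifest()
    rows, idx = [], []
    for scan in scans:
        rows.append(extract_all(scan, manifest, n_levels, target_spacing_mm))
        idx.append((scan.subject_id, scan.timepoint))
    index = pd.MultiIndex.from_tuples(idx, names=["subject_id", "timepoint"])
    return pd.DataFrame(rows, index=index, columns=manifest.names)
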