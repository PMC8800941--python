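"""SUV normalization and non-radiomic PET quantification.

Implements the standard-uptake-value relation
``SUV = activity (Bq/mL) x body weight (g) / injected dose (Bq)``,
the nine-metric SUV summary panel (PERCIST-style SUL_peak included),
caliper tumor volume, metabolic tumor volume, percent change, and the
volume-change trichotomy used to label preclinical response to therapy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .types import ScanRecord

#: Volume of the SUL_peak averaging sphere (PERCIST uses ~1 mL).
PEAK_SPHERE_ML = 1.0


def normalize_suv(
    activity_bq_ml: np.ndarray, body_weight_g: float, injected_dose_bq: float
) -> np.ndarray:
    """Voxelwise SUV from an activity grid.

    SUV = activity (Bq/mL) x weight (g) / dose (Bq). The transform is linear
    and order-preserving.
    """
    if injected_dose_bq <= 0:
        raise ValueError("injected dose must be positive")
    if body_weight_g <= 0:
        raise ValueError("body weight must be positive")
    activity = np.asarray(activity_bq_ml, dtype=np.float64)
    return activity * (body_weight_g / injected_dose_bq)


def lean_body_mass_g(sex: str, body_weight_g: float, height_cm: float) -> float:
    """Lean body mass (g) by the Janmahasatian formulation.

    LBM_kg = 9270 W / (6680 + 216 BMI) for males,
             9270 W / (8780 + 244 BMI) for females, with W in kg and
    BMI = W / height_m^2.
    """
    if height_cm is None or height_cm <= 0:
        raise ValueError("height required for lean body mass")
    w_kg = body_weight_g / 1000.0
    bmi = w_kg / (height_cm / 100.0) ** 2
    if sex == "M":
        lbm_kg = 9270.0 * w_kg / (6680.0 + 216.0 * bmi)
    elif sex == "F":
        lbm_kg = 9270.0 * w_kg / (8780.0 + 244.0 * bmi)
    else:
        raise ValueError("sex must be 'M' or 'F' for lean body mass")
    return lbm_kg * 1000.0


def _sphere_offsets(spacing_mm: tuple[float, float, float], volume_ml: float):
    """Voxel offsets of a sphere of the given volume centred on a voxel."""
    r_mm = (3.0 * volume_ml * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)
    half = [int(math.floor(r_mm / s)) for s in spacing_mm]
    ax = [np.arange(-h, h + 1) * s for h, s in zip(half, spacing_mm)]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    inside = gx**2 + gy**2 + gz**2 <= r_mm**2
    ox, oy, oz = np.nonzero(inside)
    return (
        ox - half[0],
        oy - half[1],
        oz - half[2],
    )


def suv_peak(scan: ScanRecord, volume_ml: float = PEAK_SPHERE_ML):
    """Maximal sphere-averaged SUV with the sphere centred inside the VOI.

    Returns ``(peak, fell_back)``: if the VOI is smaller than the averaging
    sphere the whole-VOI mean is returned and flagged.
    """
    suv = scan.suv_values()
    mask = scan.mask
    if scan.tumor_volume_ml < volume_ml:
        return float(suv[mask].mean()), True
    ox, oy, oz = _sphere_offsets(scan.image.spacing_mm, volume_ml)
    shape = suv.shape
    centers = np.argwhere(mask)
    best = -np.inf
    for cx, cy, cz in centers:
        xs, ys, zs = cx + ox, cy + oy, cz + oz
        keep = (
            (xs >= 0) & (xs < shape[0])
            & (ys >= 0) & (ys < shape[1])
            & (zs >= 0) & (zs < shape[2])
        )
        vals = suv[xs[keep], ys[keep], zs[keep]]
        m = float(vals.mean())
        if m > best:  # ties keep the first center in lexicographic order
            best = m
    return best, False


def sul_peak(scan: ScanRecord, volume_ml: float = PEAK_SPHERE_ML):
    """SUL_peak = SUV_peak x LBM / body weight.

    Clinical scans use the Janmahasatian lean body mass (sex and height
    required); for preclinical animals SUL is taken identical to SUV (no
    accepted rodent LBM model). Returns ``(sul_peak, fell_back)``.
    """
    peak, fell_back = suv_peak(scan, volume_ml)
    return peak * _sul_factor(scan), fell_back


def _sul_factor(scan: ScanRecord) -> float:
    if scan.arm == "clinical":
        lbm = lean_body_mass_g(scan.sex, scan.body_weight_g, scan.height_cm)
        return lbm / scan.body_weight_g
    return 1.0


def metabolic_tumor_volume(scan: ScanRecord, fraction_of_max: float = 0.40) -> float:
    """Volume (mL) of mask voxels with SUV >= fraction_of_max x SUV_max."""
    suv = scan.suv_values()
    in_mask = suv[scan.mask]
    thr = fraction_of_max * in_mask.max()
    return float((in_mask >= thr).sum()) * scan.image.voxel_volume_ml


@dataclass
class SuvSummary:
    """The nine-metric SUV panel plus tumor and metabolic volumes."""

    suv_mean: float
    suv_max: float
    suv_peak: float
    sul_peak: float
    sul_mean: float
    suv_min: float
    suv_sd: float
    suv_median: float
    tlg: float  # total lesion glycolysis = SUV_mean x MTV, SUV.mL
    tumor_volume_ml: float
    metabolic_tumor_volume_ml: float
    peak_fell_back: bool = False

    METRIC_NAMES = (
        "suv_mean", "suv_max", "suv_peak", "sul_peak", "sul_mean",
        "suv_min", "suv_sd", "suv_median", "tlg",
    )

    def as_dict(self) -> dict[str, float]:
        d = {k: getattr(self, k) for k in self.METRIC_NAMES}
        d["tumor_volume_ml"] = self.tumor_volume_ml
        d["metabolic_tumor_volume_ml"] = self.metabolic_tumor_volume_ml
        return d


def suv_summary(scan: ScanRecord, mtv_fraction_of_max: float = 0.40) -> SuvSummary:
    """Whole-tumor SUV statistics over the mask."""
    suv = scan.suv_values()
    if not scan.mask.any():
        raise ValueError("empty mask")
    vals = suv[scan.mask]
    peak, fell_back = suv_peak(scan)
    sul = _sul_factor(scan)
    mtv = metabolic_tumor_volume(scan, mtv_fraction_of_max)
    mean = float(vals.mean())
    return SuvSummary(
        suv_mean=mean,
        suv_max=float(vals.max()),
        suv_peak=peak,
        sul_peak=peak * sul,
        sul_mean=mean * sul,
        suv_min=float(vals.min()),
        suv_sd=float(vals.std()),
        suv_median=float(np.median(vals)),
        tlg=mean * mtv,
        tumor_volume_ml=scan.tumor_volume_ml,
        metabolic_tumor_volume_ml=mtv,
        peak_fell_back=fell_back,
    )


def caliper_volume(length_mm: float, width_mm: float, ellipsoid: bool = False) -> float:
    """Caliper tumor volume (mm^3).

    Default is the literal 1/6 L W^2 convention; ``ellipsoid=True`` applies
    the pi/6 L W^2 ellipsoid variant instead.
    """
    if length_mm < 0 or width_mm < 0:
        raise ValueError("caliper measurements must be nonnegative")
    factor = math.pi / 6.0 if ellipsoid else 1.0 / 6.0
    return factor * length_mm * width_mm**2


def percent_change(baseline: float, followup: float) -> float:
    """100 x (followup - baseline) / baseline; reductions are negative."""
    if baseline == 0:
        raise ValueError("baseline must be nonzero")
    return 100.0 * (followup - baseline) / baseline


ResponseValue = Literal["response", "partial", "no_response"]


def classify_preclinical_response(
    volume_change_pct: float, cutoff: float = 20.0
) -> ResponseValue:
    """Volume-change trichotomy: > cutoff% shrinkage -> response, > cutoff%
    growth -> no_response, within +/-cutoff% (inclusive) -> partial."""
    x = float(volume_change_pct)
    if not math.isfinite(x):
        raise ValueError("volume change must be finite")
    if x < -cutoff:
        return "response"
    if x > cutoff:
        return "no_response"
    return "partial"
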