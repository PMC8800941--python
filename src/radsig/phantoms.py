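"""Synthetic co-clinical PET cohorts with known ground truth.

Tumors are ellipsoids filled with a correlated Gaussian random field
(smoothed white noise — one knob, the correlation length, controls texture)
on a noisy background, voxelized at preclinical (~0.8 mm) or clinical
(~2 mm) spacing. Test–retest pairs perturb the day-1 realization by a
jitter that redraws voxel noise and shifts the boundary sub-voxel-wise;
longitudinal cohorts plant a latent responder status that drives volume
shrinkage and a heterogeneity shift.

Images are stored as raw activity (Bq/mL) with per-scan dose and weight so
SUV normalization is exercised end to end.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .pet_metrics import caliper_volume, classify_preclinical_response, percent_change
from .types import Arm, ScanRecord, SuvImage, Timepoint

_TIMEPOINT_CODE = {"BL": 0, "ONTX": 1, "RETEST": 2}


@dataclass
class PhantomConfig:
    """Study conditions of a synthetic cohort.

    Defaults mirror the co-clinical acquisition: 0.8 mm isotropic
    preclinical voxels (2.0 mm clinical), PDX-scale tumors, moderate
    texture, small day-to-day jitter.
    """

    n_subjects: int = 40
    arm: Arm = "preclinical"
    voxel_spacing_mm: tuple[float, float, float] | None = None
    tumor_radius_range_mm: tuple[float, float] = (3.0, 7.0)
    texture_correlation_length_mm: float = 1.6
    texture_amplitude: float = 0.30  # fractional SD of the correlated field
    background_suv: float = 0.4
    tumor_suv_mean: float = 2.5
    noise_sd: float = 0.05  # SUV units, white voxel noise
    retest_jitter: float = 0.05
    responder_fraction: float = 0.5
    effect_size: float = 1.0
    fov_margin_mm: float = 3.0
    fov_mm: float | None = None  # fixed field of view; default fits the tumor
    seed: int = 0

    def __post_init__(self) -> None:
        if self.voxel_spacing_mm is None:
            self.voxel_spacing_mm = (
                (0.8, 0.8, 0.8) if self.arm == "preclinical" else (2.0, 2.0, 2.0)
            )
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError("voxel spacing must be positive")
        lo, hi = self.tumor_radius_range_mm
        if not (0 < lo <= hi):
            raise ValueError("tumor radius range must be positive and ordered")
        if self.texture_correlation_length_mm <= 0:
            raise ValueError("texture correlation length must be positive")
        if self.background_suv <= 0 or self.tumor_suv_mean <= 0:
            raise ValueError("SUV levels must be positive")
        if self.noise_sd < 0 or self.retest_jitter < 0:
            raise ValueError("noise_sd and retest_jitter must be nonnegative")
        if not 0.0 <= self.responder_fraction <= 1.0:
            raise ValueError("responder_fraction must lie in [0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be nonnegative")


def _subject_rng(config: PhantomConfig, subject_id: str, timepoint: str):
    key = zlib.crc32(subject_id.encode())
    return np.random.default_rng(
        [config.seed & 0x7FFFFFFF, key, _TIMEPOINT_CODE.get(timepoint, 3)]
    )


@dataclass
class _TumorGeometry:
    semi_axes_mm: np.ndarray  # (3,)
    field_seed: int
    amp: float


def _draw_geometry(config: PhantomConfig, rng, amp: float) -> _TumorGeometry:
    lo, hi = config.tumor_radius_range_mm
    r = rng.uniform(lo, hi)
    ratios = rng.uniform(0.8, 1.2, size=3)
    semi = r * ratios / ratios.prod() ** (1 / 3)  # volume of the r-sphere
    return _TumorGeometry(semi, int(rng.integers(0, 2**31 - 1)), amp)


def _metadata(config: PhantomConfig, rng) -> dict:
    if config.arm == "preclinical":
        return {
            "injected_dose_bq": float(rng.uniform(6.66e6, 8.14e6)),
            "body_weight_g": float(rng.normal(25.0, 2.0)),
            "sex": "F",
            "height_cm": None,
        }
    return {
        "injected_dose_bq": float(rng.uniform(3.5e8, 3.9e8)),  # ~10 mCi
        "body_weight_g": float(np.clip(rng.normal(7.0e4, 8.0e3), 4.5e4, 1.1e5)),
        "sex": "F",
        "height_cm": float(rng.normal(162.0, 6.0)),
    }


def _realize(
    config: PhantomConfig,
    geom: _TumorGeometry,
    subject_id: str,
    timepoint: Timepoint,
    noise_rng,
    meta: dict,
    center_shift_mm: np.ndarray | None = None,
    scale: float = 1.0,
) -> ScanRecord:
    spacing = np.asarray(config.voxel_spacing_mm)
    semi = geom.semi_axes_mm
    fov = config.fov_mm or 2 * (semi.max() + config.fov_margin_mm)
    shape = tuple(int(np.ceil(fov / s)) for s in spacing)
    if any(2 * a >= n * s for a, n, s in zip(semi, shape, spacing)):
        raise ValueError("tumor larger than field of view")
    center = (np.asarray(shape) - 1) / 2.0 * spacing
    if center_shift_mm is not None:
        center = center + center_shift_mm
    ax = [np.arange(n) * s for n, s in zip(shape, spacing)]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    mask = (
        ((gx - center[0]) / semi[0]) ** 2
        + ((gy - center[1]) / semi[1]) ** 2
        + ((gz - center[2]) / semi[2]) ** 2
    ) <= 1.0
    if not mask.any():
        raise ValueError("tumor mask is empty at this voxel spacing")

    # correlated texture field: same realization across timepoints of a tumor
    field_rng = np.random.default_rng(geom.field_seed)
    white = field_rng.standard_normal(shape)
    sigma_vox = config.texture_correlation_length_mm / spacing
    fieldv = ndimage.gaussian_filter(white, sigma=sigma_vox)
    sd = fieldv.std()
    if sd > 0:
        fieldv /= sd

    suv = np.full(shape, config.background_suv, dtype=np.float64)
    tumor = config.tumor_suv_mean * (1.0 + geom.amp * fieldv[mask])
    suv[mask] = tumor
    if config.noise_sd > 0:
        suv += noise_rng.normal(0.0, config.noise_sd, size=shape)
    suv *= scale
    np.clip(suv, 0.0, None, out=suv)

    activity = suv * meta["injected_dose_bq"] / meta["body_weight_g"]
    return ScanRecord(
        subject_id=subject_id,
        arm=config.arm,
        timepoint=timepoint,
        image=SuvImage(activity, tuple(spacing)),
        mask=mask,
        is_suv=False,
        **meta,
    )


def generate_scan(
    config: PhantomConfig, subject_id: str, timepoint: Timepoint = "BL"
) -> ScanRecord:
    """One synthetic acquisition; bit-identical under identical config+seed."""
    rng = _subject_rng(config, subject_id, timepoint)
    geom = _draw_geometry(config, rng, config.texture_amplitude)
    meta = _metadata(config, rng)
    return _realize(config, geom, subject_id, timepoint, rng, meta)


def generate_test_retest_pair(
    config: PhantomConfig, subject_id: str
) -> tuple[ScanRecord, ScanRecord]:
    """Day-1/day-2 pair: same tumor, day-2 perturbed by ``retest_jitter``.

    Jitter redraws the voxel noise, scales intensities globally by
    ``1 + jitter * eps``, and shifts the boundary by a sub-voxel offset
    proportional to jitter. ``retest_jitter = 0`` returns identical scans.
    """
    rng = _subject_rng(config, subject_id, "BL")
    geom = _draw_geometry(config, rng, config.texture_amplitude)
    meta = _metadata(config, rng)
    day1 = _realize(config, geom, subject_id, "BL", rng, meta)
    j = config.retest_jitter
    if j == 0:
        day2 = replace(day1)
        day2.image = SuvImage(day1.image.values.copy(), day1.image.spacing_mm)
        day2.mask = day1.mask.copy()
        return day1, day2
    rng2 = _subject_rng(config, subject_id, "RETEST")
    shift = rng2.normal(0.0, j, size=3) * np.asarray(config.voxel_spacing_mm)
    scale = float(np.exp(rng2.normal(0.0, j)))
    day2 = _realize(
        config, geom, subject_id, "BL", rng2, meta,
        center_shift_mm=shift, scale=scale,
    )
    return day1, day2


#: classes of the preclinical volume-change trichotomy
PRECLINICAL_CLASSES = ("response", "partial", "no_response")

_VOLUME_FACTOR = {
    "response": (0.40, 0.75),   # > 20% shrinkage
    "partial": (0.85, 1.15),    # within +/- 20%
    "no_response": (1.25, 1.70),  # > 20% growth
}


@dataclass
class LongitudinalCohort:
    """Baseline and on-treatment scans with ground-truth response labels."""

    scans: list[ScanRecord]
    labels: pd.Series  # subject_id -> class
    caliper: pd.DataFrame  # subject_id x (L/W at BL and endpoint, %change)
    config: PhantomConfig

    def at(self, timepoint: Timepoint) -> list[ScanRecord]:
        return [s for s in self.scans if s.timepoint == timepoint]


def _assign_classes(config: PhantomConfig, binary: bool) -> list[str]:
    n = config.n_subjects
    n_resp = int(round(config.responder_fraction * n))
    if binary:
        return ["response"] * n_resp + ["no_response"] * (n - n_resp)
    rest = n - n_resp
    n_partial = rest // 2
    return (
        ["response"] * n_resp
        + ["partial"] * n_partial
        + ["no_response"] * (rest - n_partial)
    )


def generate_longitudinal_cohort(
    config: PhantomConfig, binary: bool = False
) -> LongitudinalCohort:
    """Baseline + on-treatment cohort with planted response structure.

    Responders carry elevated baseline texture amplitude
    (``amp * (1 + effect_size)``) which relaxes to the nominal amplitude on
    treatment, and shrink by > 20%; non-responders grow by > 20% with
    unchanged texture; partials stay within +/-20%. ``binary=True`` emulates
    the clinical pCR dichotomy (responder -> pCR, no partial class).
    """
    classes = _assign_classes(config, binary)
    scans: list[ScanRecord] = []
    labels = {}
    cal_rows = []
    for i, cls in enumerate(classes):
        sid = f"{config.arm[:3]}{i:03d}"
        rng = _subject_rng(config, sid, "BL")
        amp_bl = config.texture_amplitude * (
            1.0 + (config.effect_size if cls == "response" else 0.0)
        )
        geom = _draw_geometry(config, rng, amp_bl)
        meta = _metadata(config, rng)
        scans.append(_realize(config, geom, sid, "BL", rng, meta))

        lo, hi = _VOLUME_FACTOR[cls]
        rng2 = _subject_rng(config, sid, "ONTX")
        factor = rng2.uniform(lo, hi)
        geom2 = _TumorGeometry(
            geom.semi_axes_mm * factor ** (1 / 3),
            geom.field_seed,
            config.texture_amplitude,  # responders relax to nominal
        )
        scans.append(_realize(config, geom2, sid, "ONTX", rng2, meta))

        ax_bl = np.sort(geom.semi_axes_mm)[::-1] * 2.0
        ax_tx = np.sort(geom2.semi_axes_mm)[::-1] * 2.0
        v_bl = caliper_volume(ax_bl[0], ax_bl[1])
        v_tx = caliper_volume(ax_tx[0], ax_tx[1])
        pct = percent_change(v_bl, v_tx)
        labels[sid] = (
            cls if binary else classify_preclinical_response(pct)
        )
        cal_rows.append(
            {
                "subject_id": sid,
                "L_bl_mm": ax_bl[0], "W_bl_mm": ax_bl[1],
                "L_tx_mm": ax_tx[0], "W_tx_mm": ax_tx[1],
                "caliper_volume_bl_mm3": v_bl,
                "caliper_volume_tx_mm3": v_tx,
                "volume_change_pct": pct,
                "latent_class": cls,
            }
        )
    if binary:
        labels = {k: ("pCR" if v == "response" else "non_pCR") for k, v in labels.items()}
    return LongitudinalCohort(
        scans=scans,
        labels=pd.Series(labels, name="label"),
        caliper=pd.DataFrame(cal_rows).set_index("subject_id"),
        config=config,
    )


def generate_tabular_cohort(
    n_samples: int,
    n_features: int = 30,
    n_signal: int = 4,
    effect_size: float = 1.6,
    n_classes: int = 2,
    seed: int = 0,
    feature_names: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Feature-space cohort with exactly ``n_signal`` planted discriminative
    features among pure-noise decoys.

    Signal features are shifted by ``effect_size`` standard deviations
    between consecutive classes; decoys are N(0, 1) regardless of class.
    """
    rng = np.random.default_rng(seed)
    classes = np.arange(n_classes).repeat(
        np.diff(np.linspace(0, n_samples, n_classes + 1).astype(int))
    )
    rng.shuffle(classes)
    x = rng.standard_normal((n_samples, n_features))
    x[:, :n_signal] += effect_size * classes[:, None]
    if feature_names is None:
        feature_names = [
            f"signal_{i}" if i < n_signal else f"decoy_{i - n_signal}"
            for i in range(n_features)
        ]
    idx = pd.Index([f"s{i:03d}" for i in range(n_samples)], name="subject_id")
    table = pd.DataFrame(x, index=idx, columns=feature_names)
    labels = pd.Series(classes, index=idx, name="label").map(
        lambda c: f"class_{c}"
    )
    return table, labels
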