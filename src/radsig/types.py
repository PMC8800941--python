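"""Core containers shared across the pipeline.

A scan is a 3D PET volume (raw activity in Bq/mL or already-normalized SUV)
with an aligned binary tumor mask and the acquisition metadata needed for
SUV/SUL normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

Arm = Literal["preclinical", "clinical"]
Timepoint = Literal["BL", "ONTX"]
Sex = Literal["F", "M", "unknown"]


@dataclass
class SuvImage:
    """A 3D voxel grid with its voxel spacing in mm.

    ``values`` may hold raw activity (Bq/mL) or SUV; the interpretation is
    tracked by :attr:`ScanRecord.is_suv`.
    """

    values: np.ndarray  # 3D, nonnegative
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("image must be 3D")
        sp = tuple(float(s) for s in self.spacing_mm)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValueError("spacing must be three positive values (mm)")
        self.spacing_mm = sp

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    @property
    def voxel_volume_ml(self) -> float:
        return self.voxel_volume_mm3 / 1000.0


@dataclass
class ScanRecord:
    """One acquisition: image + tumor mask + subject/timepoint metadata."""

    subject_id: str
    arm: Arm
    timepoint: Timepoint
    image: SuvImage
    mask: np.ndarray  # boolean, same shape as image
    injected_dose_bq: float
    body_weight_g: float
    sex: Sex = "unknown"
    height_cm: float | None = None
    is_suv: bool = False

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.shape != self.image.values.shape:
            raise ValueError("image and mask shapes differ")
        if not self.mask.any():
            raise ValueError("mask has no foreground voxel")
        if self.injected_dose_bq <= 0:
            raise ValueError("injected dose must be positive")
        if self.body_weight_g <= 0:
            raise ValueError("body weight must be positive")

    def suv_values(self) -> np.ndarray:
        """The voxel grid on the SUV scale (normalizing on the fly if raw)."""
        if self.is_suv:
            return self.image.values
        from .pet_metrics import normalize_suv

        return normalize_suv(
            self.image.values, self.body_weight_g, self.injected_dose_bq
        )

    def as_suv(self) -> "ScanRecord":
        """A copy of this record with the image converted to SUV units."""
        if self.is_suv:
            return self
        return replace(
            self,
            image=SuvImage(self.suv_values(), self.image.spacing_mm),
            is_suv=True,
        )

    @property
    def tumor_volume_ml(self) -> float:
        return float(self.mask.sum()) * self.image.voxel_volume_ml
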