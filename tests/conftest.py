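from __future__ import annotations

import numpy as np
import pytest

from radsig.features.preprocess import QuantizedImage
from radsig.phantoms import PhantomConfig, generate_scan
from radsig.types import ScanRecord, SuvImage


def make_scan(
    values,
    mask=None,
    spacing=(1.0, 1.0, 1.0),
    arm="preclinical",
    dose=7.4e6,
    weight=25.0,
    is_suv=True,
    **kwargs,
):
    values = np.asarray(values, float)
    if mask is None:
        mask = np.ones_like(values, bool)
    return ScanRecord(
        subject_id=kwargs.pop("subject_id", "t0"),
        arm=arm,
        timepoint=kwargs.pop("timepoint", "BL"),
        image=SuvImage(values, spacing),
        mask=mask,
        injected_dose_bq=dose,
        body_weight_g=weight,
        is_suv=is_suv,
        **kwargs,
    )


def random_quantized(seed=0, shape=(4, 4, 4), ng=4, mask_fraction=0.8):
    """A small random quantized grid with a ragged mask for oracle tests."""
    rng = np.random.default_rng(seed)
    levels = rng.integers(1, ng + 1, size=shape)
    mask = rng.random(shape) < mask_fraction
    if not mask.any():
        mask[tuple(s // 2 for s in shape)] = True
    levels = np.where(mask, levels, 0)
    return QuantizedImage(levels, mask, ng)


@pytest.fixture(scope="session")
def phantom_config():
    return PhantomConfig(n_subjects=4, seed=11)


@pytest.fixture(scope="session")
def sample_scan(phantom_config):
    return generate_scan(phantom_config, "fix000")
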