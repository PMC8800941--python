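"""First-order features: 18 intensity statistics on the raw in-mask voxels
plus 19 statistics of the Ng-level equal-probability intensity histogram."""

from __future__ import annotations

import numpy as np

from ..types import ScanRecord
from .preprocess import equalize_quantize


def _dispersion_stats(x: np.ndarray) -> dict[str, float]:
    """The 16 shared location/dispersion statistics of a sample."""
    x = np.asarray(x, float)
    n = x.size
    mean = float(x.mean())
    var = float(x.var())
    sd = var**0.5
    med = float(np.median(x))
    p10, q1, q3, p90 = (float(v) for v in np.percentile(x, [10, 25, 75, 90]))
    centred = x - mean
    skew = float((centred**3).mean() / sd**3) if sd > 0 else 0.0
    kurt = float((centred**4).mean() / sd**4 - 3.0) if sd > 0 else 0.0
    robust = x[(x >= p10) & (x <= p90)]
    return {
        "mean": mean,
        "variance": var,
        "skewness": skew,
        "kurtosis": kurt,
        "median": med,
        "minimum": float(x.min()),
        "p10": p10,
        "p90": p90,
        "maximum": float(x.max()),
        "interquartile_range": q3 - q1,
        "range": float(x.max() - x.min()),
        "mean_absolute_deviation": float(np.abs(centred).mean()),
        "robust_mean_absolute_deviation": float(
            np.abs(robust - robust.mean()).mean()
        )
        if robust.size
        else 0.0,
        "median_absolute_deviation": float(np.abs(x - med).mean()),
        "coefficient_of_variation": sd / mean if mean != 0 else 0.0,
        "quartile_coefficient_of_dispersion": (q3 - q1) / (q3 + q1)
        if (q3 + q1) != 0
        else 0.0,
    }


def intensity_features(values: np.ndarray) -> dict[str, float]:
    """18 raw-intensity statistics, ``fo_`` prefixed."""
    x = np.asarray(values, float)
    if x.size == 0:
        raise ValueError("no in-mask voxels")
    out = {f"fo_{k}": v for k, v in _dispersion_stats(x).items()}
    out["fo_energy"] = float((x**2).sum())
    out["fo_root_mean_square"] = float(np.sqrt((x**2).mean()))
    return out


def histogram_features(values: np.ndarray, n_levels: int = 64) -> dict[str, float]:
    """19 statistics of the equal-probability quantized histogram,
    ``ih_`` prefixed. Entropy is in bits."""
    x = np.asarray(values, float).ravel()
    if x.size == 0:
        raise ValueError("no in-mask voxels")
    q = equalize_quantize(x.reshape(-1, 1, 1), np.ones((x.size, 1, 1), bool), n_levels)
    lv = q.levels[q.mask].astype(float)
    out = {f"ih_{k}": v for k, v in _dispersion_stats(lv).items()}
    counts = np.bincount(lv.astype(int), minlength=n_levels + 1)[1:]
    p = counts / counts.sum()
    nz = p[p > 0]
    out["ih_mode"] = float(np.argmax(counts) + 1)
    out["ih_entropy"] = float(-(nz * np.log2(nz)).sum())
    out["ih_uniformity"] = float((p**2).sum())
    return out


def first_order_features(scan: ScanRecord, n_levels: int = 64) -> dict[str, float]:
    """All 37 first-order features of a scan (raw grid, no resampling)."""
    vals = scan.suv_values()[scan.mask]
    out = intensity_features(vals)
    out.update(histogram_features(vals, n_levels))
    return out
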