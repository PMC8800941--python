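"""The clinical interim-analysis cohort.

Twenty stage II/III TNBC patients (25 breast lesions) with pathological
response (pCR yes/no), baseline SUV_mean / SUL_peak / SUV_max, and the
percent change in each between on-treatment (post cycle 1) and baseline.
Shipped as a packaged CSV; group statistics treat lesion rows as
observations (sample SD, NA rows excluded), the convention under which the
published group means/SDs reproduce exactly.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import numpy as np
import pandas as pd

_FIXTURE_SHA256 = "be96812836fc7ab77d99eb83003a84406d8c0c010ea2df353e573699ad760dc4"

DELTA_METRICS = ("d_suv_mean", "d_sul_peak", "d_suv_max")
GROUPS = ("pCR", "non_pCR")


def _fixture_bytes() -> bytes:
    ref = resources.files("radsig.data").joinpath("clinical_cohort.csv")
    return ref.read_bytes()


def load_cohort(verify: bool = True) -> pd.DataFrame:
    """The 25 lesion rows over 20 patients; grade '?' is stored missing."""
    raw = _fixture_bytes()
    if verify:
        digest = hashlib.sha256(raw).hexdigest()
        if digest != _FIXTURE_SHA256:
            raise ValueError("clinical cohort fixture failed its checksum")
    import io

    df = pd.read_csv(io.BytesIO(raw), dtype={"grade": "string"})
    _validate(df)
    return df


def _validate(df: pd.DataFrame) -> None:
    if len(df) != 25:
        raise ValueError("expected 25 lesion rows")
    if df["patient_id"].nunique() != 20:
        raise ValueError("expected 20 patients")
    per_patient = df.groupby("patient_id")["pcr"].nunique()
    if (per_patient != 1).any():
        raise ValueError("pCR must be constant within a patient")
    na = df[list(DELTA_METRICS)].isna()
    if not (na.all(axis=1) | (~na).all(axis=1)).all():
        raise ValueError("%-change fields must be jointly present or NA")


def pcr_patient_count(df: pd.DataFrame | None = None) -> int:
    if df is None:
        df = load_cohort()
    return int(df[df["pcr"] == "Yes"]["patient_id"].nunique())


def group_delta_stats(
    df: pd.DataFrame | None = None,
    metric: str = "d_suv_mean",
    group: str = "non_pCR",
) -> tuple[float, float]:
    """Mean and sample SD (n-1) of a percent-change metric over the lesion
    rows of one response group, NA rows excluded."""
    if df is None:
        df = load_cohort()
    if metric not in DELTA_METRICS:
        raise ValueError(f"metric must be one of {DELTA_METRICS}")
    pcr_value = "Yes" if group == "pCR" else "No"
    vals = df.loc[df["pcr"] == pcr_value, metric].dropna()
    if vals.empty:
        raise ValueError("no observations in the selected group")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else float("nan")
    return mean, sd


def all_group_stats(df: pd.DataFrame | None = None) -> pd.DataFrame:
    """The six (metric x group) mean +/- SD percent reductions."""
    if df is None:
        df = load_cohort()
    rows = []
    for group in GROUPS:
        for metric in DELTA_METRICS:
            mean, sd = group_delta_stats(df, metric, group)
            rows.append({"group": group, "metric": metric, "mean": mean, "sd": sd})
    return pd.DataFrame(rows).set_index(["group", "metric"])


def pcr_labels(df: pd.DataFrame | None = None) -> pd.Series:
    """Patient-level pCR/non_pCR labels."""
    if df is None:
        df = load_cohort()
    per = df.drop_duplicates("patient_id").set_index("patient_id")["pcr"]
    return per.map({"Yes": "pCR", "No": "non_pCR"}).rename("label")
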