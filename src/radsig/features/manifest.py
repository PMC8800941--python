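"""The versioned manifest of the 131-feature panel.

Composition: 37 first-order + 25 GLCM + 16 GLRLM + 16 GLSZM + 16 GLDZM +
5 NGTDM + 5 GLDM dependence features = 120 radiomic features, plus tumor
volume, metabolic tumor volume, and the nine SUV metrics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

MANIFEST_VERSION = "1.0"

FIRST_ORDER_STATS = [
    "mean", "variance", "skewness", "kurtosis", "median", "minimum",
    "p10", "p90", "maximum", "interquartile_range", "range",
    "mean_absolute_deviation", "robust_mean_absolute_deviation",
    "median_absolute_deviation", "coefficient_of_variation",
    "quartile_coefficient_of_dispersion", "energy", "root_mean_square",
]
# histogram features reuse the 16 location/dispersion statistics on bin
# indices (energy/RMS replaced by mode/entropy/uniformity)
HISTOGRAM_STATS = FIRST_ORDER_STATS[:16] + ["mode", "entropy", "uniformity"]

GLCM_FEATURES = [
    "joint_maximum", "joint_average", "joint_variance", "joint_entropy",
    "difference_average", "difference_variance", "difference_entropy",
    "sum_average", "sum_variance", "sum_entropy", "angular_second_moment",
    "contrast", "dissimilarity", "inverse_difference",
    "inverse_difference_normalized", "inverse_difference_moment",
    "inverse_difference_moment_normalized", "inverse_variance",
    "correlation", "autocorrelation", "cluster_tendency", "cluster_shade",
    "cluster_prominence", "information_correlation_1",
    "information_correlation_2",
]

GLRLM_FEATURES = [
    "short_run_emphasis", "long_run_emphasis", "low_gray_level_run_emphasis",
    "high_gray_level_run_emphasis", "short_run_low_gray_level_emphasis",
    "short_run_high_gray_level_emphasis", "long_run_low_gray_level_emphasis",
    "long_run_high_gray_level_emphasis", "gray_level_non_uniformity",
    "gray_level_non_uniformity_normalized", "run_length_non_uniformity",
    "run_length_non_uniformity_normalized", "run_percentage",
    "gray_level_variance", "run_length_variance", "run_entropy",
]

GLSZM_FEATURES = [
    "small_zone_emphasis", "large_zone_emphasis",
    "low_gray_level_zone_emphasis", "high_gray_level_zone_emphasis",
    "small_zone_low_gray_level_emphasis", "small_zone_high_gray_level_emphasis",
    "large_zone_low_gray_level_emphasis", "large_zone_high_gray_level_emphasis",
    "gray_level_non_uniformity", "gray_level_non_uniformity_normalized",
    "zone_size_non_uniformity", "zone_size_non_uniformity_normalized",
    "zone_percentage", "gray_level_variance", "zone_size_variance",
    "zone_size_entropy",
]

GLDZM_FEATURES = [
    "small_distance_emphasis", "large_distance_emphasis",
    "low_gray_level_zone_emphasis", "high_gray_level_zone_emphasis",
    "small_distance_low_gray_level_emphasis",
    "small_distance_high_gray_level_emphasis",
    "large_distance_low_gray_level_emphasis",
    "large_distance_high_gray_level_emphasis",
    "gray_level_non_uniformity", "gray_level_non_uniformity_normalized",
    "zone_distance_non_uniformity", "zone_distance_non_uniformity_normalized",
    "zone_percentage", "gray_level_variance", "zone_distance_variance",
    "zone_distance_entropy",
]

NGTDM_FEATURES = ["coarseness", "contrast", "busyness", "complexity", "strength"]

GLDM_FEATURES = [
    "small_dependence_emphasis", "large_dependence_emphasis",
    "dependence_non_uniformity", "dependence_variance", "dependence_entropy",
]

SUV_METRICS = [
    "suv_mean", "suv_max", "suv_peak", "sul_peak", "sul_mean",
    "suv_min", "suv_sd", "suv_median", "tlg",
]


@dataclass(frozen=True)
class FeatureDescriptor:
    name: str
    family: str  # first_order | glcm | glrlm | glszm | gldzm | ngtdm | gldm | volume | mtv | suv_metric
    preprocessing: str  # raw | quantized+resampled


@dataclass
class FeatureManifest:
    """Ordered feature descriptors; names are unique, length is 131."""

    descriptors: list[FeatureDescriptor] = field(default_factory=list)
    version: str = MANIFEST_VERSION

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.descriptors]

    def family(self, name: str) -> str:
        for d in self.descriptors:
            if d.name == name:
                return d.family
        raise KeyError(name)

    def names_in_family(self, *families: str) -> list[str]:
        return [d.name for d in self.descriptors if d.family in families]

    @property
    def radiomic_names(self) -> list[str]:
        """The 120 first-order + texture features."""
        return self.names_in_family(
            "first_order", "glcm", "glrlm", "glszm", "gldzm", "ngtdm", "gldm"
        )

    @property
    def screened_names(self) -> list[str]:
        """The 129 features entering robustness screening (everything but
        the two volume features, which the volume screen regresses against)."""
        return [d.name for d in self.descriptors if d.family not in ("volume", "mtv")]

    def validate(self) -> None:
        names = self.names
        if len(names) != len(set(names)):
            raise ValueError("feature names must be unique")
        counts = {}
        for d in self.descriptors:
            counts[d.family] = counts.get(d.family, 0) + 1
        expected = {
            "first_order": 37, "glcm": 25, "glrlm": 16, "glszm": 16,
            "gldzm": 16, "ngtdm": 5, "gldm": 5, "volume": 1, "mtv": 1,
            "suv_metric": 9,
        }
        if counts != expected:
            raise ValueError(f"panel composition {counts} != {expected}")
        if len(names) != 131:
            raise ValueError("panel must hold exactly 131 features")

    def to_json(self, path) -> None:
        payload = {
            "version": self.version,
            "aggregation": "per-direction features averaged over 13 directions",
            "features": [
                {"name": d.name, "family": d.family, "preprocessing": d.preprocessing}
                for d in self.descriptors
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def default_manifest() -> FeatureManifest:
    desc: list[FeatureDescriptor] = []
    for s in FIRST_ORDER_STATS:
        desc.append(FeatureDescriptor(f"fo_{s}", "first_order", "raw"))
    for s in HISTOGRAM_STATS:
        desc.append(FeatureDescriptor(f"ih_{s}", "first_order", "raw"))
    for fam, feats in (
        ("glcm", GLCM_FEATURES),
        ("glrlm", GLRLM_FEATURES),
        ("glszm", GLSZM_FEATURES),
        ("gldzm", GLDZM_FEATURES),
        ("ngtdm", NGTDM_FEATURES),
        ("gldm", GLDM_FEATURES),
    ):
        for s in feats:
            desc.append(FeatureDescriptor(f"{fam}_{s}", fam, "quantized+resampled"))
    desc.append(FeatureDescriptor("tumor_volume_ml", "volume", "raw"))
    desc.append(FeatureDescriptor("metabolic_tumor_volume_ml", "mtv", "raw"))
    for s in SUV_METRICS:
        desc.append(FeatureDescriptor(s, "suv_metric", "raw"))
    m = FeatureManifest(desc)
    m.validate()
    return m
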