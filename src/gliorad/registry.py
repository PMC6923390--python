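"""Feature registry and enumeration of the full radiomic feature space.

The study's feature space pairs two MR sequences (CE-T1, T2) with nine image
versions each (the original image plus eight stationary wavelet sub-bands).
Shape features are computed once per subject from the mask alone; intensity
and histogram features per image version; the five texture families per
image version and per quantization level (4-8 bit).  With the registered
family sizes 8 / 18 / 20 / 11 / 13 / 13 / 16 / 5 this enumerates

    8 + S * (9 * (18 + 20) + 9 * 5 * 58) = 5912   for S = 2 sequences.

Feature identities are IBSI-named.  The exact family memberships are
documented here; each set is chosen to contain the canonical members of its
family (in particular intensity median and root mean square, GLRLM
run-length variance, GLSZM gray-level non-uniformity normalized and
gray-level variance, NGLDM high dependence low gray-level emphasis).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .exceptions import ConfigError

__all__ = [
    "SHAPE_FEATURES",
    "INTENSITY_FEATURES",
    "HISTOGRAM_FEATURES",
    "GLCM_FEATURES",
    "GLRLM_FEATURES",
    "GLSZM_FEATURES",
    "NGLDM_FEATURES",
    "NGTDM_FEATURES",
    "FAMILY_FEATURES",
    "TEXTURE_FAMILIES",
    "FILTERS",
    "FeatureDescriptor",
    "SpaceConfig",
    "enumerate_feature_space",
]

SHAPE_FEATURES = (
    "volume",
    "surface_area",
    "surface_to_volume_ratio",
    "sphericity",
    "compactness1",
    "compactness2",
    "spherical_disproportion",
    "max_3d_diameter",
)

INTENSITY_FEATURES = (
    "mean",
    "variance",
    "skewness",
    "kurtosis",
    "median",
    "minimum",
    "maximum",
    "percentile10",
    "percentile90",
    "interquartile_range",
    "range",
    "mean_absolute_deviation",
    "robust_mean_absolute_deviation",
    "median_absolute_deviation",
    "coefficient_of_variation",
    "quartile_coefficient_of_dispersion",
    "energy",
    "root_mean_square",
)

HISTOGRAM_FEATURES = (
    "mean",
    "variance",
    "skewness",
    "kurtosis",
    "median",
    "minimum",
    "maximum",
    "mode",
    "percentile10",
    "percentile90",
    "interquartile_range",
    "range",
    "mean_absolute_deviation",
    "robust_mean_absolute_deviation",
    "coefficient_of_variation",
    "quartile_coefficient_of_dispersion",
    "entropy",
    "uniformity",
    "max_gradient",
    "max_gradient_level",
)

GLCM_FEATURES = (
    "joint_maximum",
    "joint_average",
    "joint_variance",
    "joint_entropy",
    "angular_second_moment",
    "contrast",
    "dissimilarity",
    "inverse_difference",
    "inverse_difference_moment",
    "correlation",
    "autocorrelation",
)

GLRLM_FEATURES = (
    "short_run_emphasis",
    "long_run_emphasis",
    "gray_level_non_uniformity",
    "gray_level_non_uniformity_normalized",
    "run_length_non_uniformity",
    "run_length_non_uniformity_normalized",
    "run_percentage",
    "low_gray_level_run_emphasis",
    "high_gray_level_run_emphasis",
    "short_run_low_gray_level_emphasis",
    "short_run_high_gray_level_emphasis",
    "gray_level_variance",
    "run_length_variance",
)

GLSZM_FEATURES = (
    "small_zone_emphasis",
    "large_zone_emphasis",
    "gray_level_non_uniformity",
    "gray_level_non_uniformity_normalized",
    "zone_size_non_uniformity",
    "zone_size_non_uniformity_normalized",
    "zone_percentage",
    "low_gray_level_zone_emphasis",
    "high_gray_level_zone_emphasis",
    "small_zone_high_gray_level_emphasis",
    "gray_level_variance",
    "zone_size_variance",
    "zone_size_entropy",
)

NGLDM_FEATURES = (
    "low_dependence_emphasis",
    "high_dependence_emphasis",
    "low_gray_level_count_emphasis",
    "high_gray_level_count_emphasis",
    "low_dependence_low_gray_level_emphasis",
    "low_dependence_high_gray_level_emphasis",
    "high_dependence_low_gray_level_emphasis",
    "high_dependence_high_gray_level_emphasis",
    "gray_level_non_uniformity",
    "gray_level_non_uniformity_normalized",
    "dependence_count_non_uniformity",
    "dependence_count_non_uniformity_normalized",
    "dependence_count_percentage",
    "gray_level_variance",
    "dependence_count_variance",
    "dependence_count_entropy",
)

NGTDM_FEATURES = ("coarseness", "contrast", "busyness", "complexity", "strength")

TEXTURE_FAMILIES = ("GLCM", "GLRLM", "GLSZM", "NGLDM", "NGTDM")

FAMILY_FEATURES: dict[str, tuple[str, ...]] = {
    "shape": SHAPE_FEATURES,
    "intensity": INTENSITY_FEATURES,
    "histogram": HISTOGRAM_FEATURES,
    "GLCM": GLCM_FEATURES,
    "GLRLM": GLRLM_FEATURES,
    "GLSZM": GLSZM_FEATURES,
    "NGLDM": NGLDM_FEATURES,
    "NGTDM": NGTDM_FEATURES,
}

#: Image versions: the unfiltered image plus the eight wavelet sub-bands.
FILTERS = ("orig", "HHH", "HHL", "HLH", "HLL", "LHH", "LHL", "LLH", "LLL")


@dataclass(frozen=True, order=True)
class FeatureDescriptor:
    """Identity of one radiomic feature.

    ``sequence`` is an MR sequence tag, or ``"mask"`` for shape features
    (computed from the tumor mask alone).  ``quant_bits`` is ``None`` except
    for texture features, which carry their quantization level.
    """

    sequence: str
    filter: str
    quant_bits: int | None
    family: str
    name: str

    def __str__(self) -> str:
        q = "none" if self.quant_bits is None else f"{self.quant_bits}bit"
        return f"{self.sequence}|{self.filter}|{q}|{self.family}|{self.name}"

    @classmethod
    def parse(cls, s: str) -> "FeatureDescriptor":
        seq, filt, q, family, name = s.split("|")
        bits = None if q == "none" else int(q.removesuffix("bit"))
        return cls(seq, filt, bits, family, name)


@dataclass(frozen=True)
class SpaceConfig:
    """Which slices of the feature space to enumerate/extract."""

    sequences: tuple[str, ...] = ("CE-T1", "T2")
    filters: tuple[str, ...] = FILTERS
    texture_bits: tuple[int, ...] = (4, 5, 6, 7, 8)
    histogram_bits: int = 6
    include_shape: bool = True

    def __post_init__(self):
        unknown = set(self.filters) - set(FILTERS)
        if unknown:
            raise ConfigError(f"unknown filters: {sorted(unknown)}")
        if any(not 1 <= b <= 16 for b in self.texture_bits):
            raise ConfigError("texture bits out of range")


def enumerate_feature_space(config: SpaceConfig | None = None) -> list[FeatureDescriptor]:
    """Enumerate the feature space in canonical order.

    Order: shape block first (mask-only, counted once), then per sequence,
    per filter: intensity, histogram, then each texture family with its
    quantization levels.  Deterministic; descriptor strings are unique.
    """
    config = config or SpaceConfig()
    out: list[FeatureDescriptor] = []
    if config.include_shape:
        out.extend(
            FeatureDescriptor("mask", "orig", None, "shape", n) for n in SHAPE_FEATURES
        )
    for seq in config.sequences:
        for filt in config.filters:
            out.extend(
                FeatureDescriptor(seq, filt, None, "intensity", n)
                for n in INTENSITY_FEATURES
            )
            out.extend(
                FeatureDescriptor(seq, filt, None, "histogram", n)
                for n in HISTOGRAM_FEATURES
            )
            for family in TEXTURE_FAMILIES:
                for bits in config.texture_bits:
                    out.extend(
                        FeatureDescriptor(seq, filt, bits, family, n)
                        for n in FAMILY_FEATURES[family]
                    )
    return out
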