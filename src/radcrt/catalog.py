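"""The 476-entry radiomics feature catalog.

One case yields 8 shape features (mask only) plus, for each of the 9
component images (the original ``ROI`` and 8 wavelet subbands), 10 histogram
features and 42 texture features (22 GLCM + 11 GLRLM + 9 GLSZM):
``8 + 9 x (10 + 42) = 476``.

Feature ids concatenate the component name and the feature name, with GLCM
features carrying a ``G`` marker after the component (``ROIGCorrelation``)
while histogram, run-length and size-zone features do not (``LLLEnergy``,
``HLLLRE``, ``HHLZP``).
"""

from __future__ import annotations

from dataclasses import dataclass

from .wavelet import COMPONENT_NAMES

__all__ = [
    "SHAPE_FEATURES",
    "HISTOGRAM_FEATURES",
    "GLCM_FEATURES",
    "GLRLM_FEATURES",
    "GLSZM_FEATURES",
    "CatalogEntry",
    "FeatureCatalog",
    "build_catalog",
]

SHAPE_FEATURES = (
    "Volume",
    "SurfaceArea",
    "SurfaceToVolumeRatio",
    "Sphericity",
    "Compactness1",
    "Compactness2",
    "SphericalDisproportion",
    "Max3DDiameter",
)

HISTOGRAM_FEATURES = (
    "Energy",
    "Entropy",
    "Uniformity",
    "Mean",
    "Variance",
    "Skewness",
    "Kurtosis",
    "Min",
    "Max",
    "Range",
)

GLCM_FEATURES = (
    "Autocorrelation",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceEntropy",
    "Dissimilarity",
    "Energy",
    "Entropy",
    "Homogeneity1",
    "Homogeneity2",
    "IMC1",
    "IMC2",
    "IDMN",
    "IDN",
    "InverseVariance",
    "MaxProbability",
    "SumAverage",
    "SumEntropy",
    "SumVariance",
    "Variance",
)

GLRLM_FEATURES = (
    "SRE", "LRE", "GLN", "RLN", "RP",
    "LGRE", "HGRE", "SRLGE", "SRHGE", "LRLGE", "LRHGE",
)

# zone-family gray-level nonuniformity is ZGLN so its id cannot collide with
# the run-length GLN under the shared component prefix
GLSZM_FEATURES = (
    "SZE", "LZE", "ZGLN", "ZSN", "ZP",
    "LGZE", "HGZE", "SZLGE", "SZHGE",
)


@dataclass(frozen=True)
class CatalogEntry:
    feature_id: str
    component: str  # "Shape" or a component image name
    family: str     # shape | histogram | glcm | glrlm | glszm
    name: str


@dataclass(frozen=True)
class FeatureCatalog:
    entries: tuple[CatalogEntry, ...]

    def __post_init__(self) -> None:
        ids = [e.feature_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate feature ids in catalog")
        if len(ids) != 476:
            raise ValueError(f"catalog must contain 476 features, got {len(ids)}")

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(e.feature_id for e in self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in set(self.ids)

    def family(self, family: str) -> tuple[str, ...]:
        return tuple(e.feature_id for e in self.entries if e.family == family)

    def to_records(self) -> list[dict]:
        return [vars(e).copy() for e in self.entries]


def _component_ids(component: str):
    for name in HISTOGRAM_FEATURES:
        yield CatalogEntry(f"{component}{name}", component, "histogram", name)
    for name in GLCM_FEATURES:
        yield CatalogEntry(f"{component}G{name}", component, "glcm", name)
    for name in GLRLM_FEATURES:
        yield CatalogEntry(f"{component}{name}", component, "glrlm", name)
    for name in GLSZM_FEATURES:
        yield CatalogEntry(f"{component}{name}", component, "glszm", name)


def build_catalog() -> FeatureCatalog:
    """The canonical ordered catalog: shape block, then per-component blocks."""
    entries: list[CatalogEntry] = [
        CatalogEntry(f"Shape{name}", "Shape", "shape", name) for name in SHAPE_FEATURES
    ]
    for component in COMPONENT_NAMES:
        entries.extend(_component_ids(component))
    return FeatureCatalog(tuple(entries))
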