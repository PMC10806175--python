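"""End-to-end per-case feature extraction: crop, wavelet, resample, quantize,
and the full 476-feature vector.

Pipeline order (per case): crop to the VOI bounding box with padding, run
the undecimated 3D wavelet on the native-grid crop, then resample every
component image (and the mask, once) to the isotropic target grid, requantize
each component with the fixed bin width anchored at its own in-mask minimum,
and compute shape (once) + histogram + GLCM/GLRLM/GLSZM features per
component.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .catalog import FeatureCatalog, build_catalog
from .features import FeatureVector, histogram_features, shape_features
from .preprocess import (
    CTVolume,
    VOIMask,
    crop_to_voi,
    quantize,
    resample_isotropic,
    resample_like_isotropic,
)
from .texture import (
    build_glcm,
    build_glrlm,
    build_glszm,
    glcm_features,
    glrlm_features,
    glszm_features,
)
from .wavelet import COMPONENT_NAMES, DEFAULT_BASIS, decompose

__all__ = ["ExtractionConfig", "extract_case", "features_to_frame"]


@dataclass(frozen=True)
class ExtractionConfig:
    """Knobs of the extraction pipeline, defaulting to the study protocol:
    2 mm isotropic resampling, 25 HU bin width, single-level undecimated
    wavelet, 8-voxel crop pad, distance-1 co-occurrence offsets."""

    target_spacing: float = 2.0
    bin_width: float = 25.0
    wavelet_basis: str = DEFAULT_BASIS
    pad: int = 8
    glcm_distance: int = 1

    def to_dict(self) -> dict:
        return asdict(self)


def extract_case(
    vol: CTVolume,
    mask: VOIMask,
    config: ExtractionConfig | None = None,
    case_id: str = "case",
    catalog: FeatureCatalog | None = None,
) -> FeatureVector:
    """Compute the full 476-entry feature vector for one case."""
    cfg = config or ExtractionConfig()
    cat = catalog or build_catalog()

    cvol, cmask = crop_to_voi(vol, mask, pad=cfg.pad)
    bank = decompose(cvol, basis=cfg.wavelet_basis)
    rvol, rmask = resample_isotropic(cvol, cmask, target=cfg.target_spacing)

    values: dict[str, float] = {}
    for name, val in shape_features(rmask).items():
        values[f"Shape{name}"] = val

    mask_arr = rmask.flags
    for component in COMPONENT_NAMES:
        if component == "ROI":
            comp_arr = rvol.values
        else:
            comp_arr = resample_like_isotropic(
                bank.components[component], cvol, target=cfg.target_spacing
            )
        comp_vol = CTVolume(comp_arr, rvol.spacing, rvol.origin)
        q = quantize(comp_vol, rmask, bin_width=cfg.bin_width)

        for name, val in histogram_features(comp_arr, mask_arr, q).items():
            values[f"{component}{name}"] = val
        for name, val in glcm_features(build_glcm(q, cfg.glcm_distance)).items():
            values[f"{component}G{name}"] = val
        for name, val in glrlm_features(build_glrlm(q)).items():
            values[f"{component}{name}"] = val
        for name, val in glszm_features(build_glszm(q)).items():
            values[f"{component}{name}"] = val

    missing = set(cat.ids) - set(values)
    if missing:
        raise RuntimeError(f"extraction missed catalog features: {sorted(missing)[:5]}")
    ordered = {fid: float(values[fid]) for fid in cat.ids}
    return FeatureVector(case_id, ordered)


def features_to_frame(vectors: list[FeatureVector],
                      catalog: FeatureCatalog | None = None) -> pd.DataFrame:
    """Stack feature vectors into a case-by-feature table (case_id index)."""
    cat = catalog or build_catalog()
    data = {fv.case_id: [fv.values[i] for i in cat.ids] for fv in vectors}
    frame = pd.DataFrame.from_dict(data, orient="index", columns=list(cat.ids))
    frame.index.name = "case_id"
    return frame
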