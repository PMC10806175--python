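"""First-order (shape, histogram) features and the per-case feature vector.

Shape descriptors are computed once per case from the VOI mask on the
isotropically resampled grid; histogram features are computed from the raw
(continuous) in-mask intensities of each component image, with entropy and
uniformity taken over the fixed-bin-width probability vector of its
quantized counterpart.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist

from .catalog import FeatureCatalog, build_catalog
from .preprocess import EmptyMaskError, QuantizedVolume, VOIMask

__all__ = ["shape_features", "histogram_features", "FeatureVector"]


@dataclass(frozen=True)
class FeatureVector:
    """The named 476-value radiomics profile of one case.

    Missing values (e.g. correlation of a single-gray-level region) are
    carried as NaN flags; they never poison other entries.
    """

    case_id: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        if len(self.values) != 476:
            raise ValueError(
                f"feature vector must have 476 entries, got {len(self.values)}"
            )

    def __getitem__(self, feature_id: str) -> float:
        return self.values[feature_id]

    def as_array(self, catalog: FeatureCatalog | None = None) -> np.ndarray:
        cat = catalog or build_catalog()
        return np.array([self.values[i] for i in cat.ids], dtype=float)


# ---------------------------------------------------------------------------
# Shape
# ---------------------------------------------------------------------------

def _surface_area(flags: np.ndarray, spacing) -> float:
    """Total area of exposed voxel faces (boundary faces included)."""
    area = 0.0
    face = (
        spacing[1] * spacing[2],
        spacing[0] * spacing[2],
        spacing[0] * spacing[1],
    )
    for axis in range(3):
        d = np.diff(flags.astype(np.int8), axis=axis)
        exposed = int(np.abs(d).sum())
        # faces on the array boundary
        first = np.take(flags, 0, axis=axis)
        last = np.take(flags, -1, axis=axis)
        exposed += int(first.sum()) + int(last.sum())
        area += exposed * face[axis]
    return area


def _surface_voxels(flags: np.ndarray) -> np.ndarray:
    """Indices of voxels with at least one exposed face (6-neighborhood)."""
    b = flags.astype(bool)
    interior = b.copy()
    for axis in range(3):
        for shiftdir in (1, -1):
            rolled = np.zeros_like(b)
            src = [slice(None)] * 3
            dst = [slice(None)] * 3
            if shiftdir == 1:
                src[axis], dst[axis] = slice(1, None), slice(0, -1)
            else:
                src[axis], dst[axis] = slice(0, -1), slice(1, None)
            rolled[tuple(dst)] = b[tuple(src)]
            interior &= rolled
    return np.argwhere(b & ~interior)


def _max_diameter(flags: np.ndarray, spacing) -> float:
    pts = _surface_voxels(flags) * np.asarray(spacing, dtype=float)
    if len(pts) == 1:
        return 0.0
    if len(pts) > 4:
        try:
            hull = ConvexHull(pts)
            pts = pts[hull.vertices]
        except Exception:
            pass  # degenerate (coplanar) point sets fall back to all pairs
    return float(pdist(pts).max())


def shape_features(mask: VOIMask, spacing=None) -> dict[str, float]:
    """The 8 size-and-shape descriptors of the VOI.

    ``volume`` is voxel count x voxel volume (mm^3); ``surface_area`` sums
    exposed voxel faces (mm^2); sphericity = pi^(1/3) (6V)^(2/3) / A, equal
    to 1 for a perfect ball and smaller for any other shape.
    """
    sp = tuple(spacing) if spacing is not None else tuple(mask.spacing)
    flags = mask.flags
    if not flags.any():
        raise EmptyMaskError("cannot compute shape features of an empty mask")
    n = int(flags.sum())
    voxel_volume = float(np.prod(sp))
    v = n * voxel_volume
    a = _surface_area(flags, sp)
    sphericity = np.pi ** (1.0 / 3.0) * (6.0 * v) ** (2.0 / 3.0) / a
    r_equiv = (3.0 * v / (4.0 * np.pi)) ** (1.0 / 3.0)
    return {
        "Volume": v,
        "SurfaceArea": a,
        "SurfaceToVolumeRatio": a / v,
        "Sphericity": sphericity,
        "Compactness1": v / (np.sqrt(np.pi) * a ** 1.5),
        "Compactness2": 36.0 * np.pi * v ** 2 / a ** 3,
        "SphericalDisproportion": a / (4.0 * np.pi * r_equiv ** 2),
        "Max3DDiameter": _max_diameter(flags, sp),
    }


# ---------------------------------------------------------------------------
# Histogram
# ---------------------------------------------------------------------------

def histogram_features(values: np.ndarray, mask: np.ndarray,
                       quantized: QuantizedVolume) -> dict[str, float]:
    """The 10 first-order statistics of in-mask intensities.

    Entropy and uniformity are computed over the fixed-bin probability
    vector of ``quantized``; the moments use the raw continuous values
    (population variance, Pearson non-excess kurtosis).  Zero-variance
    regions flag skewness/kurtosis as missing (NaN) rather than erroring.
    """
    m = mask.astype(bool)
    x = np.asarray(values, dtype=float)[m]
    if x.size < 2:
        raise ValueError("histogram features need at least 2 in-mask voxels")
    levels = quantized.levels[m]
    probs = np.bincount(levels, minlength=quantized.n_levels + 1)[1:] / x.size
    pnz = probs[probs > 0]
    mean = float(x.mean())
    var = float(x.var())  # population
    if var > 0:
        sd = np.sqrt(var)
        skew = float(((x - mean) ** 3).mean() / sd ** 3)
        kurt = float(((x - mean) ** 4).mean() / var ** 2)
    else:
        skew = float("nan")
        kurt = float("nan")
    return {
        "Energy": float((x ** 2).sum()),
        "Entropy": float(-(pnz * np.log2(pnz)).sum()),
        "Uniformity": float((pnz ** 2).sum()),
        "Mean": mean,
        "Variance": var,
        "Skewness": skew,
        "Kurtosis": kurt,
        "Min": float(x.min()),
        "Max": float(x.max()),
        "Range": float(x.max() - x.min()),
    }
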