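"""Gray-level co-occurrence, run-length and size-zone matrices and their features.

All three builders operate on a :class:`~radcrt.preprocess.QuantizedVolume`
(levels 1..Ng inside the VOI, 0 outside).  GLCM and GLRLM are computed per
direction over the 13 unique 3D offsets of the 26-neighborhood and their
features are averaged across directions (the matrices themselves are not
pooled); the GLSZM uses 26-connected zones and needs no directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .catalog import GLCM_FEATURES, GLRLM_FEATURES, GLSZM_FEATURES
from .preprocess import QuantizedVolume

__all__ = [
    "DIRECTIONS_13",
    "TextureMatrix",
    "build_glcm",
    "glcm_features",
    "build_glrlm",
    "glrlm_features",
    "build_glszm",
    "glszm_features",
]


def _unique_directions() -> tuple[tuple[int, int, int], ...]:
    dirs = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                d = (dz, dy, dx)
                if d == (0, 0, 0):
                    continue
                if d > (0, 0, 0):  # keep one of each +/- pair
                    dirs.append(d)
    return tuple(dirs)


#: the 13 unique (up to sign) 3D direction vectors, array-axis order (z, y, x)
DIRECTIONS_13 = _unique_directions()


@dataclass(frozen=True)
class TextureMatrix:
    """Raw texture counts plus the metadata needed to normalize them.

    ``counts`` has a leading direction axis for GLCM/GLRLM and none for
    GLSZM.  ``n_voxels`` is the in-mask voxel count (the denominator of run
    percentage / zone percentage).
    """

    kind: str  # GLCM | GLRLM | GLSZM
    counts: np.ndarray
    n_levels: int
    n_voxels: int
    directions: tuple = field(default=())

    def normalized(self) -> np.ndarray:
        """Per-direction probability matrices (sum to 1 where non-empty)."""
        c = self.counts.astype(float)
        if self.kind == "GLSZM":
            total = c.sum()
            return c / total if total > 0 else c
        totals = c.sum(axis=(1, 2), keepdims=True)
        with np.errstate(invalid="ignore"):
            out = np.where(totals > 0, c / np.maximum(totals, 1e-300), 0.0)
        return out


def _shift(a: np.ndarray, d: tuple[int, int, int], fill=0) -> np.ndarray:
    """out[v] = a[v + d] where defined, else fill."""
    out = np.full_like(a, fill)
    src = []
    dst = []
    for n, step in zip(a.shape, d):
        if step >= 0:
            src.append(slice(step, n))
            dst.append(slice(0, n - step))
        else:
            src.append(slice(0, n + step))
            dst.append(slice(-step, n))
    out[tuple(dst)] = a[tuple(src)]
    return out


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def build_glcm(q: QuantizedVolume, distance: int = 1) -> TextureMatrix:
    """Symmetrized co-occurrence counts for each of the 13 directions.

    A pair is counted when both endpoints, ``distance`` steps apart along
    the direction vector, fall inside the mask.
    """
    ng = q.n_levels
    mask = q.mask.astype(bool)
    levels = q.levels
    mats = np.zeros((len(DIRECTIONS_13), ng, ng), dtype=np.int64)
    for k, d in enumerate(DIRECTIONS_13):
        off = tuple(distance * c for c in d)
        nb_levels = _shift(levels, off)
        nb_mask = _shift(mask, off, fill=False)
        valid = mask & nb_mask
        a = levels[valid] - 1
        b = nb_levels[valid] - 1
        if a.size:
            flat = np.bincount(a * ng + b, minlength=ng * ng)
            m = flat.reshape(ng, ng)
            mats[k] = m + m.T  # symmetrize
    return TextureMatrix("GLCM", mats, ng, int(mask.sum()), DIRECTIONS_13)


def _glcm_features_single(p: np.ndarray) -> dict[str, float]:
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    diff = np.abs(ii - jj)

    px = p.sum(axis=1)
    mu = float((i * px).sum())
    sigma2 = float(((i - mu) ** 2 * px).sum())
    sigma = np.sqrt(sigma2)

    nz = p > 0
    entropy = float(-(p[nz] * np.log2(p[nz])).sum())

    # marginal entropies (symmetric matrix: HX == HY)
    pxnz = px[px > 0]
    hx = float(-(pxnz * np.log2(pxnz)).sum())
    with np.errstate(divide="ignore"):
        lpx = np.where(px > 0, np.log2(np.where(px > 0, px, 1.0)), 0.0)
    pipj = np.outer(px, px)
    hxy1 = float(-(p * np.where(pipj > 0, np.log2(np.where(pipj > 0, pipj, 1.0)), 0.0)).sum())
    hxy2 = float(-(pipj[pipj > 0] * np.log2(pipj[pipj > 0])).sum())

    # diagonal and cross-diagonal distributions
    k_sum = np.arange(2, 2 * ng + 1, dtype=float)
    p_sum = np.zeros(2 * ng - 1)
    k_diff = np.arange(0, ng, dtype=float)
    p_diff = np.zeros(ng)
    for d in range(ng):
        p_diff[d] = p[diff == d].sum()
    for s_idx, s in enumerate(range(2, 2 * ng + 1)):
        p_sum[s_idx] = p[(ii + jj) == s].sum()

    sum_avg = float((k_sum * p_sum).sum())
    se_nz = p_sum > 0
    sum_entropy = float(-(p_sum[se_nz] * np.log2(p_sum[se_nz])).sum())
    sum_variance = float(((k_sum - sum_avg) ** 2 * p_sum).sum())
    de_nz = p_diff > 0
    diff_entropy = float(-(p_diff[de_nz] * np.log2(p_diff[de_nz])).sum())

    if sigma > 0:
        correlation = float(((ii * jj * p).sum() - mu * mu) / sigma2)
    else:
        correlation = np.nan
    if hx > 0:
        imc1 = (entropy - hxy1) / hx
    else:
        imc1 = np.nan
    arg = -2.0 * (hxy2 - entropy)
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(arg)))) if hx > 0 else np.nan

    off_diag = diff > 0
    inverse_variance = float((p[off_diag] / diff[off_diag] ** 2).sum())

    return {
        "Autocorrelation": float((ii * jj * p).sum()),
        "ClusterProminence": float(((ii + jj - 2 * mu) ** 4 * p).sum()),
        "ClusterShade": float(((ii + jj - 2 * mu) ** 3 * p).sum()),
        "ClusterTendency": float(((ii + jj - 2 * mu) ** 2 * p).sum()),
        "Contrast": float(((ii - jj) ** 2 * p).sum()),
        "Correlation": correlation,
        "DifferenceEntropy": diff_entropy,
        "Dissimilarity": float((diff * p).sum()),
        "Energy": float((p ** 2).sum()),
        "Entropy": entropy,
        "Homogeneity1": float((p / (1.0 + diff)).sum()),
        "Homogeneity2": float((p / (1.0 + diff ** 2)).sum()),
        "IMC1": imc1,
        "IMC2": imc2,
        "IDMN": float((p / (1.0 + diff ** 2 / ng ** 2)).sum()),
        "IDN": float((p / (1.0 + diff / ng)).sum()),
        "InverseVariance": inverse_variance,
        "MaxProbability": float(p.max()),
        "SumAverage": sum_avg,
        "SumEntropy": sum_entropy,
        "SumVariance": sum_variance,
        "Variance": float(((ii - mu) ** 2 * p).sum()),
    }


def glcm_features(tm: TextureMatrix) -> dict[str, float]:
    """The 22 Haralick-family features, averaged over directions.

    Features undefined for a direction (zero marginal spread) are skipped in
    the average; if undefined everywhere they are reported as NaN (the
    missing-value flag).
    """
    if tm.kind != "GLCM":
        raise ValueError(f"expected a GLCM, got {tm.kind}")
    probs = tm.normalized()
    per_dir = [
        _glcm_features_single(probs[k])
        for k in range(probs.shape[0])
        if probs[k].sum() > 0
    ]
    if not per_dir:
        raise ValueError("GLCM has no co-occurring pair in any direction")
    out = {}
    for name in GLCM_FEATURES:
        vals = np.array([f[name] for f in per_dir], dtype=float)
        finite = vals[np.isfinite(vals)]
        out[name] = float(finite.mean()) if finite.size else float("nan")
    return out


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def build_glrlm(q: QuantizedVolume) -> TextureMatrix:
    """Run-length counts per direction: maximal runs of equal level in-mask."""
    ng = q.n_levels
    mask = q.mask.astype(bool)
    levels = np.where(mask, q.levels, 0)  # 0 can never match a level >= 1
    max_len = int(np.ceil(np.sqrt(sum(n ** 2 for n in levels.shape)))) + 1
    mats = np.zeros((len(DIRECTIONS_13), ng, max_len), dtype=np.int64)
    for k, d in enumerate(DIRECTIONS_13):
        nxt = _shift(levels, d)
        link = mask & (nxt == levels)  # run continues from v to v+d
        # forward match count f[v]: consecutive links starting at v
        f = np.zeros(levels.shape, dtype=np.int32)
        while True:
            f_new = np.where(link, 1 + _shift(f, d), 0)
            if np.array_equal(f_new, f):
                break
            f = f_new
        pred_link = _shift(link, tuple(-c for c in d), fill=False)
        starts = mask & ~pred_link
        run_levels = levels[starts] - 1
        run_lengths = f[starts]  # length - 1
        flat = np.bincount(run_levels * max_len + run_lengths,
                           minlength=ng * max_len)
        mats[k] = flat.reshape(ng, max_len)
    # trim unused tail of the run-length axis (keep at least one column)
    used = max(1, int(np.max(np.nonzero(mats.sum(axis=(0, 1)))[0])) + 1) \
        if mats.any() else 1
    return TextureMatrix("GLRLM", mats[:, :, :used], ng, int(mask.sum()),
                         DIRECTIONS_13)


def _glrlm_features_single(r: np.ndarray, n_voxels: int) -> dict[str, float]:
    nr = r.sum()
    i = np.arange(1, r.shape[0] + 1, dtype=float)[:, None]
    j = np.arange(1, r.shape[1] + 1, dtype=float)[None, :]
    p = r / nr
    r_i = r.sum(axis=1)
    r_j = r.sum(axis=0)
    return {
        "SRE": float((p / j ** 2).sum()),
        "LRE": float((p * j ** 2).sum()),
        "GLN": float((r_i.astype(float) ** 2).sum() / nr),
        "RLN": float((r_j.astype(float) ** 2).sum() / nr),
        "RP": float(nr / n_voxels),
        "LGRE": float((p / i ** 2).sum()),
        "HGRE": float((p * i ** 2).sum()),
        "SRLGE": float((p / (i ** 2 * j ** 2)).sum()),
        "SRHGE": float((p * i ** 2 / j ** 2).sum()),
        "LRLGE": float((p * j ** 2 / i ** 2).sum()),
        "LRHGE": float((p * i ** 2 * j ** 2).sum()),
    }


def glrlm_features(tm: TextureMatrix) -> dict[str, float]:
    """The 11 run-length features averaged over the 13 directions."""
    if tm.kind != "GLRLM":
        raise ValueError(f"expected a GLRLM, got {tm.kind}")
    per_dir = [
        _glrlm_features_single(tm.counts[k].astype(float), tm.n_voxels)
        for k in range(tm.counts.shape[0])
        if tm.counts[k].sum() > 0
    ]
    if not per_dir:
        raise ValueError("GLRLM contains no run in any direction")
    return {
        name: float(np.mean([f[name] for f in per_dir]))
        for name in GLRLM_FEATURES
    }


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def build_glszm(q: QuantizedVolume) -> TextureMatrix:
    """Size-zone counts: 26-connected components of equal level in-mask."""
    ng = q.n_levels
    mask = q.mask.astype(bool)
    n_voxels = int(mask.sum())
    zones: list[tuple[int, int]] = []  # (level, size)
    for g in range(1, ng + 1):
        binary = mask & (q.levels == g)
        if not binary.any():
            continue
        labels, n = ndimage.label(binary, structure=_STRUCT_26)
        sizes = np.bincount(labels.ravel())[1:]
        zones.extend((g, int(s)) for s in sizes)
    max_size = max((s for _, s in zones), default=1)
    mat = np.zeros((ng, max_size), dtype=np.int64)
    for g, s in zones:
        mat[g - 1, s - 1] += 1
    return TextureMatrix("GLSZM", mat, ng, n_voxels)


def glszm_features(tm: TextureMatrix) -> dict[str, float]:
    """The 9 size-zone features (single matrix, no direction average)."""
    if tm.kind != "GLSZM":
        raise ValueError(f"expected a GLSZM, got {tm.kind}")
    z = tm.counts.astype(float)
    nz = z.sum()
    if nz == 0:
        raise ValueError("GLSZM contains no zone")
    g = np.arange(1, z.shape[0] + 1, dtype=float)[:, None]
    s = np.arange(1, z.shape[1] + 1, dtype=float)[None, :]
    p = z / nz
    z_g = z.sum(axis=1)
    z_s = z.sum(axis=0)
    return {
        "SZE": float((p / s ** 2).sum()),
        "LZE": float((p * s ** 2).sum()),
        "ZGLN": float((z_g ** 2).sum() / nz),
        "ZSN": float((z_s ** 2).sum() / nz),
        "ZP": float(nz / tm.n_voxels),
        "LGZE": float((p / g ** 2).sum()),
        "HGZE": float((p * g ** 2).sum()),
        "SZLGE": float((p / (g ** 2 * s ** 2)).sum()),
        "SZHGE": float((p * g ** 2 / s ** 2).sum()),
    }
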