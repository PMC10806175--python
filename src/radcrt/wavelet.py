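"""Single-level undecimated 3D wavelet decomposition into 8 subbands.

The transform is stationary (no downsampling), so every subband stays on the
input grid and in register with the VOI mask — a requirement for extracting
masked features from each component.  It is implemented as a separable
convolution with the low/high analysis filter pair of a PyWavelets basis,
with symmetric boundary extension.

Component names follow the ``(x-filter, y-filter, z-filter)`` convention:
``LLH`` means low-pass along x and y, high-pass along z.  Together with the
unfiltered original (named ``ROI``) the decomposition yields the 9 component
images that the feature extractor consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy.ndimage import correlate1d

from .preprocess import CTVolume

__all__ = ["WaveletBank", "SUBBAND_NAMES", "COMPONENT_NAMES", "decompose"]

#: the 8 subband names, x-filter first
SUBBAND_NAMES = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")

#: all 9 component images, original first
COMPONENT_NAMES = ("ROI",) + SUBBAND_NAMES

DEFAULT_BASIS = "coif1"


@dataclass(frozen=True)
class WaveletBank:
    """The original volume plus its 8 stationary wavelet subbands."""

    components: dict[str, np.ndarray]
    basis_name: str

    def __post_init__(self) -> None:
        if set(self.components) != set(COMPONENT_NAMES):
            raise ValueError(f"expected components {COMPONENT_NAMES}, "
                             f"got {sorted(self.components)}")
        shapes = {v.shape for v in self.components.values()}
        if len(shapes) != 1:
            raise ValueError(f"components on mismatched grids: {shapes}")


def _filter_axis(values: np.ndarray, kernel: np.ndarray, axis: int) -> np.ndarray:
    # scipy 'reflect' is half-sample symmetric extension (d c b a | a b c d)
    return correlate1d(values, kernel, axis=axis, mode="reflect")


def decompose(vol: CTVolume, basis: str = DEFAULT_BASIS) -> WaveletBank:
    """Decompose a volume into its 8 undecimated level-1 subbands.

    Parameters
    ----------
    vol : CTVolume
        Input volume; every axis must be at least as long as the analysis
        filter of ``basis``.
    basis : str
        Any PyWavelets discrete wavelet name (default Coiflet-1; Haar is
        convenient for hand-checkable tests).
    """
    w = pywt.Wavelet(basis)
    lo = np.asarray(w.dec_lo, dtype=float)
    hi = np.asarray(w.dec_hi, dtype=float)
    if min(vol.shape) < len(lo):
        raise ValueError(
            f"volume shape {vol.shape} smaller than the {basis} filter "
            f"support ({len(lo)}) along some axis"
        )
    kernels = {"L": lo, "H": hi}
    # array axes are (z, y, x); subband names are (x, y, z) so name[0]
    # filters array axis 2, name[2] filters array axis 0
    components: dict[str, np.ndarray] = {"ROI": vol.values.astype(float).copy()}
    for name in SUBBAND_NAMES:
        out = vol.values.astype(float)
        for axis_char, axis in zip(name, (2, 1, 0)):
            out = _filter_axis(out, kernels[axis_char], axis)
        components[name] = out
    return WaveletBank(components, basis)
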