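"""Single-level stationary (undecimated) 3D wavelet filter bank.

Each of the eight sub-bands is the separable application of the analysis
low-pass (L) or high-pass (H) filter along x, y, z according to its label
(``"HLL"`` = high-pass along x, low-pass along y and z).  The transform is
undecimated, so every sub-band lives on the input grid and the original
tumor mask applies to all of them.

Filtering convention: along one axis with analysis filter ``h`` of length
``L_f``, output sample ``n`` is the discrete convolution

    y[n] = sum_k h[k] * x[n + c - k],   c = L_f - 1 - L_f // 2,

with symmetric (half-sample reflect) boundary extension.  This places the
kernel centre on the output voxel, so the LLL band of a constant image is
constant and the transform is shift-covariant away from boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import ndimage

from .exceptions import ImageTooSmall
from .image import VolumeImage

__all__ = ["SUBBANDS", "WaveletBank", "decompose"]

#: Canonical sub-band order; axis order of the letters is (x, y, z).
SUBBANDS = ("HHH", "HHL", "HLH", "HLL", "LHH", "LHL", "LLH", "LLL")


@dataclass(frozen=True)
class WaveletBank:
    """Analysis filter bank: a Coiflet family by default, single level.

    ``mode`` is the scipy.ndimage boundary name; ``"reflect"`` is the
    half-sample symmetric extension usual for image filter banks.
    """

    family: str = "coif1"
    mode: str = "reflect"

    @property
    def filters(self) -> dict[str, np.ndarray]:
        w = pywt.Wavelet(self.family)
        return {"L": np.asarray(w.dec_lo), "H": np.asarray(w.dec_hi)}

    @property
    def filter_length(self) -> int:
        return len(pywt.Wavelet(self.family).dec_lo)


def _filter_axis(values: np.ndarray, h: np.ndarray, axis: int, mode: str) -> np.ndarray:
    # correlate1d with the reversed filter realizes the stated convolution.
    return ndimage.correlate1d(values, h[::-1], axis=axis, mode=mode, output=np.float64)


def decompose(image: VolumeImage, bank: WaveletBank | None = None) -> dict[str, VolumeImage]:
    """Decompose a volume into its eight stationary wavelet sub-bands.

    Returns a dict keyed by sub-band label, each value a :class:`VolumeImage`
    with the same shape, spacing, and modality as the input.

    Raises
    ------
    ImageTooSmall
        If any image axis is shorter than the analysis filter.
    """
    bank = bank or WaveletBank()
    filters = bank.filters
    L_f = bank.filter_length
    if any(n < L_f for n in image.shape):
        raise ImageTooSmall(
            f"image shape {image.shape} has an axis shorter than the "
            f"{bank.family} filter (length {L_f})"
        )
    # Factor the separable filtering: filter along x once per x-letter, reuse.
    out: dict[str, VolumeImage] = {}
    for lx in "HL":
        vx = _filter_axis(image.values, filters[lx], 0, bank.mode)
        for ly in "HL":
            vxy = _filter_axis(vx, filters[ly], 1, bank.mode)
            for lz in "HL":
                vxyz = _filter_axis(vxy, filters[lz], 2, bank.mode)
                out[lx + ly + lz] = image.with_values(vxyz)
    return {label: out[label] for label in SUBBANDS}
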