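"""ROI gray-level quantization and the five texture matrix families.

Quantization follows the fixed-bin-count rule over the mu +/- 3 sigma range
of the in-ROI intensities (population SD): values are clipped to that range
and binned into ``N_g = 2**bits`` equal-width bins,

    level = min(N_g, 1 + floor(N_g * (v - lo) / (hi - lo))),

so levels run 1..N_g inside the ROI and 0 outside.  A constant ROI
(sigma = 0) maps every voxel to level 1.

Matrix conventions (IBSI 3D, merged aggregation):

* GLCM — co-occurrences at Chebyshev distance 1 over the 13 unique 3D
  direction vectors, both voxels in-ROI, all directions merged into one
  matrix, symmetrized, normalized to unit mass.
* GLRLM — maximal same-level runs along each of the 13 directions, confined
  to in-ROI voxels, merged into one (level x run-length) matrix.
* GLSZM — 26-connected zones of equal level within the ROI (direction-free).
* NGLDM — per in-ROI voxel, the dependence k = number of its in-ROI
  26-neighbours whose level differs by <= alpha (alpha = 0); matrix indexed
  by (level, k + 1).
* NGTDM — per level i, ``s_i`` = summed absolute difference between i and
  the mean level of the in-ROI 26-neighbourhood, over in-ROI voxels of
  level i that have at least one in-ROI neighbour; ``n_i`` counts those
  voxels.  Stored as an (N_g, 2) table with columns (s_i, n_i).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.measure import label as _cc_label

from .exceptions import EmptyRoi
from .image import RoiMask, VolumeImage

__all__ = [
    "QuantizedRoi",
    "GrayLevelMatrix",
    "DIRECTIONS_13",
    "quantize_roi",
    "quantize_values",
    "glcm",
    "glrlm",
    "glszm",
    "ngldm",
    "ngtdm",
]

#: The 13 unique direction vectors of the 3D Chebyshev-1 neighbourhood
#: (one representative per +/- pair, lexicographically positive).
DIRECTIONS_13 = tuple(
    d
    for d in (
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
    )
    if d > (0, 0, 0)
)
assert len(DIRECTIONS_13) == 13


@dataclass
class QuantizedRoi:
    """Integer level array (0 outside the ROI, 1..n_levels inside)."""

    levels: np.ndarray
    n_levels: int
    mask: RoiMask

    @property
    def in_roi_levels(self) -> np.ndarray:
        return self.levels[self.mask.values]

    # the matrix builders all work on the ROI bounding box and share shifted
    # copies of it; both are cached because five families reuse them
    @property
    def bbox_levels(self) -> np.ndarray:
        cached = getattr(self, "_bbox", None)
        if cached is None:
            idx = np.argwhere(self.mask.values)
            lo = idx.min(axis=0)
            hi = idx.max(axis=0) + 1
            cached = self.levels[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
            object.__setattr__(self, "_bbox", cached)
        return cached

    def shifted(self, d) -> np.ndarray:
        cache = getattr(self, "_shift_cache", None)
        if cache is None:
            cache = {}
            object.__setattr__(self, "_shift_cache", cache)
        if d not in cache:
            cache[d] = _shift(self.bbox_levels, d)
        return cache[d]


@dataclass
class GrayLevelMatrix:
    """One texture matrix: family tag, the table, and how it was aggregated."""

    family: str
    table: np.ndarray
    aggregation: str = ""
    n_levels: int = 0
    n_voxels: int = 0  # in-ROI voxel count of the source ROI

    @property
    def is_all_zero(self) -> bool:
        return not np.any(self.table)


def quantize_values(values: np.ndarray, bits: int) -> np.ndarray:
    """Quantize a 1D array of in-ROI intensities to levels 1..2**bits."""
    if not 4 <= bits <= 8:
        # the study grid is 4-8 bit, but the rule itself is generic; only
        # guard against nonsense
        if bits < 1:
            raise ValueError("bits must be >= 1")
    n_g = 2**bits
    mu = float(values.mean())
    sigma = float(values.std())  # population SD
    # sigma of a constant array can land at ~1e-16 through round-off; treat
    # anything below relative double precision as the degenerate case
    if sigma <= 1e-13 * max(1.0, abs(mu)):
        return np.ones(values.shape, dtype=np.int64)
    lo, hi = mu - 3.0 * sigma, mu + 3.0 * sigma
    clipped = np.clip(values, lo, hi)
    lev = 1 + np.floor(n_g * (clipped - lo) / (hi - lo)).astype(np.int64)
    return np.minimum(lev, n_g)


def quantize_roi(image: VolumeImage, mask: RoiMask, bits: int) -> QuantizedRoi:
    """Quantize the in-ROI intensities of ``image`` to ``2**bits`` levels."""
    if mask.is_empty:
        raise EmptyRoi("cannot quantize an empty ROI")
    levels = np.zeros(image.shape, dtype=np.int64)
    levels[mask.values] = quantize_values(image.values[mask.values], bits)
    return QuantizedRoi(levels, 2**bits, mask)


# ---------------------------------------------------------------------------
# helpers


def _shift(arr: np.ndarray, d, fill=0) -> np.ndarray:
    """Shift so that out[p] = arr[p + d], zero-filled at the faces."""
    out = np.full_like(arr, fill)
    src = tuple(
        slice(max(di, 0), arr.shape[k] + min(di, 0)) for k, di in enumerate(d)
    )
    dst = tuple(
        slice(max(-di, 0), arr.shape[k] + min(-di, 0)) for k, di in enumerate(d)
    )
    out[dst] = arr[src]
    return out


def _warn_degenerate(family: str) -> None:
    warnings.warn(
        f"{family}: ROI too small to form any entry; features of this "
        "family will be reported as 0",
        stacklevel=3,
    )


# ---------------------------------------------------------------------------
# matrix builders


def glcm(q: QuantizedRoi, directions=DIRECTIONS_13) -> GrayLevelMatrix:
    """Merged-direction, symmetrized, normalized co-occurrence matrix.

    ``directions`` can restrict the offsets (default: all 13)."""
    lev = q.bbox_levels
    n_g = q.n_levels
    counts = np.zeros((n_g, n_g), dtype=np.int64)
    for d in directions:
        nb = q.shifted(tuple(d))
        ok = (lev > 0) & (nb > 0)
        if ok.any():
            np.add.at(counts, (lev[ok] - 1, nb[ok] - 1), 1)
    counts = counts + counts.T  # count (i,j) and (j,i)
    total = counts.sum()
    if total == 0:
        _warn_degenerate("GLCM")
        table = counts.astype(np.float64)
    else:
        table = counts / total
    return GrayLevelMatrix("GLCM", table, "merged-13-dirs symmetric", n_g, q.mask.n_voxels)


def glrlm(q: QuantizedRoi, directions=DIRECTIONS_13) -> GrayLevelMatrix:
    """Merged-direction run-length matrix (level x run length, counts).

    ``directions`` can restrict the scan directions (default: all 13)."""
    lev = q.bbox_levels
    n_g = q.n_levels
    max_len = max(lev.shape)
    # chain counting: N_k[i] = number of length-k same-level chains of level
    # i along d; runs of length exactly l then satisfy
    # R[i, l] = N_l - 2*N_{l+1} + N_{l+2}.
    counts = np.zeros((n_g, max_len), dtype=np.int64)
    for d in directions:
        chain = lev > 0  # chain starts of length k (k = 1 initially)
        n_k = []
        k = 1
        while chain.any():
            n_k.append(np.bincount(lev[chain], minlength=n_g + 1)[1:])
            nb = _shift(lev, tuple(k * di for di in d))
            chain = chain & (nb == lev) & (nb > 0)
            k += 1
        n_k.append(np.zeros(n_g, dtype=np.int64))
        n_k.append(np.zeros(n_g, dtype=np.int64))
        n_k = np.asarray(n_k)
        exact = n_k[:-2] - 2 * n_k[1:-1] + n_k[2:]
        counts[:, : exact.shape[0]] += exact.T
    if counts.sum() == 0:
        _warn_degenerate("GLRLM")
    return GrayLevelMatrix("GLRLM", counts, "merged-13-dirs", n_g, q.mask.n_voxels)


def glszm(q: QuantizedRoi) -> GrayLevelMatrix:
    """Size-zone matrix: 26-connected equal-level zones (level x size, counts)."""
    lev = q.bbox_levels
    n_g = q.n_levels
    labels, n_zones = _cc_label(lev, background=0, connectivity=3, return_num=True)
    if n_zones == 0:
        _warn_degenerate("GLSZM")
        return GrayLevelMatrix("GLSZM", np.zeros((n_g, 1), dtype=np.int64), "26-conn", n_g, q.mask.n_voxels)
    flat_lab = labels.ravel()
    sizes = np.bincount(flat_lab, minlength=n_zones + 1)[1:]
    zone_level = np.zeros(n_zones + 1, dtype=np.int64)
    zone_level[flat_lab] = lev.ravel()  # all voxels of a zone share the level
    counts = np.zeros((n_g, int(sizes.max())), dtype=np.int64)
    np.add.at(counts, (zone_level[1:] - 1, sizes - 1), 1)
    return GrayLevelMatrix("GLSZM", counts, "26-conn", n_g, q.mask.n_voxels)


def ngldm(q: QuantizedRoi) -> GrayLevelMatrix:
    """Dependence matrix: (level, k+1) counts, k = equal-level 26-neighbours."""
    lev = q.bbox_levels
    n_g = q.n_levels
    in_roi = lev > 0
    k = np.zeros(lev.shape, dtype=np.int64)
    for d in DIRECTIONS_13:
        for dv in (d, tuple(-x for x in d)):
            nb = q.shifted(dv)
            k += ((nb > 0) & (nb == lev) & in_roi).astype(np.int64)
    counts = np.zeros((n_g, 27), dtype=np.int64)
    np.add.at(counts, (lev[in_roi] - 1, k[in_roi]), 1)
    return GrayLevelMatrix("NGLDM", counts, "26-neigh alpha=0", n_g, q.mask.n_voxels)


def ngtdm(q: QuantizedRoi) -> GrayLevelMatrix:
    """Gray-tone difference table: columns (s_i, n_i), rows = levels."""
    lev = q.bbox_levels
    n_g = q.n_levels
    in_roi = lev > 0
    nb_sum = np.zeros(lev.shape, dtype=np.float64)
    nb_cnt = np.zeros(lev.shape, dtype=np.int64)
    for d in DIRECTIONS_13:
        for dv in (d, tuple(-x for x in d)):
            nb = q.shifted(dv)
            has = nb > 0
            nb_sum += np.where(has, nb, 0)
            nb_cnt += has.astype(np.int64)
    valid = in_roi & (nb_cnt > 0)
    table = np.zeros((n_g, 2), dtype=np.float64)
    if valid.any():
        diff = np.abs(lev[valid] - nb_sum[valid] / nb_cnt[valid])
        li = lev[valid] - 1
        np.add.at(table[:, 0], li, diff)
        np.add.at(table[:, 1], li, 1)
    else:
        _warn_degenerate("NGTDM")
    return GrayLevelMatrix("NGTDM", table, "26-neigh", n_g, q.mask.n_voxels)
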