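"""IBSI-style scalar features computed from the five gray-level matrices.

All logarithms are base 2.  Division guards: marginal distributions with a
single support point give zero variances; NGTDM coarseness uses
``1 / (eps + sum p_i s_i)`` with ``eps = 1e-12`` so that perfectly uniform
ROIs stay finite.  A matrix with no entries (single-voxel ROI) yields all
features equal to 0 (the builder has already warned).
"""

from __future__ import annotations

import numpy as np

from .registry import (
    FAMILY_FEATURES,
    GLCM_FEATURES,
    GLRLM_FEATURES,
    GLSZM_FEATURES,
    NGLDM_FEATURES,
    NGTDM_FEATURES,
)
from .texture import GrayLevelMatrix

__all__ = ["matrix_features"]

_EPS = 1e-12


def _log2(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = np.log2(p[nz])
    return out


def _glcm_features(table: np.ndarray) -> dict[str, float]:
    p = table
    n_g = p.shape[0]
    i = np.arange(1, n_g + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    p_i = p.sum(axis=1)  # symmetric: row marginal = column marginal
    mu = float((ii * p).sum())
    sd = float(np.sqrt(((i - float((i * p_i).sum())) ** 2 * p_i).sum()))
    corr_num = float((ii * jj * p).sum()) - float((i * p_i).sum()) ** 2
    correlation = 1.0 if sd == 0.0 else corr_num / (sd * sd)
    return {
        "joint_maximum": float(p.max()),
        "joint_average": mu,
        "joint_variance": float(((ii - mu) ** 2 * p).sum()),
        "joint_entropy": float(-(p * _log2(p)).sum()),
        "angular_second_moment": float((p**2).sum()),
        "contrast": float(((ii - jj) ** 2 * p).sum()),
        "dissimilarity": float((np.abs(ii - jj) * p).sum()),
        "inverse_difference": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "inverse_difference_moment": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "correlation": correlation,
        "autocorrelation": float((ii * jj * p).sum()),
    }


def _rl_style(counts: np.ndarray, n_voxels: int, n_dirs: int, names: dict) -> dict[str, float]:
    """Shared run-length / size-zone machinery.

    ``counts[i-1, l-1]`` counts runs (zones) of level i and length (size) l.
    ``names`` maps generic keys to the family's feature names.
    """
    n_s = counts.sum()
    i = np.arange(1, counts.shape[0] + 1, dtype=np.float64)
    l = np.arange(1, counts.shape[1] + 1, dtype=np.float64)
    r_i = counts.sum(axis=1).astype(np.float64)
    r_l = counts.sum(axis=0).astype(np.float64)
    p = counts / n_s
    p_i = r_i / n_s
    p_l = r_l / n_s
    mu_i = float((i * p_i).sum())
    mu_l = float((l * p_l).sum())
    ii = i[:, None]
    ll = l[None, :]
    out = {
        names["se"]: float((r_l / l**2).sum() / n_s),
        names["le"]: float((r_l * l**2).sum() / n_s),
        names["gln"]: float((r_i**2).sum() / n_s),
        names["glnn"]: float((r_i**2).sum() / n_s**2),
        names["ln"]: float((r_l**2).sum() / n_s),
        names["lnn"]: float((r_l**2).sum() / n_s**2),
        names["pct"]: n_s / (n_voxels * n_dirs),
        names["lgle"]: float((r_i / i**2).sum() / n_s),
        names["hgle"]: float((r_i * i**2).sum() / n_s),
        names["glv"]: float(((i - mu_i) ** 2 * p_i).sum()),
        names["lv"]: float(((l - mu_l) ** 2 * p_l).sum()),
    }
    extras = {
        "slge": float((counts / (ii**2 * ll**2)).sum() / n_s),
        "shge": float((counts * ii**2 / ll**2).sum() / n_s),
        "szhge": float((counts * ii**2 / ll**2).sum() / n_s),
        "entropy": float(-(p * _log2(p)).sum()),
    }
    for k, name in names.get("extras", {}).items():
        out[name] = extras[k]
    return out


def _glrlm_features(m: GrayLevelMatrix) -> dict[str, float]:
    names = {
        "se": "short_run_emphasis",
        "le": "long_run_emphasis",
        "gln": "gray_level_non_uniformity",
        "glnn": "gray_level_non_uniformity_normalized",
        "ln": "run_length_non_uniformity",
        "lnn": "run_length_non_uniformity_normalized",
        "pct": "run_percentage",
        "lgle": "low_gray_level_run_emphasis",
        "hgle": "high_gray_level_run_emphasis",
        "glv": "gray_level_variance",
        "lv": "run_length_variance",
        "extras": {
            "slge": "short_run_low_gray_level_emphasis",
            "shge": "short_run_high_gray_level_emphasis",
        },
    }
    out = _rl_style(m.table, m.n_voxels, 13, names)
    return {k: out[k] for k in GLRLM_FEATURES}


def _glszm_features(m: GrayLevelMatrix) -> dict[str, float]:
    names = {
        "se": "small_zone_emphasis",
        "le": "large_zone_emphasis",
        "gln": "gray_level_non_uniformity",
        "glnn": "gray_level_non_uniformity_normalized",
        "ln": "zone_size_non_uniformity",
        "lnn": "zone_size_non_uniformity_normalized",
        "pct": "zone_percentage",
        "lgle": "low_gray_level_zone_emphasis",
        "hgle": "high_gray_level_zone_emphasis",
        "glv": "gray_level_variance",
        "lv": "zone_size_variance",
        "extras": {
            "szhge": "small_zone_high_gray_level_emphasis",
            "entropy": "zone_size_entropy",
        },
    }
    out = _rl_style(m.table, m.n_voxels, 1, names)
    return {k: out[k] for k in GLSZM_FEATURES}


def _ngldm_features(m: GrayLevelMatrix) -> dict[str, float]:
    counts = m.table.astype(np.float64)
    n = counts.sum()
    i = np.arange(1, counts.shape[0] + 1, dtype=np.float64)
    j = np.arange(1, counts.shape[1] + 1, dtype=np.float64)  # j = k + 1
    r_i = counts.sum(axis=1)
    c_j = counts.sum(axis=0)
    p = counts / n
    p_i = r_i / n
    p_j = c_j / n
    mu_i = float((i * p_i).sum())
    mu_j = float((j * p_j).sum())
    ii = i[:, None]
    jj = j[None, :]
    return {
        "low_dependence_emphasis": float((c_j / j**2).sum() / n),
        "high_dependence_emphasis": float((c_j * j**2).sum() / n),
        "low_gray_level_count_emphasis": float((r_i / i**2).sum() / n),
        "high_gray_level_count_emphasis": float((r_i * i**2).sum() / n),
        "low_dependence_low_gray_level_emphasis": float((counts / (ii**2 * jj**2)).sum() / n),
        "low_dependence_high_gray_level_emphasis": float((counts * ii**2 / jj**2).sum() / n),
        "high_dependence_low_gray_level_emphasis": float((counts * jj**2 / ii**2).sum() / n),
        "high_dependence_high_gray_level_emphasis": float((counts * ii**2 * jj**2).sum() / n),
        "gray_level_non_uniformity": float((r_i**2).sum() / n),
        "gray_level_non_uniformity_normalized": float((r_i**2).sum() / n**2),
        "dependence_count_non_uniformity": float((c_j**2).sum() / n),
        "dependence_count_non_uniformity_normalized": float((c_j**2).sum() / n**2),
        "dependence_count_percentage": float(n / m.n_voxels),
        "gray_level_variance": float(((i - mu_i) ** 2 * p_i).sum()),
        "dependence_count_variance": float(((j - mu_j) ** 2 * p_j).sum()),
        "dependence_count_entropy": float(-(p * _log2(p)).sum()),
    }


def _ngtdm_features(m: GrayLevelMatrix) -> dict[str, float]:
    s = m.table[:, 0]
    n_i = m.table[:, 1]
    n = n_i.sum()
    p = n_i / n
    present = p > 0
    i = np.arange(1, len(s) + 1, dtype=np.float64)
    n_gp = int(present.sum())
    ip = i[present]
    pp = p[present]
    sp = s[present]
    ps = float((pp * sp).sum())
    coarseness = 1.0 / (_EPS + ps)
    if n_gp > 1:
        di2 = (ip[:, None] - ip[None, :]) ** 2
        pij = pp[:, None] * pp[None, :]
        contrast = float((pij * di2).sum()) / (n_gp * (n_gp - 1)) * float(sp.sum()) / n
        denom = float(np.abs(ip[:, None] * pp[:, None] - ip[None, :] * pp[None, :]).sum())
        busyness = 0.0 if denom == 0.0 else ps / denom
        num = np.abs(ip[:, None] - ip[None, :]) * (
            pp[:, None] * sp[:, None] + pp[None, :] * sp[None, :]
        ) / (pp[:, None] + pp[None, :])
        complexity = float(num.sum()) / n
        strength = float(((pp[:, None] + pp[None, :]) * di2).sum()) / (_EPS + float(sp.sum()))
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "coarseness": coarseness,
        "contrast": contrast,
        "busyness": busyness,
        "complexity": complexity,
        "strength": strength,
    }


_DISPATCH = {
    "GLCM": lambda m: _glcm_features(m.table),
    "GLRLM": _glrlm_features,
    "GLSZM": _glszm_features,
    "NGLDM": _ngldm_features,
    "NGTDM": _ngtdm_features,
}


def matrix_features(m: GrayLevelMatrix) -> dict[str, float]:
    """Compute the registered scalar features for one gray-level matrix.

    Returns exactly the registry's feature set for the matrix family, in
    registry order.  An all-zero matrix yields all-zero features.
    """
    names = FAMILY_FEATURES[m.family]
    if m.is_all_zero:
        return {n: 0.0 for n in names}
    feats = _DISPATCH[m.family](m)
    assert tuple(feats) == names or set(feats) == set(names)
    return {n: float(feats[n]) for n in names}
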