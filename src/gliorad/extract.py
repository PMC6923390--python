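"""Per-subject feature extraction and the subjects x features table.

``extract_subject`` assumes a preprocessed subject (Z-scored, isotropic,
mask aligned); ``preprocess_subject`` brings a raw subject there (resample
first, then normalize, so the normalization statistics refer to the
analysis grid).  Quantization statistics (mu, sigma) are recomputed per
filtered image, since wavelet sub-band value ranges differ from the
original image's.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .firstorder import histogram_features, intensity_features, shape_features
from .image import RoiMask, VolumeImage, load_mask, load_volume
from .phantom import PhantomSubject
from .preprocess import resample_image_isotropic, resample_mask_isotropic, zscore_normalize
from .registry import FeatureDescriptor, SpaceConfig, enumerate_feature_space
from .texture import glcm, glrlm, glszm, ngldm, ngtdm, quantize_roi
from .texture_features import matrix_features
from .wavelet import WaveletBank, decompose

log = logging.getLogger(__name__)

__all__ = ["ExtractionConfig", "FeatureTable", "preprocess_subject", "extract_subject", "build_feature_table"]

_BUILDERS = {"GLCM": glcm, "GLRLM": glrlm, "GLSZM": glszm, "NGLDM": ngldm, "NGTDM": ngtdm}


@dataclass(frozen=True)
class ExtractionConfig:
    """Feature-space slice plus filtering options."""

    space: SpaceConfig = field(default_factory=SpaceConfig)
    wavelet: WaveletBank = field(default_factory=WaveletBank)
    target_spacing_mm: float = 1.0

    def descriptors(self) -> list[FeatureDescriptor]:
        return enumerate_feature_space(self.space)


def desk_extraction_config() -> ExtractionConfig:
    """Reduced slice of the feature space used for fast end-to-end studies:
    three image versions (orig, LLL, HHH) and two quantization levels."""
    return ExtractionConfig(
        space=SpaceConfig(filters=("orig", "LLL", "HHH"), texture_bits=(4, 8))
    )


@dataclass
class FeatureTable:
    """Subjects x features value matrix with grade labels and cohort tags."""

    subject_ids: list[str]
    grades: np.ndarray  # array of "III"/"IV"
    cohorts: list[str]
    descriptors: list[FeatureDescriptor]
    values: np.ndarray  # (n_subjects, n_features) float64

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        assert self.values.shape == (len(self.subject_ids), len(self.descriptors))

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def labels(self) -> np.ndarray:
        """Binary labels with grade IV positive."""
        return (np.asarray(self.grades) == "IV").astype(np.int64)

    def subset_rows(self, idx) -> "FeatureTable":
        idx = np.asarray(idx)
        return FeatureTable(
            [self.subject_ids[i] for i in idx],
            np.asarray(self.grades)[idx],
            [self.cohorts[i] for i in idx],
            self.descriptors,
            self.values[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=[str(d) for d in self.descriptors])
        df.insert(0, "cohort", self.cohorts)
        df.insert(0, "grade", self.grades)
        df.insert(0, "subject_id", self.subject_ids)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        df = pd.read_csv(path)
        meta = ["subject_id", "grade", "cohort"]
        desc = [FeatureDescriptor.parse(c) for c in df.columns if c not in meta]
        return cls(
            df["subject_id"].astype(str).tolist(),
            df["grade"].to_numpy(dtype=object),
            df["cohort"].astype(str).tolist(),
            desc,
            df.drop(columns=meta).to_numpy(dtype=np.float64),
        )


def preprocess_subject(subject: PhantomSubject, config: ExtractionConfig | None = None) -> PhantomSubject:
    """Resample everything to the isotropic analysis grid, then Z-score."""
    config = config or ExtractionConfig()
    t = config.target_spacing_mm
    brain = resample_mask_isotropic(subject.brain_mask, t)
    tumor = resample_mask_isotropic(subject.tumor_mask, t)
    out = {}
    for name, img in (("ce_t1", subject.ce_t1), ("t2", subject.t2)):
        iso = resample_image_isotropic(img, t) if img.spacing != (t, t, t) else img
        out[name] = zscore_normalize(iso, brain) if iso.normalization != "zscored" else iso
    return PhantomSubject(subject.subject_id, subject.grade, out["ce_t1"], out["t2"], tumor, brain)


def _texture_block(image: VolumeImage, mask: RoiMask, bits_list, families) -> dict[tuple, dict]:
    out = {}
    for bits in bits_list:
        q = quantize_roi(image, mask, bits)
        for family in families:
            out[(family, bits)] = matrix_features(_BUILDERS[family](q))
    return out


def extract_subject(subject: PhantomSubject, config: ExtractionConfig | None = None) -> np.ndarray:
    """One finite value per enumerated descriptor, in enumeration order."""
    config = config or ExtractionConfig()
    space = config.space
    descriptors = config.descriptors()

    values: dict[str, float] = {}
    if space.include_shape:
        for name, v in shape_features(subject.tumor_mask).items():
            values[str(FeatureDescriptor("mask", "orig", None, "shape", name))] = v

    images = {"CE-T1": subject.ce_t1, "T2": subject.t2}
    need_wavelet = any(f != "orig" for f in space.filters)
    tex_families = sorted({d.family for d in descriptors if d.quant_bits is not None})
    for seq in space.sequences:
        base = images[seq]
        versions = {"orig": base}
        if need_wavelet:
            versions.update(decompose(base, config.wavelet))
        for filt in space.filters:
            img = versions[filt]
            for name, v in intensity_features(img, subject.tumor_mask).items():
                values[str(FeatureDescriptor(seq, filt, None, "intensity", name))] = v
            for name, v in histogram_features(img, subject.tumor_mask, space.histogram_bits).items():
                values[str(FeatureDescriptor(seq, filt, None, "histogram", name))] = v
            block = _texture_block(img, subject.tumor_mask, space.texture_bits, tex_families)
            for (family, bits), feats in block.items():
                for name, v in feats.items():
                    values[str(FeatureDescriptor(seq, filt, bits, family, name))] = v

    row = np.array([values[str(d)] for d in descriptors], dtype=np.float64)
    if not np.all(np.isfinite(row)):
        bad = [str(d) for d, v in zip(descriptors, row) if not np.isfinite(v)]
        raise ValueError(f"non-finite features for {subject.subject_id}: {bad[:5]}")
    return row


def _load_subject(row) -> PhantomSubject:
    try:
        return PhantomSubject(
            subject_id=str(row["subject_id"]),
            grade=str(row["grade"]),
            ce_t1=load_volume(row["ce_t1_path"], "CE-T1"),
            t2=load_volume(row["t2_path"], "T2"),
            tumor_mask=load_mask(row["tumor_mask_path"]),
            brain_mask=load_mask(row["brain_mask_path"]),
        )
    except Exception as e:
        raise OSError(f"cannot load subject {row.get('subject_id', '?')}: {e}") from e


def build_feature_table(
    source,
    config: ExtractionConfig | None = None,
    csv_out=None,
    preprocess: bool = True,
) -> FeatureTable:
    """Extract the feature matrix for a cohort.

    ``source`` is either a manifest CSV path (as written by
    :func:`gliorad.phantom.write_cohort`) or a list of
    :class:`PhantomSubject` objects.
    """
    config = config or ExtractionConfig()
    if isinstance(source, (str, Path)):
        manifest = pd.read_csv(source)
        subjects = [_load_subject(r) for _, r in manifest.iterrows()]
    else:
        subjects = list(source)
    descriptors = config.descriptors()
    rows, ids, grades, cohorts = [], [], [], []
    for s in subjects:
        t0 = time.perf_counter()
        if preprocess:
            s = preprocess_subject(s, config)
        rows.append(extract_subject(s, config))
        log.info("extracted %s (%d features, %.2fs)", s.subject_id, len(descriptors), time.perf_counter() - t0)
        ids.append(s.subject_id)
        grades.append(s.grade)
        cohorts.append(s.subject_id.rsplit("-", 1)[0])
    table = FeatureTable(ids, np.asarray(grades, dtype=object), cohorts, descriptors, np.vstack(rows))
    if csv_out is not None:
        table.to_csv(csv_out)
    return table
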