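"""Full feature extraction: 107 original + 744 wavelet features.

Column names follow ``<filter>_<class>_<name>`` where filter is
``original`` or ``wavelet-<subband>``; shape features exist only for the
original filter, while first-order and the five texture classes are
recomputed (with re-discretisation) on every wavelet sub-band.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

from ..types import LesionSample
from . import formulas
from .discretize import DiscretizationConfig, discretize
from .matrices import glcm, gldm, glrlm, glszm, ngtdm
from .shape import shape_features
from .wavelet import SUBBAND_NAMES, swt3

__all__ = [
    "FeatureName",
    "ExtractionConfig",
    "extract_all",
    "build_feature_table",
    "EXTRACTOR_REGISTRY",
    "TEXTURE_CLASSES",
    "ALL_CLASSES",
]

TEXTURE_CLASSES = ("glcm", "glrlm", "glszm", "gldm", "ngtdm")
ALL_CLASSES = ("shape", "firstorder") + TEXTURE_CLASSES


@dataclass(frozen=True)
class FeatureName:
    """Parsed provenance of one feature column."""

    image_filter: str  # "original" | "wavelet-XXX"
    feature_class: str
    name: str

    def __post_init__(self) -> None:
        if self.feature_class == "shape" and self.image_filter != "original":
            raise ValueError("shape features only pair with the original filter")

    def __str__(self) -> str:
        return f"{self.image_filter}_{self.feature_class}_{self.name}"

    @classmethod
    def parse(cls, column: str) -> "FeatureName":
        image_filter, feature_class, name = column.split("_", 2)
        return cls(image_filter, feature_class, name)


@dataclass
class ExtractionConfig:
    """Knobs of one extractor slot."""

    discretization: DiscretizationConfig = field(default_factory=DiscretizationConfig)
    wavelet: bool = True
    glcm_distance: int = 1
    gldm_alpha: int = 0
    classes: tuple[str, ...] = ALL_CLASSES

    def __post_init__(self) -> None:
        unknown = set(self.classes) - set(ALL_CLASSES)
        if unknown:
            raise ValueError(f"unknown feature classes: {sorted(unknown)}")


def _filter_features(
    data: np.ndarray,
    mask: np.ndarray,
    voxel_volume: float,
    config: ExtractionConfig,
) -> dict[str, dict[str, float]]:
    """First-order + texture features of one (possibly filtered) image."""
    out: dict[str, dict[str, float]] = {}
    values = data[mask]
    if "firstorder" in config.classes:
        bw = (
            config.discretization.bin_width
            if config.discretization.mode == "fixed_bin_width"
            else max((values.max() - values.min()), 1e-12) / config.discretization.bin_count
        )
        out["firstorder"] = formulas.firstorder_features(values, voxel_volume, bw)
    needed = [c for c in TEXTURE_CLASSES if c in config.classes]
    if needed:
        levels, ng = discretize(data, mask, config.discretization)
        n_vox = float(mask.sum())
        if "glcm" in needed:
            out["glcm"] = formulas.glcm_features(
                glcm(levels, mask, ng, config.glcm_distance)
            )
        if "glrlm" in needed:
            out["glrlm"] = formulas.glrlm_features(glrlm(levels, mask, ng), n_vox)
        if "glszm" in needed:
            out["glszm"] = formulas.glszm_features(glszm(levels, mask, ng), n_vox)
        if "gldm" in needed:
            out["gldm"] = formulas.gldm_features(
                gldm(levels, mask, ng, config.gldm_alpha), n_vox
            )
        if "ngtdm" in needed:
            n, p, s = ngtdm(levels, mask, ng)
            out["ngtdm"] = formulas.ngtdm_features(n, p, s)
    return out


def extract_all(sample: LesionSample, config: ExtractionConfig | None = None) -> pd.Series:
    """Extract every configured feature from one (preprocessed) sample.

    With the default config the result has 851 entries: 107 on the
    original image (14 shape + 93 intensity/texture) and 93 on each of
    the 8 wavelet sub-bands.  Any failure inside a feature computation
    propagates; features are never silently dropped.
    """
    config = config or ExtractionConfig()
    data = sample.volume.data
    mask = sample.mask.data
    vv = sample.volume.voxel_volume_mm3
    names: list[str] = []
    values: list[float] = []

    if "shape" in config.classes:
        for k, v in shape_features(mask, sample.volume.spacing).items():
            names.append(f"original_shape_{k}")
            values.append(v)
    for cls_name, feats in _filter_features(data, mask, vv, config).items():
        for k, v in feats.items():
            names.append(f"original_{cls_name}_{k}")
            values.append(v)
    if config.wavelet:
        bands = swt3(data)
        for band_name in SUBBAND_NAMES:
            for cls_name, feats in _filter_features(
                bands[band_name], mask, vv, config
            ).items():
                for k, v in feats.items():
                    names.append(f"wavelet-{band_name}_{cls_name}_{k}")
                    values.append(v)
    series = pd.Series(values, index=names, dtype=np.float64, name=sample.subject_id)
    if series.isna().any():
        bad = series.index[series.isna()].tolist()
        raise FloatingPointError(f"non-finite feature values: {bad}")
    return series


def build_feature_table(
    samples: Iterable[LesionSample], config: ExtractionConfig | None = None
) -> pd.DataFrame:
    """Extract a cohort into a samples x features table (index = subject id)."""
    rows = []
    ids = []
    for s in samples:
        rows.append(extract_all(s, config))
        ids.append(s.subject_id)
    table = pd.DataFrame(rows)
    table.index = pd.Index(ids, name="subject_id")
    return table


def _registry() -> dict[str, ExtractionConfig]:
    """Seven radiomics extractor slots obtained by parameter variation.

    The study design combines seven extractors; with learned-feature
    extractors out of scope the slots are filled by discretisation /
    filter variants of the radiomics extractor (user plugins may replace
    any slot).
    """
    base = ExtractionConfig()
    return {
        "radiomics": base,
        "radiomics-bw10": replace(
            base, discretization=DiscretizationConfig(bin_width=10.0)
        ),
        "radiomics-bw40": replace(
            base, discretization=DiscretizationConfig(bin_width=40.0)
        ),
        "radiomics-fbc16": replace(
            base,
            discretization=DiscretizationConfig(mode="fixed_bin_count", bin_count=16),
        ),
        "radiomics-fbc32": replace(
            base,
            discretization=DiscretizationConfig(mode="fixed_bin_count", bin_count=32),
        ),
        "radiomics-nowavelet": replace(base, wavelet=False),
        "radiomics-d2": replace(base, glcm_distance=2),
    }


EXTRACTOR_REGISTRY: dict[str, ExtractionConfig] = _registry()
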