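"""Per-image feature extraction: 21 texture descriptors + 4 chaotic indices.

Glues segmentation to the two feature families and assembles the 25-column
feature table consumed by selection and classification.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .chaos import CHAOS_FEATURE_NAMES, EmbeddingConfig, roi_chaos_features
from .preprocess import ThermalImage
from .segmentation import FCMConfig, segment_image
from .texture import GLCMConfig, TEXTURE_FEATURE_NAMES, roi_texture_features

__all__ = [
    "ALL_FEATURE_NAMES",
    "extract_features",
    "feature_table",
    "TEXTURE_FEATURE_NAMES",
    "CHAOS_FEATURE_NAMES",
]

ALL_FEATURE_NAMES = tuple(TEXTURE_FEATURE_NAMES) + tuple(CHAOS_FEATURE_NAMES)


def extract_features(img: ThermalImage,
                     fcm: FCMConfig = FCMConfig(),
                     glcm: GLCMConfig = GLCMConfig(),
                     emb: EmbeddingConfig = EmbeddingConfig(dim=3, delay=2)) -> dict[str, float]:
    """Segment one thermogram and compute its 25 features.

    The embedding defaults here fix (dim, delay) = (3, 2) rather than the
    per-series automatic choice: a common embedding makes the Lyapunov /
    correlation-dimension columns comparable across images (and an order of
    magnitude faster over a cohort).  Pass ``EmbeddingConfig()`` for fully
    automatic selection.
    """
    seg = segment_image(img, fcm)
    out = dict(roi_texture_features(img.pixels, seg.roi_mask, glcm))
    out.update(roi_chaos_features(img.pixels, seg.roi_mask, seg.binary_image, emb))
    return out


def feature_table(images: list[ThermalImage], **kwargs) -> pd.DataFrame:
    """Feature rows for a cohort, indexed by image id."""
    rows = {img.id: extract_features(img, **kwargs) for img in images}
    return pd.DataFrame.from_dict(rows, orient="index")[list(ALL_FEATURE_NAMES)]
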