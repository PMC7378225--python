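"""Masked texture-feature extraction for single images and whole cohorts.

One call produces the 25-element feature vector (13 GLCM + 7 GLRLM + 5 GLDM)
of a masked grey-scale image, using G = 16 grey levels and unit pixel
distance by default.  Cohort extraction walks a manifest and returns a tidy
table with columns ``glcm_*``, ``glrlm_*`` and ``gldm_*``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .gldm import GLDM_FEATURE_NAMES, gldm_features
from .glcm import GLCM_FEATURE_NAMES, glcm_features
from .glrlm import GLRLM_FEATURE_NAMES, glrlm_features
from .preprocessing import quantize

__all__ = ["TEXTURE_COLUMNS", "extract_texture_features", "extract_cohort_features"]

TEXTURE_COLUMNS = (
    [f"glcm_{n}" for n in GLCM_FEATURE_NAMES]
    + [f"glrlm_{n}" for n in GLRLM_FEATURE_NAMES]
    + [f"gldm_{n}" for n in GLDM_FEATURE_NAMES]
)


def extract_texture_features(
    image: np.ndarray,
    mask: np.ndarray,
    G: int = 16,
    d: int = 1,
    glcm_average: str = "features",
) -> dict[str, float]:
    """All 25 texture features of one masked image, as a flat named dict."""
    roi = quantize(image, mask, G=G)
    out = {}
    for name, value in glcm_features(roi, d=d, average=glcm_average).items():
        out[f"glcm_{name}"] = value
    for name, value in glrlm_features(roi).items():
        out[f"glrlm_{name}"] = value
    for name, value in gldm_features(roi, d=d).items():
        out[f"gldm_{name}"] = value
    return out


def extract_cohort_features(
    manifest: pd.DataFrame,
    base_dir: str | Path,
    G: int = 16,
    d: int = 1,
) -> pd.DataFrame:
    """Texture features for every patient in a cohort manifest.

    ``image_path``/``mask_path`` are resolved relative to ``base_dir``.
    Returns one row per patient: ``id`` plus the 25 texture columns.
    """
    from .io import read_image, read_mask

    base = Path(base_dir)
    rows = []
    for rec in manifest.itertuples(index=False):
        image = read_image(base / rec.image_path)
        mask = read_mask(base / rec.mask_path)
        rows.append({"id": rec.id, **extract_texture_features(image, mask, G=G, d=d)})
    return pd.DataFrame(rows, columns=["id"] + TEXTURE_COLUMNS)
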