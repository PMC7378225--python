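"""Raster and manifest I/O helpers."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["read_image", "read_mask", "read_manifest"]


def read_image(path: str | Path) -> np.ndarray:
    """Read a single-channel raster image (PNG/TIFF, 8- or 16-bit) as a 2D array."""
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(Path(path)))
    if arr.ndim == 3:  # collapse an accidental channel axis
        arr = arr[..., 0]
    return arr


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask raster; any nonzero pixel is inside the ROI."""
    return read_image(path) > 0


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest CSV."""
    return pd.read_csv(Path(path))
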