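"""Mask-aware grey-level quantization and voxel-based volume computation.

Texture matrices are computed on a small number of grey levels (G = 16 by
default) to suppress noise in the co-occurrence statistics.  Quantization is
done per region of interest: the in-mask intensity range [min, max] is split
into G equal-width bins and levels are 1-based, so run-emphasis formulas that
divide by the squared level are always well defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["QuantizedROI", "quantize", "volume_from_mask", "volume_from_nifti"]

#: value carried by pixels outside the mask in a :class:`QuantizedROI`
OUTSIDE_SENTINEL = 0


@dataclass(frozen=True)
class QuantizedROI:
    """A 2D image reduced to ``G`` grey levels inside a binary mask.

    ``levels`` holds integers in ``{1..G}`` inside the mask and
    ``OUTSIDE_SENTINEL`` (0) outside.  ``source_range`` records the in-mask
    (min, max) intensities used for binning.
    """

    levels: np.ndarray
    mask: np.ndarray
    G: int
    source_range: tuple[float, float]

    @property
    def n_pixels(self) -> int:
        """Number of in-mask pixels."""
        return int(self.mask.sum())


def quantize(image: np.ndarray, mask: np.ndarray, G: int = 16) -> QuantizedROI:
    """Uniformly quantize the in-mask intensities of ``image`` to ``G`` levels.

    Bin edges span the in-mask [min, max]; the maximum maps to level ``G`` and
    a constant region maps entirely to level 1.  Quantization is therefore
    invariant to affine rescaling of the in-mask intensities and monotone in
    the original grey values.

    Parameters
    ----------
    image : 2D array of intensities (any numeric dtype).
    mask : 2D boolean (or 0/1) array of the same shape; True selects the ROI.
    G : number of grey levels, at least 2.

    Returns
    -------
    QuantizedROI
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if image.shape != mask.shape:
        raise ValueError(
            f"image shape {image.shape} and mask shape {mask.shape} differ"
        )
    if image.ndim != 2:
        raise ValueError("quantize expects 2D arrays (single axial slice)")
    if G < 2:
        raise ValueError(f"G must be >= 2, got {G}")
    n_in = int(mask.sum())
    if n_in == 0:
        raise ValueError("mask is empty: no pixels to quantize")
    if n_in < G:
        warnings.warn(
            f"ROI has only {n_in} pixels for G={G} grey levels; "
            "texture statistics will be unstable",
            UserWarning,
            stacklevel=2,
        )

    vals = image[mask]
    lo, hi = float(vals.min()), float(vals.max())
    levels = np.full(image.shape, OUTSIDE_SENTINEL, dtype=np.int64)
    if hi == lo:
        levels[mask] = 1
    else:
        binned = np.floor((vals - lo) / (hi - lo) * G).astype(np.int64) + 1
        np.clip(binned, 1, G, out=binned)
        levels[mask] = binned
    return QuantizedROI(levels=levels, mask=mask, G=G, source_range=(lo, hi))


def volume_from_mask(mask3d: np.ndarray, spacing: tuple[float, float, float]) -> float:
    """Volume of a binary 3D mask in cubic centimetres.

    ``spacing`` gives the per-axis voxel size in millimetres; the result is
    (voxel count) x (voxel volume in mm^3) / 1000.
    """
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be positive on all three axes, got {spacing}")
    mask3d = np.asarray(mask3d).astype(bool)
    voxel_mm3 = spacing[0] * spacing[1] * spacing[2]
    return float(mask3d.sum()) * voxel_mm3 / 1000.0


def volume_from_nifti(path) -> float:
    """Volume in cc of a binary mask stored as a NIfTI file (spacing from the header)."""
    import nibabel as nib

    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    data = np.asanyarray(img.dataobj)
    return volume_from_mask(data > 0, spacing)
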