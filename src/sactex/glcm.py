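"""Grey-level co-occurrence matrix (GLCM) and the 13 Haralick features.

The GLCM estimates the second-order joint probability of observing grey
levels (i, j) at two pixels separated by a displacement of length ``d`` along
angle ``theta``.  Pairs are counted in both orders, so the matrix is
symmetric, and pairs with either pixel outside the mask are skipped.  The
sac texture is treated as isotropic: each feature is computed per direction
(0, 45, 90, 135 degrees) and averaged.

Feature definitions follow the classical Haralick set: angular second moment
(energy), contrast (inertia), correlation, entropy, inverse difference
moment, sum average/variance/entropy, difference average/variance/entropy
and the two information measures of correlation.  Logarithms are base 2 with
the convention 0*log(0) = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocessing import QuantizedROI

__all__ = [
    "CooccurrenceMatrix",
    "GLCM_ANGLES",
    "GLCM_FEATURE_NAMES",
    "glcm_matrix",
    "glcm_features",
]

#: the four standard in-plane directions, degrees
GLCM_ANGLES = (0, 45, 90, 135)

#: fixed output order of the 13 features
GLCM_FEATURE_NAMES = (
    "energy",
    "contrast",
    "correlation",
    "entropy",
    "inverse_difference_moment",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "difference_average",
    "difference_variance",
    "difference_entropy",
    "imc1",
    "imc2",
)

# (row, col) unit offsets; rows grow downwards so 45 deg points up-right
_ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


class NoValidPairsError(ValueError):
    """Raised when the ROI contains no in-mask pixel pair at the displacement."""


@dataclass(frozen=True)
class CooccurrenceMatrix:
    """Symmetric normalized co-occurrence matrix for one (d, theta)."""

    P: np.ndarray
    d: int
    theta: int
    n_pairs: int  # ordered pair count before normalization


def _offset(d: int, theta: int) -> tuple[int, int]:
    if theta not in _ANGLE_OFFSETS:
        raise ValueError(f"theta must be one of {GLCM_ANGLES}, got {theta}")
    if d < 1:
        raise ValueError(f"distance d must be >= 1, got {d}")
    dr, dc = _ANGLE_OFFSETS[theta]
    return dr * d, dc * d


def _pair_counts(roi: QuantizedROI, dr: int, dc: int) -> np.ndarray:
    """Count in-mask level pairs at displacement (dr, dc), one order only."""
    lv, mk, G = roi.levels, roi.mask, roi.G
    H, W = lv.shape
    counts = np.zeros((G, G), dtype=np.int64)
    r0a, r1a = max(0, -dr), H - max(0, dr)
    c0a, c1a = max(0, -dc), W - max(0, dc)
    if r1a <= r0a or c1a <= c0a:
        return counts
    a = lv[r0a:r1a, c0a:c1a]
    b = lv[r0a + dr:r1a + dr, c0a + dc:c1a + dc]
    valid = mk[r0a:r1a, c0a:c1a] & mk[r0a + dr:r1a + dr, c0a + dc:c1a + dc]
    np.add.at(counts, (a[valid] - 1, b[valid] - 1), 1)
    return counts


def glcm_matrix(roi: QuantizedROI, d: int = 1, theta: int = 0) -> CooccurrenceMatrix:
    """Symmetric, normalized co-occurrence matrix of ``roi`` at (d, theta).

    Raises :class:`NoValidPairsError` when no in-mask pair exists at the
    requested displacement (distinct from an empty mask, which is refused at
    quantization time).
    """
    dr, dc = _offset(d, theta)
    counts = _pair_counts(roi, dr, dc)
    counts = counts + counts.T  # both orders -> symmetric
    total = int(counts.sum())
    if total == 0:
        raise NoValidPairsError(
            f"no in-mask pixel pair at d={d}, theta={theta} deg"
        )
    return CooccurrenceMatrix(P=counts / total, d=d, theta=theta, n_pairs=total)


def _xlog2(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def haralick_features(P: np.ndarray) -> dict[str, float]:
    """The 13 Haralick features of one normalized symmetric GLCM."""
    G = P.shape[0]
    i = np.arange(1, G + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    py = P.sum(axis=0)

    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    sig_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))
    sig_y = float(np.sqrt(((i - mu_y) ** 2 * py).sum()))

    energy = float((P**2).sum())
    contrast = float(((ii - jj) ** 2 * P).sum())
    if sig_x * sig_y == 0.0:
        correlation = 0.0  # constant ROI: zero-variance marginal
    else:
        correlation = float(((ii * jj * P).sum() - mu_x * mu_y) / (sig_x * sig_y))
    entropy = float(-_xlog2(P).sum())
    idm = float((P / (1.0 + (ii - jj) ** 2)).sum())

    # p_{x+y}(k), k = 2..2G and p_{|x-y|}(k), k = 0..G-1
    ksum = (ii + jj).astype(int).ravel()
    p_sum = np.bincount(ksum, weights=P.ravel(), minlength=2 * G + 1)[2:]
    kdiff = np.abs(ii - jj).astype(int).ravel()
    p_diff = np.bincount(kdiff, weights=P.ravel(), minlength=G)

    k_sum = np.arange(2, 2 * G + 1, dtype=float)
    k_diff = np.arange(0, G, dtype=float)
    sum_average = float((k_sum * p_sum).sum())
    sum_variance = float(((k_sum - sum_average) ** 2 * p_sum).sum())
    sum_entropy = float(-_xlog2(p_sum).sum())
    difference_average = float((k_diff * p_diff).sum())
    difference_variance = float(((k_diff - difference_average) ** 2 * p_diff).sum())
    difference_entropy = float(-_xlog2(p_diff).sum())

    hx = float(-_xlog2(px).sum())
    hy = float(-_xlog2(py).sum())
    pxy = np.outer(px, py)
    nz = P > 0
    hxy1 = float(-(P[nz] * np.log2(pxy[nz])).sum())
    hxy2 = float(-_xlog2(pxy).sum())
    denom = max(hx, hy)
    imc1 = 0.0 if denom == 0.0 else float((entropy - hxy1) / denom)
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    return {
        "energy": energy,
        "contrast": contrast,
        "correlation": correlation,
        "entropy": entropy,
        "inverse_difference_moment": idm,
        "sum_average": sum_average,
        "sum_variance": sum_variance,
        "sum_entropy": sum_entropy,
        "difference_average": difference_average,
        "difference_variance": difference_variance,
        "difference_entropy": difference_entropy,
        "imc1": imc1,
        "imc2": imc2,
    }


def glcm_features(
    roi: QuantizedROI,
    d: int = 1,
    angles: tuple[int, ...] = GLCM_ANGLES,
    average: str = "features",
) -> dict[str, float]:
    """Direction-averaged Haralick features.

    ``average="features"`` (default) computes the 13 features per direction
    and averages them; ``average="matrices"`` averages the four co-occurrence
    matrices first and evaluates the features once on the mean matrix.
    Directions with no valid pair raise; see :func:`glcm_matrix`.
    """
    mats = [glcm_matrix(roi, d=d, theta=t).P for t in angles]
    if average == "matrices":
        return haralick_features(np.mean(mats, axis=0))
    if average != "features":
        raise ValueError(f"average must be 'features' or 'matrices', got {average!r}")
    per_dir = [haralick_features(P) for P in mats]
    return {
        name: float(np.mean([f[name] for f in per_dir])) for name in GLCM_FEATURE_NAMES
    }
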