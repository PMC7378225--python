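"""Grey-level difference method (GLDM) histogram and its 5 features.

For a displacement delta, the method histograms the absolute grey-level
difference k = |level(x) - level(x + delta)| over every in-mask pixel whose
delta-neighbour is also in-mask, then summarises the normalized histogram
p_delta(k), k = 0..G-1, with contrast, angular second moment, entropy, mean
and an inverse difference moment (denominator k^2 + 1 so k = 0 is defined).
Features are averaged over the four displacements (0,d), (d,0), (d,d),
(d,-d), mirroring the isotropy convention of the other texture matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocessing import QuantizedROI

__all__ = [
    "DifferenceHistogram",
    "GLDM_FEATURE_NAMES",
    "gldm_displacements",
    "gldm_histogram",
    "gldm_features",
]

GLDM_FEATURE_NAMES = (
    "contrast",
    "angular_second_moment",
    "entropy",
    "mean",
    "inverse_difference_moment",
)


class NoValidPairsError(ValueError):
    """No in-mask pixel pair exists at the requested displacement."""


@dataclass(frozen=True)
class DifferenceHistogram:
    pdelta: np.ndarray  # probabilities over k = 0..G-1
    delta: tuple[int, int]
    n_pairs: int


def gldm_displacements(d: int = 1) -> tuple[tuple[int, int], ...]:
    """The four (row, col) displacements used for isotropic averaging."""
    return ((0, d), (d, 0), (d, d), (d, -d))


def gldm_histogram(roi: QuantizedROI, delta: tuple[int, int]) -> DifferenceHistogram:
    """Normalized absolute grey-level difference histogram at ``delta``."""
    dr, dc = int(delta[0]), int(delta[1])
    lv, mk, G = roi.levels, roi.mask, roi.G
    H, W = lv.shape
    r0a, r1a = max(0, -dr), H - max(0, dr)
    c0a, c1a = max(0, -dc), W - max(0, dc)
    hist = np.zeros(G, dtype=np.int64)
    if r1a > r0a and c1a > c0a:
        a = lv[r0a:r1a, c0a:c1a]
        b = lv[r0a + dr:r1a + dr, c0a + dc:c1a + dc]
        valid = mk[r0a:r1a, c0a:c1a] & mk[r0a + dr:r1a + dr, c0a + dc:c1a + dc]
        diffs = np.abs(a[valid] - b[valid])
        hist = np.bincount(diffs, minlength=G)[:G]
    total = int(hist.sum())
    if total == 0:
        raise NoValidPairsError(f"no in-mask pixel pair at delta={(dr, dc)}")
    return DifferenceHistogram(pdelta=hist / total, delta=(dr, dc), n_pairs=total)


def difference_features(hist: DifferenceHistogram) -> dict[str, float]:
    """The five GLDM features of one displacement's histogram."""
    p = hist.pdelta
    k = np.arange(p.size, dtype=float)
    nz = p > 0
    entropy = float(-(p[nz] * np.log2(p[nz])).sum())
    return {
        "contrast": float((k**2 * p).sum()),
        "angular_second_moment": float((p**2).sum()),
        "entropy": entropy,
        "mean": float((k * p).sum()),
        "inverse_difference_moment": float((p / (k**2 + 1.0)).sum()),
    }


def gldm_features(roi: QuantizedROI, d: int = 1) -> dict[str, float]:
    """GLDM features averaged over the four displacements of scale ``d``."""
    per_delta = [
        difference_features(gldm_histogram(roi, delta))
        for delta in gldm_displacements(d)
    ]
    return {
        name: float(np.mean([f[name] for f in per_delta]))
        for name in GLDM_FEATURE_NAMES
    }
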