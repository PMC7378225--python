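"""Grey-level run-length matrix (GLRLM) and the 7 Galloway features.

Entry R(i, j) counts the maximal runs of grey level i with length j along a
direction.  Runs never cross the mask boundary: a masked-out pixel ends the
current run, so every in-mask pixel belongs to exactly one run per direction
and sum_ij j * R(i, j) equals the in-mask pixel count.

Features use the classical conventions: short/long run emphasis, grey-level
and run-length nonuniformity, run percentage and low/high grey-level run
emphasis, each averaged over the four in-plane directions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocessing import QuantizedROI

__all__ = [
    "RunLengthMatrix",
    "GLRLM_ANGLES",
    "GLRLM_FEATURE_NAMES",
    "glrlm_matrix",
    "glrlm_features",
]

GLRLM_ANGLES = (0, 45, 90, 135)

GLRLM_FEATURE_NAMES = (
    "short_run_emphasis",
    "long_run_emphasis",
    "grey_level_nonuniformity",
    "run_percentage",
    "run_length_nonuniformity",
    "low_grey_level_run_emphasis",
    "high_grey_level_run_emphasis",
)


@dataclass(frozen=True)
class RunLengthMatrix:
    """Run counts R[i-1, j-1] for grey level i and run length j along theta."""

    R: np.ndarray
    theta: int
    Nr: int  # total number of runs
    Np: int  # number of in-mask pixels


def _lines(levels: np.ndarray, mask: np.ndarray, theta: int):
    """Yield (levels, mask) 1D lines of the image along direction theta."""
    H, W = levels.shape
    if theta == 0:
        for r in range(H):
            yield levels[r], mask[r]
    elif theta == 90:
        for c in range(W):
            yield levels[:, c], mask[:, c]
    elif theta == 135:  # down-right diagonals
        for off in range(-(H - 1), W):
            yield levels.diagonal(off), mask.diagonal(off)
    elif theta == 45:  # up-right anti-diagonals
        fl_lv, fl_mk = np.fliplr(levels), np.fliplr(mask)
        for off in range(-(H - 1), W):
            yield fl_lv.diagonal(off), fl_mk.diagonal(off)
    else:
        raise ValueError(f"theta must be one of {GLRLM_ANGLES}, got {theta}")


def _runs_in_line(lv: np.ndarray, mk: np.ndarray):
    """Run-length encode the in-mask stretches of one line.

    Yields (level, length) pairs; runs break where the mask is False or the
    level changes.
    """
    n = lv.size
    if n == 0:
        return
    # a new run starts wherever the level changes or the mask toggles
    change = np.ones(n, dtype=bool)
    change[1:] = (lv[1:] != lv[:-1]) | (mk[1:] != mk[:-1])
    starts = np.flatnonzero(change)
    ends = np.append(starts[1:], n)
    for s, e in zip(starts, ends):
        if mk[s]:
            yield int(lv[s]), int(e - s)


def glrlm_matrix(roi: QuantizedROI, theta: int = 0) -> RunLengthMatrix:
    """Run-length matrix of ``roi`` along ``theta`` (degrees)."""
    lv, mk, G = roi.levels, roi.mask, roi.G
    if not mk.any():
        raise ValueError("mask is empty")
    lmax = max(lv.shape)
    R = np.zeros((G, lmax), dtype=np.int64)
    for line_lv, line_mk in _lines(lv, mk, theta):
        for level, length in _runs_in_line(np.asarray(line_lv), np.asarray(line_mk)):
            R[level - 1, length - 1] += 1
    return RunLengthMatrix(R=R, theta=theta, Nr=int(R.sum()), Np=roi.n_pixels)


def run_features(rlm: RunLengthMatrix) -> dict[str, float]:
    """The 7 run-length features of one direction's matrix."""
    R = rlm.R.astype(float)
    Nr, Np = float(rlm.Nr), float(rlm.Np)
    G, lmax = R.shape
    j2 = np.arange(1, lmax + 1, dtype=float) ** 2
    i2 = np.arange(1, G + 1, dtype=float) ** 2
    return {
        "short_run_emphasis": float((R / j2).sum() / Nr),
        "long_run_emphasis": float((R * j2).sum() / Nr),
        "grey_level_nonuniformity": float((R.sum(axis=1) ** 2).sum() / Nr),
        "run_percentage": float(Nr / Np),
        "run_length_nonuniformity": float((R.sum(axis=0) ** 2).sum() / Nr),
        "low_grey_level_run_emphasis": float((R / i2[:, None]).sum() / Nr),
        "high_grey_level_run_emphasis": float((R * i2[:, None]).sum() / Nr),
    }


def glrlm_features(
    roi: QuantizedROI, angles: tuple[int, ...] = GLRLM_ANGLES
) -> dict[str, float]:
    """Run-length features averaged over the four directions."""
    per_dir = [run_features(glrlm_matrix(roi, theta=t)) for t in angles]
    return {
        name: float(np.mean([f[name] for f in per_dir]))
        for name in GLRLM_FEATURE_NAMES
    }
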