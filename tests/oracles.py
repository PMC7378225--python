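"""Independent brute-force oracles for the texture matrices and ROC metrics.

Everything here is written as plain nested loops over pixels/pairs, with the
feature formulas evaluated directly from their definitions, so the oracles
share no code path with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np

_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def brute_quantize(image, mask, G):
    """Reference quantization: equal-width bins over the in-mask min..max."""
    vals = [image[r][c] for r in range(len(image)) for c in range(len(image[0])) if mask[r][c]]
    lo, hi = min(vals), max(vals)
    out = np.zeros((len(image), len(image[0])), dtype=int)
    for r in range(len(image)):
        for c in range(len(image[0])):
            if mask[r][c]:
                if hi == lo:
                    out[r][c] = 1
                else:
                    b = int(math.floor((image[r][c] - lo) / (hi - lo) * G)) + 1
                    out[r][c] = min(max(b, 1), G)
    return out


def brute_glcm(levels, mask, G, d, theta):
    """Symmetric normalized co-occurrence matrix by explicit pair loops."""
    dr, dc = _OFFSETS[theta]
    dr, dc = dr * d, dc * d
    H, W = levels.shape
    counts = np.zeros((G, G))
    for r in range(H):
        for c in range(W):
            if not mask[r][c]:
                continue
            for sr, sc in ((dr, dc), (-dr, -dc)):
                r2, c2 = r + sr, c + sc
                if 0 <= r2 < H and 0 <= c2 < W and mask[r2][c2]:
                    counts[levels[r][c] - 1][levels[r2][c2] - 1] += 1
    total = counts.sum()
    return counts / total if total else counts


def _entropy2(p):
    return -sum(x * math.log2(x) for x in np.ravel(p) if x > 0)


def brute_haralick(P):
    """The 13 Haralick features evaluated term by term from the definitions."""
    G = P.shape[0]
    px = [sum(P[i][j] for j in range(G)) for i in range(G)]
    py = [sum(P[i][j] for i in range(G)) for j in range(G)]
    mu_x = sum((i + 1) * px[i] for i in range(G))
    mu_y = sum((j + 1) * py[j] for j in range(G))
    sig_x = math.sqrt(sum((i + 1 - mu_x) ** 2 * px[i] for i in range(G)))
    sig_y = math.sqrt(sum((j + 1 - mu_y) ** 2 * py[j] for j in range(G)))

    energy = sum(P[i][j] ** 2 for i in range(G) for j in range(G))
    contrast = sum((i - j) ** 2 * P[i][j] for i in range(G) for j in range(G))
    if sig_x * sig_y == 0:
        correlation = 0.0
    else:
        correlation = (
            sum((i + 1) * (j + 1) * P[i][j] for i in range(G) for j in range(G))
            - mu_x * mu_y
        ) / (sig_x * sig_y)
    entropy = _entropy2(P)
    idm = sum(P[i][j] / (1 + (i - j) ** 2) for i in range(G) for j in range(G))

    p_sum = {k: 0.0 for k in range(2, 2 * G + 1)}
    p_diff = {k: 0.0 for k in range(G)}
    for i in range(G):
        for j in range(G):
            p_sum[i + j + 2] += P[i][j]
            p_diff[abs(i - j)] += P[i][j]
    sum_average = sum(k * v for k, v in p_sum.items())
    sum_variance = sum((k - sum_average) ** 2 * v for k, v in p_sum.items())
    sum_entropy = _entropy2(list(p_sum.values()))
    diff_average = sum(k * v for k, v in p_diff.items())
    diff_variance = sum((k - diff_average) ** 2 * v for k, v in p_diff.items())
    diff_entropy = _entropy2(list(p_diff.values()))

    hx, hy = _entropy2(px), _entropy2(py)
    hxy1 = -sum(
        P[i][j] * math.log2(px[i] * py[j])
        for i in range(G)
        for j in range(G)
        if P[i][j] > 0
    )
    hxy2 = -sum(
        px[i] * py[j] * math.log2(px[i] * py[j])
        for i in range(G)
        for j in range(G)
        if px[i] * py[j] > 0
    )
    imc1 = 0.0 if max(hx, hy) == 0 else (entropy - hxy1) / max(hx, hy)
    imc2 = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - entropy))))
    return {
        "energy": energy,
        "contrast": contrast,
        "correlation": correlation,
        "entropy": entropy,
        "inverse_difference_moment": idm,
        "sum_average": sum_average,
        "sum_variance": sum_variance,
        "sum_entropy": sum_entropy,
        "difference_average": diff_average,
        "difference_variance": diff_variance,
        "difference_entropy": diff_entropy,
        "imc1": imc1,
        "imc2": imc2,
    }


def _brute_lines(H, W, theta):
    """Pixel coordinate sequences of every line along theta."""
    lines = []
    if theta == 0:
        for r in range(H):
            lines.append([(r, c) for c in range(W)])
    elif theta == 90:
        for c in range(W):
            lines.append([(r, c) for r in range(H)])
    elif theta == 135:  # down-right
        for s in range(-(H - 1), W):
            lines.append([(r, r + s) for r in range(H) if 0 <= r + s < W])
    elif theta == 45:  # up-right
        for s in range(H + W - 1):
            lines.append(
                [(r, s - r) for r in range(H - 1, -1, -1) if 0 <= s - r < W]
            )
    return lines


def brute_glrlm(levels, mask, G, theta, lmax):
    """Run-length matrix by scanning every direction line pixel by pixel."""
    H, W = levels.shape
    R = np.zeros((G, lmax))
    for line in _brute_lines(H, W, theta):
        run_level, run_len = None, 0
        for r, c in line + [(-1, -1)]:  # sentinel flushes the last run
            inside = r >= 0 and mask[r][c]
            lv = levels[r][c] if inside else None
            if inside and lv == run_level:
                run_len += 1
            else:
                if run_level is not None:
                    R[run_level - 1][run_len - 1] += 1
                run_level, run_len = (lv, 1) if inside else (None, 0)
    return R


def brute_glrlm_features(levels, mask, G, theta, lmax):
    R = brute_glrlm(levels, mask, G, theta, lmax)
    Nr = R.sum()
    Np = int(np.sum(mask))
    f = {
        "short_run_emphasis": sum(
            R[i][j] / (j + 1) ** 2 for i in range(G) for j in range(lmax)
        ) / Nr,
        "long_run_emphasis": sum(
            R[i][j] * (j + 1) ** 2 for i in range(G) for j in range(lmax)
        ) / Nr,
        "grey_level_nonuniformity": sum(
            sum(R[i][j] for j in range(lmax)) ** 2 for i in range(G)
        ) / Nr,
        "run_percentage": Nr / Np,
        "run_length_nonuniformity": sum(
            sum(R[i][j] for i in range(G)) ** 2 for j in range(lmax)
        ) / Nr,
        "low_grey_level_run_emphasis": sum(
            R[i][j] / (i + 1) ** 2 for i in range(G) for j in range(lmax)
        ) / Nr,
        "high_grey_level_run_emphasis": sum(
            R[i][j] * (i + 1) ** 2 for i in range(G) for j in range(lmax)
        ) / Nr,
    }
    return f


def brute_gldm_hist(levels, mask, G, delta):
    """Absolute-difference histogram by looping over every pixel."""
    dr, dc = delta
    H, W = levels.shape
    hist = np.zeros(G)
    for r in range(H):
        for c in range(W):
            r2, c2 = r + dr, c + dc
            if mask[r][c] and 0 <= r2 < H and 0 <= c2 < W and mask[r2][c2]:
                hist[abs(levels[r][c] - levels[r2][c2])] += 1
    total = hist.sum()
    return hist / total if total else hist


def brute_gldm_features(levels, mask, G, delta):
    p = brute_gldm_hist(levels, mask, G, delta)
    return {
        "contrast": sum(k**2 * p[k] for k in range(G)),
        "angular_second_moment": sum(p[k] ** 2 for k in range(G)),
        "entropy": _entropy2(p),
        "mean": sum(k * p[k] for k in range(G)),
        "inverse_difference_moment": sum(p[k] / (k**2 + 1) for k in range(G)),
    }


def mann_whitney_auc(scores, labels):
    """AUC as the tie-corrected pairwise comparison statistic."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                wins += 1.0
            elif a == b:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def youden_by_sweep(scores, labels):
    """Best J over an exhaustive sweep of every midpoint/extreme cutoff."""
    uniq = sorted(set(scores))
    cands = [uniq[0] - 1] + [(a + b) / 2 for a, b in zip(uniq, uniq[1:])] + [uniq[-1] + 1]
    best = None
    for c in cands:
        tp = sum(1 for s, y in zip(scores, labels) if s > c and y == 1)
        fp = sum(1 for s, y in zip(scores, labels) if s > c and y == 0)
        fn = sum(1 for s, y in zip(scores, labels) if s <= c and y == 1)
        tn = sum(1 for s, y in zip(scores, labels) if s <= c and y == 0)
        sens = tp / (tp + fn) if tp + fn else float("nan")
        spec = tn / (tn + fp) if tn + fp else float("nan")
        j = sens + spec - 1
        if best is None or (j, spec, c) > best:
            best = (j, spec, c)
    return best  # (J, specificity, cutoff)
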