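"""Independent brute-force oracles used by the unit and acceptance tests.

Each function evaluates the posted formula of an operation directly
(explicit loops, no shared code with the implementation paths they check).
"""

import math

import numpy as np


def brute_force_rectified(image, kernel):
    """Double-loop convolution with edge replication, clipped at zero."""
    h, w = image.shape
    r = kernel.shape[0] // 2
    out = np.zeros_like(image)
    for y in range(h):
        for x in range(w):
            acc = 0.0
            for dy in range(-r, r + 1):
                for dx in range(-r, r + 1):
                    yy = min(max(y - dy, 0), h - 1)
                    xx = min(max(x - dx, 0), w - 1)
                    acc += kernel[r + dy, r + dx] * image[yy, xx]
            out[y, x] = max(acc, 0.0)
    return out


def brute_force_blur_shift(c_map, rho, phi, sigma_prime):
    """Triple-loop weighted-max blur-and-shift; NaN where any accessed
    coordinate would fall outside the map (those pixels are skipped in
    comparisons)."""
    h, w = c_map.shape
    r = math.ceil(3 * sigma_prime)
    dx, dy = -rho * math.cos(phi), -rho * math.sin(phi)
    out = np.full((h, w), np.nan)
    for y in range(h):
        for x in range(w):
            best = -np.inf
            ok = True
            for yp in range(-r, r + 1):
                for xp in range(-r, r + 1):
                    yy = y - dy - yp
                    xx = x - dx - xp
                    if not (0 <= yy < h and 0 <= xx < w):
                        ok = False
                        break
                    weight = math.exp(-(xp**2 + yp**2) / (2 * sigma_prime**2))
                    best = max(best, c_map[int(round(yy)), int(round(xx))] * weight)
                if not ok:
                    break
            if ok:
                out[y, x] = best
    return out


def brute_force_geometric_mean(maps, rhos):
    """Direct per-pixel weighted geometric mean with the center-decaying
    weights recomputed from scratch."""
    tau = max(max(rhos) / 3.0, 1e-6)
    weights = [math.exp(-(r**2) / (2 * tau**2)) for r in rhos]
    total = sum(weights)
    h, w = maps[0].shape
    out = np.zeros((h, w))
    for y in range(h):
        for x in range(w):
            prod = 1.0
            for wgt, m in zip(weights, maps):
                prod *= m[y, x] ** wgt
            out[y, x] = prod ** (1.0 / total)
    return out


def loop_confusion(pred, gt):
    """Per-pixel counting loop."""
    tp = fp = tn = fn = 0
    h, w = pred.shape
    for y in range(h):
        for x in range(w):
            if pred[y, x] and gt[y, x]:
                tp += 1
            elif pred[y, x]:
                fp += 1
            elif gt[y, x]:
                fn += 1
            else:
                tn += 1
    return tp, fp, tn, fn


def pairwise_concordance_auc(scores, labels):
    """Exhaustive concordant-pair probability with half-credit ties."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))
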