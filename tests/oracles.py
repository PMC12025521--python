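"""Independent brute-force reference implementations used to check the
pipeline's vectorized/library-backed operations.  Everything here is
deliberately written as plain double loops over pixels/offsets and must
not call into sonoquant's implementation paths.
"""

from __future__ import annotations

import math

import numpy as np


def luma_loop(rgb: np.ndarray) -> np.ndarray:
    """Scalar per-pixel weighted sum for RGB -> gray."""
    h, w, _ = rgb.shape
    out = np.empty((h, w))
    for r in range(h):
        for c in range(w):
            p = rgb[r, c]
            out[r, c] = 0.299 * float(p[0]) + 0.587 * float(p[1]) + 0.114 * float(p[2])
    return out


def full_scan_roi(pixels: np.ndarray, threshold: float, band: tuple[float, float]):
    """Exhaustive-scan ROI oracle.

    Returns (left, right, top, bottom) half-open, or None when a scan
    direction finds no supra-threshold pixel.
    """
    h, w = pixels.shape
    r0 = int(band[0] * h)
    r1 = max(int(band[1] * h), r0 + 1)
    mid_col, mid_row = w // 2, h // 2

    left = None
    for c in range(0, mid_col + 1):
        if max(pixels[r, c] for r in range(r0, r1)) > threshold:
            left = c
            break
    right = None
    for c in range(w - 1, mid_col - 1, -1):
        if max(pixels[r, c] for r in range(r0, r1)) > threshold:
            right = c
            break
    if left is None or right is None:
        return None
    top = None
    for r in range(0, mid_row + 1):
        if max(pixels[r, c] for c in range(left, right + 1)) > threshold:
            top = r
            break
    bottom = None
    for r in range(h - 1, mid_row - 1, -1):
        if max(pixels[r, c] for c in range(left, right + 1)) > threshold:
            bottom = r
            break
    if top is None or bottom is None:
        return None
    return left, right + 1, top, bottom + 1


def zncc_all_offsets(image: np.ndarray, patch: np.ndarray):
    """Zero-mean normalized cross-correlation at every valid offset.

    Returns (best_row, best_col, best_score) by exhaustive search.
    """
    image = image.astype(np.float64)
    patch = patch.astype(np.float64)
    ph, pw = patch.shape
    p0 = patch - patch.mean()
    pnorm = math.sqrt((p0 * p0).sum())
    best = (-1, -1, -np.inf)
    for r in range(image.shape[0] - ph + 1):
        for c in range(image.shape[1] - pw + 1):
            win = image[r : r + ph, c : c + pw]
            w0 = win - win.mean()
            wnorm = math.sqrt((w0 * w0).sum())
            denom = pnorm * wnorm
            score = 0.0 if denom == 0 else float((w0 * p0).sum() / denom)
            if score > best[2]:
                best = (r, c, score)
    return best


def bilateral_loop(
    pixels: np.ndarray, sigma_spatial: float, sigma_intensity: float
) -> np.ndarray:
    """Per-pixel double-loop bilateral sum; neighbors outside the image
    are dropped, window half-width = ceil(sigma_spatial)."""
    h, w = pixels.shape
    radius = int(math.ceil(sigma_spatial))
    out = np.empty((h, w))
    for r in range(h):
        for c in range(w):
            num = den = 0.0
            for dr in range(-radius, radius + 1):
                for dc in range(-radius, radius + 1):
                    rr, cc = r + dr, c + dc
                    if not (0 <= rr < h and 0 <= cc < w):
                        continue
                    ws = math.exp(-(dr * dr + dc * dc) / (2 * sigma_spatial**2))
                    wi = math.exp(
                        -((pixels[rr, cc] - pixels[r, c]) ** 2)
                        / (2 * sigma_intensity**2)
                    )
                    num += ws * wi * pixels[rr, cc]
                    den += ws * wi
            out[r, c] = num / den
    return out


def glcm_pair_count(
    window: np.ndarray, levels: int, distance: int, angle: float, symmetric: bool
) -> np.ndarray:
    """Exhaustive pair enumeration co-occurrence matrix (normalized)."""
    q = (window.astype(np.int64) * levels) // 256
    dr = -int(round(distance * math.sin(angle)))
    dc = int(round(distance * math.cos(angle)))
    h, w = q.shape
    mat = np.zeros((levels, levels))
    for r in range(h):
        for c in range(w):
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w:
                mat[q[r, c], q[rr, cc]] += 1
    if symmetric:
        mat = mat + mat.T
    return mat / mat.sum()


def haralick_sums(p: np.ndarray) -> dict[str, float]:
    """Feature definitions evaluated as explicit double sums over one
    normalized co-occurrence matrix."""
    n = p.shape[0]
    asm = contrast = dissim = homog = entropy = 0.0
    mu_i = mu_j = 0.0
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    for i in range(n):
        mu_i += i * pi[i]
        mu_j += i * pj[i]
    var_i = var_j = 0.0
    for i in range(n):
        var_i += (i - mu_i) ** 2 * pi[i]
        var_j += (i - mu_j) ** 2 * pj[i]
    cov = 0.0
    for i in range(n):
        for j in range(n):
            v = p[i, j]
            asm += v * v
            contrast += (i - j) ** 2 * v
            dissim += abs(i - j) * v
            homog += v / (1.0 + (i - j) ** 2)
            if v > 0:
                entropy -= v * math.log2(v)
            cov += (i - mu_i) * (j - mu_j) * v
    denom = math.sqrt(var_i * var_j)
    corr = 0.0 if denom == 0 else cov / denom
    return {
        "asm": asm,
        "contrast": contrast,
        "correlation": corr,
        "dissimilarity": dissim,
        "entropy": entropy,
        "homogeneity": homog,
    }
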