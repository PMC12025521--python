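"""Texture characterization of the ROI via gray-level co-occurrence
matrices (GLCM) plus the histogram mean.

Seven variables are reported per image: angular second moment (ASM),
contrast, correlation, dissimilarity, entropy, homogeneity — all
GLCM-derived, averaged over the four canonical offsets — and the mean
of the normalized gray-level histogram.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError, DataError


@dataclass(frozen=True)
class GLCMSpec:
    """Co-occurrence construction parameters.

    levels
        Gray quantization: [0, 255] is mapped onto ``levels``
        equal-width bins before pair counting.
    distance_px, angles
        Pair offset length and directions.  Angle theta corresponds to
        the pixel offset (-d*sin(theta), +d*cos(theta)) in (row, col),
        i.e. 0 is horizontal, pi/2 vertical-up.
    symmetric
        Count each pair in both directions (matrix plus transpose).
    homogeneity_form
        "idm" (inverse difference moment, 1/(1+(i-j)^2), default) or
        "inverse_abs" (1/(1+|i-j|)).
    """

    levels: int = 32
    distance_px: int = 1
    angles: tuple[float, ...] = (0.0, math.pi / 4, math.pi / 2, 3 * math.pi / 4)
    symmetric: bool = True
    homogeneity_form: str = "idm"

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.distance_px < 1:
            raise ValueError("distance_px must be >= 1")
        if self.homogeneity_form not in ("idm", "inverse_abs"):
            raise ValueError("homogeneity_form must be 'idm' or 'inverse_abs'")


@dataclass(frozen=True)
class TextureFeatures:
    """Angle-averaged GLCM features (see :func:`texture_features`)."""

    asm: float
    contrast: float
    correlation: float
    dissimilarity: float
    entropy: float
    homogeneity: float

    def asdict(self) -> dict[str, float]:
        return {
            "asm": self.asm,
            "contrast": self.contrast,
            "correlation": self.correlation,
            "dissimilarity": self.dissimilarity,
            "entropy": self.entropy,
            "homogeneity": self.homogeneity,
        }


def quantize(window: np.ndarray, levels: int) -> np.ndarray:
    """Map byte intensities 0..255 onto ``levels`` equal-width bins."""
    window = np.asarray(window)
    if np.issubdtype(window.dtype, np.floating):
        window = np.floor(window + 0.5)
    q = (window.astype(np.int64) * levels) // 256
    return np.clip(q, 0, levels - 1)


def offset_for(angle: float, distance: int) -> tuple[int, int]:
    """(row, col) pixel offset for a GLCM angle; 0 -> (0, d),
    pi/4 -> (-d, d), pi/2 -> (-d, 0), 3pi/4 -> (-d, -d)."""
    dr = -int(round(distance * math.sin(angle)))
    dc = int(round(distance * math.cos(angle)))
    return dr, dc


def glcm(window: np.ndarray, spec: GLCMSpec = GLCMSpec()) -> np.ndarray:
    """Normalized co-occurrence matrices, one per angle.

    Returns an array of shape (levels, levels, n_angles) where each
    slice sums to 1.  Raises when the window is too small for the
    offset reach (no pairs).
    """
    window = np.asarray(window)
    if window.ndim != 2 or min(window.shape) < 2:
        raise DataError("glcm requires a window of at least 2x2 pixels")
    q = quantize(window, spec.levels)
    h, w = q.shape
    out = np.zeros((spec.levels, spec.levels, len(spec.angles)), dtype=np.float64)
    for k, angle in enumerate(spec.angles):
        dr, dc = offset_for(angle, spec.distance_px)
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        if r1 <= r0 or c1 <= c0:
            raise DataError(
                f"window {q.shape} too small for offset ({dr}, {dc})"
            )
        i = q[r0:r1, c0:c1].ravel()
        j = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel()
        counts = np.bincount(
            i * spec.levels + j, minlength=spec.levels * spec.levels
        ).reshape(spec.levels, spec.levels).astype(np.float64)
        if spec.symmetric:
            counts = counts + counts.T
        out[:, :, k] = counts / counts.sum()
    return out


def texture_features(glcms: np.ndarray, spec: GLCMSpec = GLCMSpec()) -> TextureFeatures:
    """Six Haralick-style features from normalized GLCMs, averaged over
    angles.

    Per angle, with p(i, j) the co-occurrence probability and
    mu/sigma the marginal moments:
    ASM = sum p^2; contrast = sum (i-j)^2 p; dissimilarity = sum |i-j| p;
    homogeneity = sum p / (1 + (i-j)^2); entropy = -sum p log2 p over
    p > 0; correlation = sum (i - mu_i)(j - mu_j) p / (sigma_i sigma_j),
    defined as 0 when either marginal variance vanishes.
    """
    glcms = np.asarray(glcms, dtype=np.float64)
    if glcms.ndim == 2:
        glcms = glcms[:, :, None]
    levels = glcms.shape[0]
    sums = glcms.sum(axis=(0, 1))
    if np.any(np.abs(sums - 1.0) > 1e-9):
        raise ContractError("co-occurrence matrices must each sum to 1")

    i = np.arange(levels, dtype=np.float64)[:, None]
    j = np.arange(levels, dtype=np.float64)[None, :]
    diff = i - j
    if spec.homogeneity_form == "idm":
        hom_w = 1.0 / (1.0 + diff**2)
    else:
        hom_w = 1.0 / (1.0 + np.abs(diff))

    per_angle = {k: [] for k in ("asm", "contrast", "correlation",
                                 "dissimilarity", "entropy", "homogeneity")}
    for k in range(glcms.shape[2]):
        p = glcms[:, :, k]
        per_angle["asm"].append(float((p**2).sum()))
        per_angle["contrast"].append(float((diff**2 * p).sum()))
        per_angle["dissimilarity"].append(float((np.abs(diff) * p).sum()))
        per_angle["homogeneity"].append(float((hom_w * p).sum()))
        pos = p[p > 0]
        per_angle["entropy"].append(float(-(pos * np.log2(pos)).sum()))
        pi = p.sum(axis=1)
        pj = p.sum(axis=0)
        mu_i = float((np.arange(levels) * pi).sum())
        mu_j = float((np.arange(levels) * pj).sum())
        var_i = float(((np.arange(levels) - mu_i) ** 2 * pi).sum())
        var_j = float(((np.arange(levels) - mu_j) ** 2 * pj).sum())
        denom = math.sqrt(var_i * var_j)
        if denom == 0.0:
            per_angle["correlation"].append(0.0)
        else:
            cov = float(((i - mu_i) * (j - mu_j) * p).sum())
            per_angle["correlation"].append(cov / denom)

    return TextureFeatures(**{k: float(np.mean(v)) for k, v in per_angle.items()})


def histogram_mean(window: np.ndarray) -> float:
    """Mean of the normalized 256-bin gray-level histogram (equals the
    pixel mean)."""
    window = np.asarray(window)
    if window.size == 0:
        raise DataError("histogram_mean requires a non-empty window")
    flat = np.clip(np.floor(window.astype(np.float64) + 0.5), 0, 255).astype(np.int64)
    hist = np.bincount(flat.ravel(), minlength=256).astype(np.float64)
    hist /= hist.sum()
    return float((np.arange(256) * hist).sum())


def compute_features(window: np.ndarray, spec: GLCMSpec = GLCMSpec()) -> dict[str, float]:
    """All seven image-characteristic variables for one window."""
    feats = texture_features(glcm(window, spec), spec).asdict()
    feats["histogram_mean"] = histogram_mean(window)
    return feats
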