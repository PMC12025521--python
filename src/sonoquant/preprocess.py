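"""Front half of the pipeline: grayscale conversion, center-out ROI
detection, edge-preserving bilateral filtering, and byte rescaling.

The stage order is deliberate: the ROI is located on the *unfiltered*
image so that smoothing cannot blur away the sharp dark-to-bright
transition at the transducer field edge, and the bilateral filter runs
only on the cropped ROI before intensities are re-quantized to bytes for
template matching.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError, EmptyROIError, UnsupportedFormatError

#: Rec. 601 luma weights used for RGB -> grayscale conversion.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass(frozen=True)
class ROIParams:
    """Parameters of the center-out threshold scan.

    intensity_threshold
        A pixel is "meaningful" when its intensity strictly exceeds this
        value (byte scale).  The default skips the near-black frame that
        surrounds the echo field.
    vertical_band
        Fraction of image height (top, bottom) restricting the rows
        inspected during the horizontal scan, so that on-screen overlays
        near the image borders cannot widen the ROI.
    min_roi_px
        Minimum acceptable ROI area in pixels; smaller boxes are treated
        as failed captures.
    """

    intensity_threshold: float = 10.0
    vertical_band: tuple[float, float] = (0.25, 0.75)
    min_roi_px: int = 64

    def __post_init__(self) -> None:
        lo, hi = self.vertical_band
        if not 0.0 <= lo < hi <= 1.0:
            raise ValueError(f"vertical_band must satisfy 0 <= top < bottom <= 1, got {self.vertical_band}")
        if not 0.0 <= self.intensity_threshold <= 255.0:
            raise ValueError("intensity_threshold must lie in [0, 255]")
        if self.min_roi_px < 1:
            raise ValueError("min_roi_px must be positive")


@dataclass(frozen=True)
class ROIBox:
    """Half-open pixel box [top, bottom) x [left, right), 0-based."""

    left_col: int
    right_col: int
    top_row: int
    bottom_row: int

    def __post_init__(self) -> None:
        if not (self.left_col < self.right_col and self.top_row < self.bottom_row):
            raise ValueError(f"degenerate ROI box {self}")
        if min(self.left_col, self.top_row) < 0:
            raise ValueError(f"negative ROI coordinate in {self}")

    @property
    def width(self) -> int:
        return self.right_col - self.left_col

    @property
    def height(self) -> int:
        return self.bottom_row - self.top_row

    @property
    def area(self) -> int:
        return self.width * self.height

    def crop(self, pixels: np.ndarray) -> np.ndarray:
        return pixels[self.top_row : self.bottom_row, self.left_col : self.right_col]


@dataclass(frozen=True)
class FilterParams:
    """Bilateral filter standard deviations.

    ``sigma_spatial`` is in pixels; ``sigma_intensity`` applies to
    intensities normalized to [0, 1].  The kernel window is truncated at
    a half-width of ``ceil(sigma_spatial)`` (11x11 at the default).
    """

    sigma_spatial: float = 5.0
    sigma_intensity: float = 0.1

    def __post_init__(self) -> None:
        if self.sigma_spatial <= 0 or self.sigma_intensity <= 0:
            raise ValueError("filter sigmas must be positive")


def to_grayscale(pixels: np.ndarray) -> np.ndarray:
    """Collapse a 3-channel RGB image to single-channel luma.

    Grayscale input passes through unchanged.  Integer input yields
    integer output (rounded half-up); float input stays float.
    """
    pixels = np.asarray(pixels)
    if pixels.ndim == 2:
        return pixels
    if pixels.ndim == 3 and pixels.shape[2] == 3:
        w = np.asarray(LUMA_WEIGHTS)
        luma = pixels.astype(np.float64) @ w
        if np.issubdtype(pixels.dtype, np.integer):
            return np.floor(luma + 0.5).astype(pixels.dtype)
        return luma
    raise UnsupportedFormatError(
        f"expected a 2-D or HxWx3 array, got shape {pixels.shape}"
    )


def _pixels_of(image) -> np.ndarray:
    return np.asarray(getattr(image, "pixels", image))


def compute_roi(image, params: ROIParams = ROIParams()) -> ROIBox:
    """Locate the informative sub-rectangle by center-out threshold scans.

    Horizontal pass: within the vertical band, walk from the middle
    column outward and keep the outermost column on each side whose
    band-restricted maximum exceeds the threshold.  Vertical pass:
    restricted to those columns, keep the outermost supra-threshold rows
    above and below the middle row (full height, no band).

    Raises :class:`EmptyROIError` when a scan direction finds nothing,
    which signals a blank or failed capture.
    """
    pixels = _pixels_of(image)
    if pixels.ndim != 2:
        raise UnsupportedFormatError("compute_roi expects a single-channel image")
    h, w = pixels.shape
    thr = params.intensity_threshold

    r0 = int(params.vertical_band[0] * h)
    r1 = max(int(params.vertical_band[1] * h), r0 + 1)
    col_supra = pixels[r0:r1].max(axis=0) > thr

    mid_col = w // 2
    left_hits = np.flatnonzero(col_supra[: mid_col + 1])
    if left_hits.size == 0:
        raise EmptyROIError("no supra-threshold column left of center")
    right_hits = np.flatnonzero(col_supra[mid_col:])
    if right_hits.size == 0:
        raise EmptyROIError("no supra-threshold column right of center")
    left = int(left_hits[0])
    right_incl = int(mid_col + right_hits[-1])

    row_supra = pixels[:, left : right_incl + 1].max(axis=1) > thr
    mid_row = h // 2
    top_hits = np.flatnonzero(row_supra[: mid_row + 1])
    if top_hits.size == 0:
        raise EmptyROIError("no supra-threshold row above center")
    bottom_hits = np.flatnonzero(row_supra[mid_row:])
    if bottom_hits.size == 0:
        raise EmptyROIError("no supra-threshold row below center")
    top = int(top_hits[0])
    bottom_incl = int(mid_row + bottom_hits[-1])

    box = ROIBox(left, right_incl + 1, top, bottom_incl + 1)
    if box.area < params.min_roi_px:
        raise EmptyROIError(
            f"ROI area {box.area} px below minimum {params.min_roi_px}"
        )
    return box


def to_unit_interval(pixels: np.ndarray) -> np.ndarray:
    """Map byte intensities onto [0, 1] floats (divide by 255)."""
    return np.asarray(pixels, dtype=np.float64) / 255.0


def bilateral_filter(pixels: np.ndarray, params: FilterParams = FilterParams()) -> np.ndarray:
    """Edge-preserving smoothing on [0, 1]-normalized intensities.

    Each output pixel is the spatial-Gaussian x intensity-Gaussian
    weighted mean of its neighborhood; neighbors falling outside the
    image are simply dropped (weights renormalize), so the output is
    always a convex combination of input values.

    Implemented directly (vectorized over window offsets) so the weights
    are exact rather than quantized through a lookup table.
    """
    pixels = np.asarray(pixels, dtype=np.float64)
    if pixels.ndim != 2:
        raise UnsupportedFormatError("bilateral_filter expects a 2-D image")
    if not np.all(np.isfinite(pixels)):
        raise DataError("bilateral_filter requires finite pixel values")

    radius = int(np.ceil(params.sigma_spatial))
    inv2ss = 1.0 / (2.0 * params.sigma_spatial**2)
    inv2si = 1.0 / (2.0 * params.sigma_intensity**2)

    h, w = pixels.shape
    acc = np.zeros((h, w))
    norm = np.zeros((h, w))
    for dr in range(-radius, radius + 1):
        for dc in range(-radius, radius + 1):
            sw = np.exp(-(dr * dr + dc * dc) * inv2ss)
            # overlapping slices: destination region and shifted source
            dst_r = slice(max(0, -dr), min(h, h - dr))
            src_r = slice(max(0, dr), min(h, h + dr))
            dst_c = slice(max(0, -dc), min(w, w - dc))
            src_c = slice(max(0, dc), min(w, w + dc))
            neigh = pixels[src_r, src_c]
            center = pixels[dst_r, dst_c]
            wgt = sw * np.exp(-((neigh - center) ** 2) * inv2si)
            acc[dst_r, dst_c] += wgt * neigh
            norm[dst_r, dst_c] += wgt
    return acc / norm


def rescale_to_byte(pixels: np.ndarray) -> np.ndarray:
    """Affine-map [min, max] onto integers 0..255 (rounded half-up).

    A constant image carries no intensity information and maps to all
    zeros.
    """
    pixels = np.asarray(pixels, dtype=np.float64)
    if not np.all(np.isfinite(pixels)):
        raise DataError("rescale_to_byte requires finite pixel values")
    mn = pixels.min()
    mx = pixels.max()
    if mx == mn:
        return np.zeros(pixels.shape, dtype=np.uint8)
    scaled = (pixels - mn) / (mx - mn) * 255.0
    return np.floor(scaled + 0.5).astype(np.uint8)
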