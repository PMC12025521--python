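"""Structure detection inside the ROI: bidirectional template matching
with scale/contrast fallback variants, anatomical-order validation, and
morphological contour refinement.

The match score is the zero-mean normalized cross-correlation (ZNCC),
which is invariant to affine intensity changes — essential because the
ROI is min-max rescaled before matching, while templates keep their
native brightness.  Raw (unnormalized) correlation is available behind
``MatchConfig.method = "ccorr"`` for fidelity experiments, but it is
brightness-biased and not used by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import fftconvolve
from skimage.feature import match_template as _skimage_match
from skimage.measure import find_contours, label
from skimage.morphology import closing as _closing, disk, opening as _opening
from skimage.transform import resize

from .errors import DegenerateTemplateError, TemplateSizeError
from .io_formats import ScanDescriptor, TemplateSet
from .preprocess import ROIBox

logger = logging.getLogger(__name__)

TOP_DOWN = "top_down"
BOTTOM_UP = "bottom_up"


@dataclass(frozen=True)
class MatchConfig:
    """Template-matching policy.

    accept_score
        Minimum ZNCC at which a variant match is accepted (0..1).
    variant_scales / variant_contrasts
        Fallback template variants tried in order when the original
        patch fails: bilinear rescales, then contrast remaps
        ``clip(128 + c*(p - 128))``.
    direction_order
        Which search direction wins a per-structure score tie.
    """

    accept_score: float = 0.60
    variant_scales: tuple[float, ...] = (0.9, 1.1)
    variant_contrasts: tuple[float, ...] = (0.8, 1.2)
    direction_order: str = "top_down_first"
    method: str = "zncc"

    def __post_init__(self) -> None:
        if not 0.0 < self.accept_score < 1.0:
            raise ValueError("accept_score must lie in (0, 1)")
        if any(s <= 0 for s in self.variant_scales):
            raise ValueError("variant scales must be positive")
        if self.direction_order not in ("top_down_first", "bottom_up_first"):
            raise ValueError("direction_order must be top_down_first or bottom_up_first")
        if self.method not in ("zncc", "ccorr"):
            raise ValueError("method must be 'zncc' or 'ccorr'")


@dataclass(frozen=True)
class MatchResult:
    """Best sliding-window match of one template patch."""

    structure_id: str
    score: float
    bbox: ROIBox
    variant_index: int = 0
    direction: str = TOP_DOWN


@dataclass
class StructureDetection:
    """An accepted anatomical interface/zone with its refined contour.

    ``interface_row`` is the representative boundary depth in ROI row
    coordinates (the patch center row at detection time; the median
    upper contour edge after refinement).
    """

    match: MatchResult
    contour: np.ndarray
    interface_row: float
    flags: list[str] = field(default_factory=list)

    @property
    def structure_id(self) -> str:
        return self.match.structure_id


def _bbox_outline(bbox: ROIBox) -> np.ndarray:
    t, b, l, r = bbox.top_row, bbox.bottom_row - 1, bbox.left_col, bbox.right_col - 1
    return np.array(
        [(t, l), (t, r), (b, r), (b, l), (t, l)], dtype=np.float64
    )


def match_template(
    image: np.ndarray,
    patch: np.ndarray,
    structure_id: str = "",
    method: str = "zncc",
) -> MatchResult:
    """Exhaustive sliding-window match; returns the arg-max offset.

    With ``method="zncc"`` the score at each offset is the zero-mean
    normalized cross-correlation in [-1, 1]; with ``"ccorr"`` it is the
    raw inner product (unbounded, brightness-biased).
    """
    image = np.asarray(image, dtype=np.float64)
    patch = np.asarray(patch, dtype=np.float64)
    if image.ndim != 2 or patch.ndim != 2:
        raise TemplateSizeError("match_template expects 2-D arrays")
    if not (patch.shape[0] < image.shape[0] and patch.shape[1] < image.shape[1]):
        raise TemplateSizeError(
            f"patch {patch.shape} must be strictly smaller than image {image.shape}"
        )
    if method == "zncc" and float(patch.std()) == 0.0:
        raise DegenerateTemplateError(
            f"template {structure_id or '<anonymous>'} has zero variance"
        )

    if method == "zncc":
        response = _skimage_match(image, patch, pad_input=False)
        response = np.clip(response, -1.0, 1.0)
    else:
        response = fftconvolve(image, patch[::-1, ::-1], mode="valid")
    r, c = np.unravel_index(int(np.argmax(response)), response.shape)
    bbox = ROIBox(int(c), int(c) + patch.shape[1], int(r), int(r) + patch.shape[0])
    return MatchResult(
        structure_id=structure_id,
        score=float(response[r, c]),
        bbox=bbox,
    )


def generate_variants(patch: np.ndarray, config: MatchConfig) -> list[np.ndarray]:
    """Ordered fallback list: original, bilinear rescales, contrast maps.

    Variants that would shrink below 3x3 are skipped (logged).
    """
    patch = np.asarray(patch)
    variants = [patch]
    for s in config.variant_scales:
        shape = (int(round(patch.shape[0] * s)), int(round(patch.shape[1] * s)))
        if min(shape) < 3:
            logger.warning("skipping scale variant %.3f: %s below 3x3", s, shape)
            continue
        scaled = resize(
            patch.astype(np.float64), shape, order=1, anti_aliasing=False,
            preserve_range=True,
        )
        variants.append(np.clip(np.floor(scaled + 0.5), 0, 255).astype(np.uint8))
    for c in config.variant_contrasts:
        mapped = np.clip(128.0 + c * (patch.astype(np.float64) - 128.0), 0, 255)
        variants.append(np.floor(mapped + 0.5).astype(np.uint8))
    return variants


def _scan_direction(
    roi_image: np.ndarray,
    entries,
    config: MatchConfig,
    direction: str,
) -> dict[str, StructureDetection]:
    """One directional pass; the admissible band for each structure lies
    strictly beyond the previously accepted interface."""
    found: dict[str, StructureDetection] = {}
    h = roi_image.shape[0]
    ordered = entries if direction == TOP_DOWN else list(reversed(entries))
    prev_row: float | None = None
    for entry in ordered:
        if direction == TOP_DOWN:
            band = slice(0 if prev_row is None else int(np.floor(prev_row)) + 1, h)
        else:
            band = slice(0, h if prev_row is None else int(np.ceil(prev_row)))
        sub = roi_image[band]
        accepted: StructureDetection | None = None
        for vi, vpatch in enumerate(generate_variants(entry.patch, config)):
            if not (vpatch.shape[0] < sub.shape[0] and vpatch.shape[1] < sub.shape[1]):
                continue
            try:
                m = match_template(sub, vpatch, entry.structure_id, config.method)
            except DegenerateTemplateError:
                continue
            if m.score >= config.accept_score:
                bbox = ROIBox(
                    m.bbox.left_col,
                    m.bbox.right_col,
                    m.bbox.top_row + band.start,
                    m.bbox.bottom_row + band.start,
                )
                m = replace(m, bbox=bbox, variant_index=vi, direction=direction)
                accepted = StructureDetection(
                    match=m,
                    contour=_bbox_outline(bbox),
                    interface_row=bbox.top_row + (vpatch.shape[0] - 1) / 2.0,
                    flags=["variant_fallback"] if vi > 0 else [],
                )
                break
        if accepted is not None:
            found[entry.structure_id] = accepted
            prev_row = accepted.interface_row
        else:
            logger.info(
                "detection failure: %s (%s, band %s)", entry.structure_id, direction, band
            )
    return found


def detect_structures(
    roi_image: np.ndarray,
    templates: TemplateSet,
    descriptor: ScanDescriptor,
    config: MatchConfig = MatchConfig(),
) -> list[StructureDetection]:
    """Locate every template structure for this scan category.

    Runs a top-down pass (each structure searched strictly below the
    previous accepted interface) and a bottom-up pass (strictly above),
    then fuses the two chains per structure, preferring the higher
    score subject to the whole set staying anatomically consistent
    (strictly increasing depth, bounded box overlap) — an inconsistent
    high-score lock on the wrong interface must not evict two correct
    neighbors.  Structures reaching ``accept_score`` in neither
    direction are absent from the result; the caller flags the record
    incomplete.
    """
    entries = templates.for_descriptor(descriptor)
    if not entries:
        raise ValueError(f"no templates for descriptor {descriptor.key}")
    roi_image = np.asarray(roi_image)

    td = _scan_direction(roi_image, entries, config, TOP_DOWN)
    bu = _scan_direction(roi_image, entries, config, BOTTOM_UP)

    prefer_td = config.direction_order == "top_down_first"
    options: list[list[StructureDetection | None]] = []
    for entry in entries:
        a, b = td.get(entry.structure_id), bu.get(entry.structure_id)
        cands = [a, b] if prefer_td else [b, a]
        cands = [c for c in cands if c is not None]
        if len(cands) == 2 and cands[1].match.score > cands[0].match.score:
            cands.reverse()
        options.append(cands + [None])

    best: list[StructureDetection] | None = None
    best_key = (-1, -np.inf)
    for combo in _combinations(options):
        chosen = [c for c in combo if c is not None]
        if not _consistent(chosen):
            continue
        key = (len(chosen), sum(c.match.score for c in chosen))
        if key > best_key:
            best_key = key
            best = chosen
    return best or []


def _combinations(options):
    if not options:
        yield []
        return
    for head in options[0]:
        for tail in _combinations(options[1:]):
            yield [head] + tail


def _consistent(chosen: list[StructureDetection]) -> bool:
    for a, b in zip(chosen, chosen[1:]):
        if not a.interface_row < b.interface_row:
            return False
        h_min = min(a.match.bbox.height, b.match.bbox.height)
        if _row_overlap(a.match.bbox, b.match.bbox) > 0.5 * h_min:
            return False
    return True


def _row_overlap(a: ROIBox, b: ROIBox) -> int:
    return max(0, min(a.bottom_row, b.bottom_row) - max(a.top_row, b.top_row))


def validate_order(
    detections: list[StructureDetection], templates: TemplateSet
) -> list[StructureDetection]:
    """Drop detections violating the superficial-to-deep anatomy.

    Interface rows must strictly increase with the template order index,
    and consecutive boxes may not overlap by more than half the smaller
    box height.  Of each violating pair the lower-score member is
    demoted (removed); ties keep the more superficial one.
    """
    if not detections:
        return []

    def oi(d: StructureDetection) -> int:
        for e in templates.entries:
            if e.structure_id == d.structure_id:
                return e.order_index
        raise KeyError(d.structure_id)

    survivors = sorted(detections, key=oi)
    changed = True
    while changed and len(survivors) > 1:
        changed = False
        for i in range(len(survivors) - 1):
            a, b = survivors[i], survivors[i + 1]
            monotone = a.interface_row < b.interface_row
            h_min = min(a.match.bbox.height, b.match.bbox.height)
            overlap_ok = _row_overlap(a.match.bbox, b.match.bbox) <= 0.5 * h_min
            if monotone and overlap_ok:
                continue
            loser = b if b.match.score < a.match.score else (
                a if a.match.score < b.match.score else b
            )
            logger.info(
                "order violation between %s and %s; dropping %s",
                a.structure_id, b.structure_id, loser.structure_id,
            )
            survivors.remove(loser)
            changed = True
            break
    return survivors


def binarize_bbox(roi_image: np.ndarray, bbox: ROIBox) -> np.ndarray:
    """Threshold the ROI at the Otsu level computed inside ``bbox``.

    Returns a boolean mask of the full ROI shape (True above level);
    a constant bbox yields an all-False mask.
    """
    from skimage.filters import threshold_otsu

    window = bbox.crop(np.asarray(roi_image))
    mask = np.zeros(np.asarray(roi_image).shape, dtype=bool)
    if window.size == 0 or window.max() == window.min():
        return mask
    level = threshold_otsu(window)
    mask[bbox.top_row : bbox.bottom_row, bbox.left_col : bbox.right_col] = window > level
    return mask


def refine_contour(
    binary_roi: np.ndarray,
    detection: StructureDetection,
    kernel_radius: int = 2,
) -> StructureDetection:
    """Morphological smoothing of the detection's binary support.

    Closing then opening with a disk of ``kernel_radius`` on the in-bbox
    mask; the contour becomes the boundary of the largest connected
    component and ``interface_row`` its median upper edge.  An empty
    post-morphology mask falls back to the bbox outline, flagged.
    """
    bbox = detection.match.bbox
    mask = np.asarray(binary_roi, dtype=bool)[
        bbox.top_row : bbox.bottom_row, bbox.left_col : bbox.right_col
    ]
    footprint = disk(kernel_radius)
    cleaned = _opening(_closing(mask, footprint), footprint)
    if not cleaned.any():
        return replace_detection(
            detection,
            contour=_bbox_outline(bbox),
            interface_row=detection.interface_row,
            extra_flags=["refine_fallback"],
        )

    labels = label(cleaned, connectivity=2)
    largest = int(np.argmax(np.bincount(labels.ravel())[1:])) + 1
    component = labels == largest

    padded = np.pad(component.astype(np.float64), 1)
    contours = find_contours(padded, 0.5)
    contour = max(contours, key=len) - 1.0  # undo pad
    contour += np.array([bbox.top_row, bbox.left_col], dtype=np.float64)

    cols_any = component.any(axis=0)
    upper_edges = component.argmax(axis=0)[cols_any]
    interface_row = float(np.median(upper_edges)) + bbox.top_row
    return replace_detection(
        detection, contour=contour, interface_row=interface_row, extra_flags=[]
    )


def replace_detection(
    detection: StructureDetection,
    contour: np.ndarray,
    interface_row: float,
    extra_flags: list[str],
) -> StructureDetection:
    return StructureDetection(
        match=detection.match,
        contour=contour,
        interface_row=interface_row,
        flags=list(detection.flags) + extra_flags,
    )
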