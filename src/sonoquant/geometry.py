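"""Length and area variables from validated detections.

Thicknesses ("Y-axis" variables, fat-layer depths) are vertical
distances between consecutive interface rows; widths ("X-axis") are the
ROI width; areas use a rectangular approximation for layer-like zones
and a direct least-squares ellipse fit for muscle cross-sections, with
the choice recorded in provenance.

Coordinates are (row, col), 0-based.  Ellipse orientation is the angle
of the semi-major axis measured from the +col (x) axis toward the +row
(y) axis, reduced to [0, pi).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import anatomy
from .detect import StructureDetection, binarize_bbox, refine_contour
from .errors import EllipseFitError, EmptyRecordError, OrderingError
from .io_formats import MeasurementRecord, ScanDescriptor
from .preprocess import ROIBox


@dataclass(frozen=True)
class Calibration:
    """Physical pixel scale.  ``source`` records where it came from:
    DICOM metadata, the pipeline config, or nowhere (pixel units)."""

    cm_per_px: float | None = None
    source: str = "none"

    def __post_init__(self) -> None:
        if self.source not in ("dicom", "config", "none"):
            raise ValueError("calibration source must be dicom, config, or none")
        if self.source != "none" and (self.cm_per_px is None or self.cm_per_px <= 0):
            raise ValueError("cm_per_px must be positive when a source is given")

    @property
    def scale(self) -> float:
        return self.cm_per_px if self.source != "none" else 1.0

    @property
    def length_units(self) -> str:
        return "cm" if self.source != "none" else "px"


@dataclass(frozen=True)
class EllipseParams:
    """Geometric ellipse: center (row, col), semi-axes a >= b,
    orientation of the major axis in [0, pi)."""

    center: tuple[float, float]
    semi_axis_a: float
    semi_axis_b: float
    orientation: float

    def __post_init__(self) -> None:
        if not (self.semi_axis_a >= self.semi_axis_b > 0):
            raise ValueError("semi-axes must satisfy a >= b > 0")


def thickness(upper: StructureDetection, lower: StructureDetection, cal: Calibration) -> float:
    """Vertical distance between two interface rows, scaled to cm
    (or px when uncalibrated)."""
    if upper.interface_row > lower.interface_row:
        raise OrderingError(
            f"{upper.structure_id} (row {upper.interface_row}) is below "
            f"{lower.structure_id} (row {lower.interface_row})"
        )
    return (lower.interface_row - upper.interface_row) * cal.scale


def zone_width(roi: ROIBox, cal: Calibration) -> float:
    """The X-axis variable: the ROI width set during initial processing."""
    return roi.width * cal.scale


def rect_area(height: float, width: float) -> float:
    if height < 0 or width < 0:
        raise ValueError("height and width must be non-negative")
    return height * width


def fit_ellipse_direct(points: np.ndarray) -> EllipseParams:
    """Direct least-squares conic fit with the ellipse-specific
    constraint 4AC - B^2 = 1 (Fitzgibbon's method, in the numerically
    stable partitioned form), converted to geometric parameters.

    ``points`` is an (n >= 6, 2) array of (row, col) samples.  The
    constraint guarantees an ellipse when a solution exists; degenerate
    (collinear) inputs raise :class:`EllipseFitError`.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 6:
        raise EllipseFitError("need at least 6 (row, col) points")
    y = pts[:, 0]  # rows
    x = pts[:, 1]  # cols
    # center the data for conditioning
    x0, y0 = x.mean(), y.mean()
    xc, yc = x - x0, y - y0

    d1 = np.column_stack([xc * xc, xc * yc, yc * yc])
    d2 = np.column_stack([xc, yc, np.ones_like(xc)])
    s1 = d1.T @ d1
    s2 = d1.T @ d2
    s3 = d2.T @ d2
    try:
        t = -np.linalg.solve(s3, s2.T)
    except np.linalg.LinAlgError as exc:
        raise EllipseFitError(f"degenerate point configuration ({exc})") from exc
    m = s1 + s2 @ t
    # inv(C1) @ M with C1 = [[0,0,2],[0,-1,0],[2,0,0]]
    m = np.array([m[2] / 2.0, -m[1], m[0] / 2.0])
    try:
        eigval, eigvec = np.linalg.eig(m)
    except np.linalg.LinAlgError as exc:
        raise EllipseFitError(f"eigen decomposition failed ({exc})") from exc
    if not np.all(np.isfinite(eigvec)):
        raise EllipseFitError("non-finite generalized eigen solution")
    cond = 4.0 * eigvec[0] * eigvec[2] - eigvec[1] ** 2
    ok = np.flatnonzero(cond > 0)
    if ok.size == 0:
        raise EllipseFitError("no eigenvector satisfies the ellipse constraint")
    a1 = np.real(eigvec[:, ok[0]])
    coeffs = np.concatenate([a1, t @ a1])  # A, B, C, D, E, F on centered data

    params = _conic_to_geometric(coeffs)
    # undo the centering shift
    cy, cx = params.center
    return EllipseParams(
        center=(cy + y0, cx + x0),
        semi_axis_a=params.semi_axis_a,
        semi_axis_b=params.semi_axis_b,
        orientation=params.orientation,
    )


def _conic_to_geometric(coeffs: np.ndarray) -> EllipseParams:
    """Convert conic Ax^2 + Bxy + Cy^2 + Dx + Ey + F = 0 to geometric
    ellipse parameters (x = col, y = row)."""
    A, B, C, D, E, F = (float(v) for v in coeffs)
    den = B * B - 4.0 * A * C
    if den >= 0:
        raise EllipseFitError("conic is not an ellipse (B^2 - 4AC >= 0)")
    cx = (2.0 * C * D - B * E) / den
    cy = (2.0 * A * E - B * D) / den

    a33 = np.array([[A, B / 2.0], [B / 2.0, C]])
    q = np.array([[A, B / 2.0, D / 2.0], [B / 2.0, C, E / 2.0], [D / 2.0, E / 2.0, F]])
    k = -np.linalg.det(q) / np.linalg.det(a33)
    lam, vec = np.linalg.eigh(a33)
    axes2 = k / lam
    if np.any(axes2 <= 0) or not np.all(np.isfinite(axes2)):
        raise EllipseFitError("non-positive squared semi-axes")
    axes = np.sqrt(axes2)
    major = int(np.argmax(axes))
    a, b = float(axes[major]), float(axes[1 - major])
    v = vec[:, major]  # (x, y) direction of the major axis
    theta = math.atan2(v[1], v[0]) % math.pi
    return EllipseParams(center=(cy, cx), semi_axis_a=a, semi_axis_b=b, orientation=theta)


def ellipse_area(p: EllipseParams, cal: Calibration) -> float:
    return math.pi * p.semi_axis_a * p.semi_axis_b * cal.scale**2


def ellipse_points(p: EllipseParams, n: int = 100) -> np.ndarray:
    """Sample n points on an ellipse boundary as (row, col) pairs."""
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    ct, st = np.cos(p.orientation), np.sin(p.orientation)
    x = p.semi_axis_a * np.cos(t)
    y = p.semi_axis_b * np.sin(t)
    col = p.center[1] + x * ct - y * st
    row = p.center[0] + x * st + y * ct
    return np.column_stack([row, col])


#: clearance (px) kept between a muscle-zone window and the bright
#: interface bands that bound it, so Otsu is not dominated by the bands
ZONE_PAD_PX = 8


def _muscle_zone_area(
    roi_image: np.ndarray,
    upper: StructureDetection,
    lower: StructureDetection,
    roi: ROIBox,
    cal: Calibration,
    kernel_radius: int,
) -> tuple[float, str]:
    """Elliptical area of the muscle cross-section between two
    aponeuroses; rectangular fallback when the fit fails or is
    implausible.  Returns (area, mode)."""
    rect = rect_area(thickness(upper, lower, cal), zone_width(roi, cal))
    top = int(np.ceil(upper.interface_row)) + ZONE_PAD_PX
    bottom = int(np.floor(lower.interface_row)) - ZONE_PAD_PX
    if bottom - top < 8:
        return rect, "rect_fallback"
    zone = ROIBox(0, roi_image.shape[1], top, bottom)
    mask = binarize_bbox(roi_image, zone)
    probe = StructureDetection(
        match=_zone_match(upper, zone), contour=np.empty((0, 2)), interface_row=float(top)
    )
    refined = refine_contour(mask, probe, kernel_radius=kernel_radius)
    if "refine_fallback" in refined.flags or refined.contour.shape[0] < 6:
        return rect, "rect_fallback"
    try:
        params = fit_ellipse_direct(refined.contour)
    except EllipseFitError:
        return rect, "rect_fallback"
    cy, cx = params.center
    plausible = (
        top <= cy <= bottom
        and 0 <= cx <= roi_image.shape[1]
        and 2 * params.semi_axis_a <= 1.5 * roi_image.shape[1]
        and 2 * params.semi_axis_b <= 1.5 * (bottom - top + 2 * ZONE_PAD_PX)
    )
    if not plausible:
        return rect, "rect_fallback"
    return ellipse_area(params, cal), "ellipse"


def _zone_match(upper: StructureDetection, zone: ROIBox):
    from dataclasses import replace

    return replace(upper.match, structure_id=upper.structure_id + "_zone", bbox=zone)


def measure(
    detections: list[StructureDetection],
    roi: ROIBox,
    descriptor: ScanDescriptor,
    cal: Calibration,
    roi_image: np.ndarray | None = None,
    kernel_radius: int = 2,
    image_id: str = "",
) -> MeasurementRecord:
    """Dispatch the applicable length/area variables for one scan.

    Abdomen planes yield the three fat thicknesses; leg planes yield the
    Y/X axes and areas of the rectus femoris and vastus intermedius.
    Muscle cross-section areas (transverse leg) use the ellipse fit on
    the refined zone contour when available and plausible, rectangular
    approximation otherwise; abdominal layers are always rectangular.
    Missing detections leave variables absent and flag the record.
    """
    if not detections:
        raise EmptyRecordError(f"{image_id or '<image>'}: no valid detections")
    by_id = {d.structure_id: d for d in detections}
    values: dict[str, float] = {}
    flags: list[str] = []
    prov: dict = {
        "match_scores": {d.structure_id: d.match.score for d in detections},
        "variant_indices": {d.structure_id: d.match.variant_index for d in detections},
        "directions": {d.structure_id: d.match.direction for d in detections},
        "interface_rows": {d.structure_id: d.interface_row for d in detections},
        "area_modes": {},
        "correlation_mode": "zncc",
    }

    def pair(upper_id: str, lower_id: str):
        u, lo = by_id.get(upper_id), by_id.get(lower_id)
        if u is None or lo is None:
            return None
        return u, lo

    if descriptor.region == anatomy.ABDOMEN:
        spec = {
            "Superficial Subcutaneous Fat": ("skin_fat", "fascia"),
            "Total Subcutaneous Fat": ("skin_fat", "muscle_wall"),
            "Peritoneal Fat": ("muscle_wall", "peritoneum"),
        }
        for name, (ui, li) in spec.items():
            p = pair(ui, li)
            if p is None:
                flags.append(f"incomplete:{name}")
                continue
            values[name] = thickness(p[0], p[1], cal)
    else:
        width = zone_width(roi, cal)
        muscles = {
            "Anterior Rectus": ("rectus_superficial", "rectus_intermuscular"),
            "Vastus Intermedius": ("rectus_intermuscular", "vastus_deep"),
        }
        for muscle, (ui, li) in muscles.items():
            p = pair(ui, li)
            if p is None:
                flags.append(f"incomplete:{muscle}")
                continue
            y = thickness(p[0], p[1], cal)
            values[f"Y-axis {muscle}"] = y
            values[f"X-axis {muscle}"] = width
            use_ellipse = (
                muscle == "Anterior Rectus"
                and descriptor.plane == anatomy.TRANSVERSE
                and roi_image is not None
            )
            if use_ellipse:
                area, mode = _muscle_zone_area(
                    roi_image, p[0], p[1], roi, cal, kernel_radius
                )
            else:
                area, mode = rect_area(y, width), "rect"
            values[f"{muscle} Area"] = area
            prov["area_modes"][muscle] = mode

    if not values:
        raise EmptyRecordError(f"{image_id or '<image>'}: no measurable variable")
    return MeasurementRecord(
        image_id=image_id,
        descriptor=descriptor,
        values=values,
        units=cal.length_units,
        provenance=prov,
        flags=flags,
    )
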