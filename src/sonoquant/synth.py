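"""Seeded synthetic B-mode phantoms with known ground truth.

Each phantom emulates the gross structure of a musculoskeletal
ultrasound scan: a black transducer-field margin, horizontally banded
tissue zones separated by bright echogenic interface bands (skin/fat
boundary, fasciae, aponeuroses, peritoneum), an optional elliptical
muscle cross-section (the rectus femoris in transverse leg scans), and
multiplicative lognormal speckle.  The spec fully determines the truth
(interface rows, thicknesses, areas), so the whole pipeline can be
exercised and scored offline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import anatomy
from .errors import PhantomSpecError
from .geometry import Calibration
from .io_formats import (
    ScanDescriptor,
    TemplateEntry,
    TemplateSet,
    UltrasoundImage,
)
from .preprocess import ROIBox


@dataclass(frozen=True)
class EllipseInclusion:
    """Elliptical bright inclusion (muscle cross-section) given in
    absolute image coordinates; axes in pixels, orientation radians."""

    center_row: float
    center_col: float
    semi_axis_row: float
    semi_axis_col: float
    orientation: float = 0.0
    intensity: float = 120.0


@dataclass(frozen=True)
class Interface:
    """One echogenic boundary: its depth row, band brightness, and the
    band thickness in pixels."""

    depth_row: int
    brightness: float = 230.0
    band_px: int = 5


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one phantom.

    ``zone_intensities`` gives the mean echo level of each tissue zone
    between consecutive interfaces (len(interfaces) + 1 values, from the
    skin zone down to below the deepest interface).  ``speckle_sigma``
    is the log-scale standard deviation of the multiplicative noise.
    """

    descriptor: ScanDescriptor
    shape: tuple[int, int] = (460, 520)
    cm_per_px: float = 0.01
    interfaces: tuple[Interface, ...] = ()
    zone_intensities: tuple[float, ...] = ()
    inclusion: EllipseInclusion | None = None
    speckle_sigma: float = 0.25
    margin_px: int = 30
    seed: int = 0

    def validate(self) -> None:
        rows, cols = self.shape
        n = len(self.interfaces)
        if n == 0:
            raise PhantomSpecError("phantom needs at least one interface")
        if len(self.zone_intensities) != n + 1:
            raise PhantomSpecError(
                f"need {n + 1} zone intensities for {n} interfaces, "
                f"got {len(self.zone_intensities)}"
            )
        depths = [i.depth_row for i in self.interfaces]
        if any(b <= a for a, b in zip(depths, depths[1:])):
            raise PhantomSpecError(f"interface depths must strictly increase: {depths}")
        m = self.margin_px
        if not (0 < m < min(rows, cols) // 4):
            raise PhantomSpecError(f"margin {m} incompatible with shape {self.shape}")
        for i in self.interfaces:
            if not (m <= i.depth_row and i.depth_row + i.band_px <= rows - m):
                raise PhantomSpecError(
                    f"interface band at row {i.depth_row} crosses the frame margin"
                )
        if self.inclusion is not None:
            inc = self.inclusion
            if (
                inc.center_row - inc.semi_axis_row < m
                or inc.center_row + inc.semi_axis_row > rows - m
                or inc.center_col - inc.semi_axis_col < m
                or inc.center_col + inc.semi_axis_col > cols - m
            ):
                raise PhantomSpecError("inclusion ellipse crosses the frame margin")
        if self.speckle_sigma < 0:
            raise PhantomSpecError("speckle_sigma must be non-negative")

    @property
    def structure_ids(self) -> tuple[str, ...]:
        ids = anatomy.structures_for(self.descriptor.region)
        if len(ids) != len(self.interfaces):
            raise PhantomSpecError(
                f"{self.descriptor.region} defines {len(ids)} interfaces, "
                f"spec has {len(self.interfaces)}"
            )
        return ids


@dataclass
class PhantomTruth:
    """Generator-side ground truth for one phantom."""

    descriptor: ScanDescriptor
    roi: ROIBox
    boundary_rows: dict[str, int]
    variables: dict[str, float]
    cm_per_px: float


def default_abdomen_spec(
    plane: str = anatomy.LONGITUDINAL, seed: int = 0
) -> PhantomSpec:
    """Abdominal layered phantom: skin, superficial subcutaneous fat,
    deep subcutaneous fat, abdominal-wall muscle, visceral compartment."""
    return PhantomSpec(
        descriptor=ScanDescriptor(region=anatomy.ABDOMEN, plane=plane),
        # entrance echo thick and bright, fasciae thinner, peritoneal
        # line broad (bowel-gas reverberation below)
        interfaces=(
            Interface(depth_row=80, brightness=235.0, band_px=7),
            Interface(depth_row=160, brightness=225.0, band_px=4),
            Interface(depth_row=260, brightness=230.0, band_px=5),
            Interface(depth_row=360, brightness=240.0, band_px=9),
        ),
        # skin, superficial fat, deep fat, muscle wall, visceral
        zone_intensities=(120.0, 40.0, 70.0, 55.0, 30.0),
        seed=seed,
    )


def default_leg_spec(plane: str = anatomy.TRANSVERSE, seed: int = 0) -> PhantomSpec:
    """Thigh phantom: skin, subcutaneous fat, rectus femoris (with an
    elliptical cross-section in the transverse plane), vastus
    intermedius, femur shadow."""
    interfaces = (
        Interface(depth_row=70, brightness=235.0, band_px=7),
        Interface(depth_row=130, brightness=225.0, band_px=4),
        Interface(depth_row=330, brightness=230.0, band_px=5),
        Interface(depth_row=410, brightness=240.0, band_px=8),
    )
    inclusion = None
    if plane == anatomy.TRANSVERSE:
        inclusion = EllipseInclusion(
            center_row=230.0,
            center_col=260.0,
            semi_axis_row=85.0,
            semi_axis_col=130.0,
            intensity=125.0,
        )
    return PhantomSpec(
        descriptor=ScanDescriptor(region=anatomy.LEG, plane=plane),
        interfaces=interfaces,
        # skin, fat, rectus femoris, vastus intermedius, femur shadow
        zone_intensities=(120.0, 50.0, 65.0, 55.0, 25.0),
        inclusion=inclusion,
        seed=seed,
    )


def _truth_from_spec(spec: PhantomSpec) -> PhantomTruth:
    rows, cols = spec.shape
    m = spec.margin_px
    roi = ROIBox(m, cols - m, m, rows - m)
    ids = spec.structure_ids
    boundary_rows = {sid: i.depth_row for sid, i in zip(ids, spec.interfaces)}
    s = spec.cm_per_px
    v: dict[str, float] = {}
    d = boundary_rows
    if spec.descriptor.region == anatomy.ABDOMEN:
        v["Superficial Subcutaneous Fat"] = (d["fascia"] - d["skin_fat"]) * s
        v["Total Subcutaneous Fat"] = (d["muscle_wall"] - d["skin_fat"]) * s
        v["Peritoneal Fat"] = (d["peritoneum"] - d["muscle_wall"]) * s
    else:
        width = roi.width * s
        y_rect = (d["rectus_intermuscular"] - d["rectus_superficial"]) * s
        y_vast = (d["vastus_deep"] - d["rectus_intermuscular"]) * s
        v["Y-axis Anterior Rectus"] = y_rect
        v["X-axis Anterior Rectus"] = width
        v["Y-axis Vastus Intermedius"] = y_vast
        v["X-axis Vastus Intermedius"] = width
        if spec.inclusion is not None:
            v["Anterior Rectus Area"] = (
                np.pi * spec.inclusion.semi_axis_row * spec.inclusion.semi_axis_col * s * s
            )
        else:
            v["Anterior Rectus Area"] = y_rect * width
        v["Vastus Intermedius Area"] = y_vast * width
    return PhantomTruth(
        descriptor=spec.descriptor,
        roi=roi,
        boundary_rows=boundary_rows,
        variables=v,
        cm_per_px=spec.cm_per_px,
    )


def _check_band_salience(pixels: np.ndarray, spec: PhantomSpec) -> None:
    """Interface bands must remain the row-wise intensity maxima of
    their neighborhood after speckle, or the threshold-scan premise of
    the ROI stage breaks down."""
    rows, cols = spec.shape
    m = spec.margin_px
    row_means = pixels[:, m : cols - m].mean(axis=1)
    depths = [m] + [i.depth_row for i in spec.interfaces] + [rows - m]
    for k, iface in enumerate(spec.interfaces):
        lo, hi = (depths[k] + depths[k + 1]) // 2, (depths[k + 1] + depths[k + 2]) // 2
        local = row_means[lo:hi]
        peak = lo + int(np.argmax(local))
        if not (iface.depth_row <= peak < iface.depth_row + iface.band_px):
            raise PhantomSpecError(
                f"speckle drowned the interface at row {iface.depth_row} "
                f"(row-mean peak at {peak}); reduce speckle_sigma or raise brightness"
            )


def generate_phantom(spec: PhantomSpec) -> tuple[UltrasoundImage, PhantomTruth]:
    """Render one phantom deterministically from (spec, spec.seed)."""
    spec.validate()
    rows, cols = spec.shape
    m = spec.margin_px
    base = np.zeros((rows, cols), dtype=np.float64)

    depths = [i.depth_row for i in spec.interfaces]
    zone_edges = [m] + depths + [rows - m]
    for z, intensity in enumerate(spec.zone_intensities):
        base[zone_edges[z] : zone_edges[z + 1], m : cols - m] = intensity

    if spec.inclusion is not None:
        inc = spec.inclusion
        rr, cc = np.mgrid[0:rows, 0:cols]
        ct, st = np.cos(inc.orientation), np.sin(inc.orientation)
        dx = cc - inc.center_col
        dy = rr - inc.center_row
        u = dx * ct + dy * st
        w = -dx * st + dy * ct
        inside = (u / inc.semi_axis_col) ** 2 + (w / inc.semi_axis_row) ** 2 <= 1.0
        base[inside] = inc.intensity

    # the echogenic band starts at the interface depth and extends into
    # the deeper tissue, so the band's upper edge IS the boundary
    for iface in spec.interfaces:
        base[iface.depth_row : iface.depth_row + iface.band_px, m : cols - m] = (
            iface.brightness
        )

    rng = np.random.default_rng(spec.seed)
    if spec.speckle_sigma > 0:
        noise = np.exp(
            rng.normal(0.0, spec.speckle_sigma, size=(rows, cols))
            - spec.speckle_sigma**2 / 2.0
        )
        interior = np.zeros((rows, cols), dtype=bool)
        interior[m : rows - m, m : cols - m] = True
        base = np.where(interior, base * noise, base)

    pixels = np.clip(np.floor(base + 0.5), 0, 255).astype(np.uint8)
    if spec.speckle_sigma > 0:
        _check_band_salience(pixels.astype(np.float64), spec)
    image = UltrasoundImage(
        pixels=pixels,
        pixel_spacing_cm=spec.cm_per_px,
        source_path="",
        descriptor=spec.descriptor,
    )
    return image, _truth_from_spec(spec)


def extract_templates(
    image: UltrasoundImage,
    truth: PhantomTruth,
    patch_size: tuple[int, int] = (21, 61),
    preprocess: bool = True,
) -> TemplateSet:
    """Cut one patch per true interface, centered on the boundary at the
    ROI mid-column, ordered superficial to deep.

    With ``preprocess`` (default) the patches are cut from the
    bilateral-filtered, byte-rescaled ROI — the same representation the
    detector searches — so templates are clean interface signatures
    rather than raw speckle.
    """
    from .preprocess import bilateral_filter, rescale_to_byte, to_unit_interval

    ph, pw = patch_size
    roi = truth.roi
    source = np.asarray(image.pixels)
    if preprocess:
        source = rescale_to_byte(
            bilateral_filter(to_unit_interval(roi.crop(source)))
        )
        offset_r, offset_c = roi.top_row, roi.left_col
    else:
        offset_r, offset_c = 0, 0
    cc = (roi.left_col + roi.right_col) // 2 - offset_c
    entries = []
    ids = anatomy.structures_for(truth.descriptor.region)
    for order, sid in enumerate(ids):
        if sid not in truth.boundary_rows:
            continue
        r = truth.boundary_rows[sid] - offset_r
        r0, c0 = r - ph // 2, cc - pw // 2
        r1, c1 = r0 + ph, c0 + pw
        if (
            r0 < roi.top_row - offset_r
            or r1 > roi.bottom_row - offset_r
            or c0 < roi.left_col - offset_c
            or c1 > roi.right_col - offset_c
        ):
            raise PhantomSpecError(
                f"patch for {sid} at row {r} crosses the frame/margin"
            )
        patch = source[r0:r1, c0:c1].copy()
        entries.append(
            TemplateEntry(
                structure_id=sid,
                descriptor=truth.descriptor,
                patch=patch,
                order_index=order,
            )
        )
    return TemplateSet(entries=entries)


@dataclass(frozen=True)
class CohortJitter:
    """Uniform perturbation ranges applied per phantom: interface depths
    (+/- px, order-preserving), zone/band intensities (+/- levels), and
    inclusion semi-axes (+/- px)."""

    depth_px: int = 10
    intensity: float = 8.0
    axes_px: float = 8.0


def _jitter_spec(base: PhantomSpec, jitter: CohortJitter, rng: np.random.Generator,
                 seed: int) -> PhantomSpec:
    for _ in range(100):
        interfaces = tuple(
            replace(i, depth_row=int(i.depth_row + rng.integers(-jitter.depth_px,
                                                                jitter.depth_px + 1)))
            for i in base.interfaces
        )
        zones = tuple(
            float(np.clip(z + rng.uniform(-jitter.intensity, jitter.intensity), 5, 250))
            for z in base.zone_intensities
        )
        inclusion = base.inclusion
        if inclusion is not None:
            depths = [i.depth_row for i in interfaces]
            # keep the muscle cross-section centered in its jittered zone
            zone_mid = (depths[1] + depths[2]) / 2.0
            inclusion = replace(
                inclusion,
                center_row=zone_mid,
                semi_axis_row=float(
                    inclusion.semi_axis_row + rng.uniform(-jitter.axes_px, jitter.axes_px)
                ),
                semi_axis_col=float(
                    inclusion.semi_axis_col + rng.uniform(-jitter.axes_px, jitter.axes_px)
                ),
            )
        candidate = replace(
            base, interfaces=interfaces, zone_intensities=zones,
            inclusion=inclusion, seed=seed,
        )
        try:
            candidate.validate()
            if inclusion is not None:
                depths = [i.depth_row for i in interfaces]
                if (
                    inclusion.center_row - inclusion.semi_axis_row <= depths[1] + 4
                    or inclusion.center_row + inclusion.semi_axis_row >= depths[2] - 4
                ):
                    continue
            return candidate
        except PhantomSpecError:
            continue
    raise PhantomSpecError("could not draw a valid jittered spec in 100 attempts")


def generate_cohort(
    n: int,
    base_spec: PhantomSpec,
    jitter: CohortJitter | None = None,
    seed: int = 0,
) -> list[tuple[UltrasoundImage, PhantomTruth]]:
    """n reproducibly seeded phantoms with jittered geometry/intensity."""
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        child_seed = int(rng.integers(0, 2**31 - 1))
        if jitter is None:
            spec = replace(base_spec, seed=child_seed)
        else:
            spec = _jitter_spec(base_spec, jitter, rng, child_seed)
        out.append(generate_phantom(spec))
    return out


def simulate_reader(
    truths: list[PhantomTruth],
    image_ids: list[str],
    sigma: float = 0.05,
    seed: int = 0,
):
    """Simulated expert operator: truth + Normal(0, sigma) reading noise
    on every variable (sigma in the variable's own units).  Returns
    MeasurementRecords suitable for the agreement module."""
    from .io_formats import MeasurementRecord

    rng = np.random.default_rng(seed)
    records = []
    for truth, image_id in zip(truths, image_ids):
        values = {
            k: float(v + rng.normal(0.0, sigma)) for k, v in truth.variables.items()
        }
        records.append(
            MeasurementRecord(
                image_id=image_id,
                descriptor=truth.descriptor,
                values=values,
                units="cm" if truth.cm_per_px else "px",
                provenance={"source": "simulated_reader", "sigma": sigma},
            )
        )
    return records


def truth_records(truths: list[PhantomTruth], image_ids: list[str]):
    """Ground-truth values packaged as MeasurementRecords (zero-noise
    reference reader)."""
    return simulate_reader(truths, image_ids, sigma=0.0, seed=0)


def calibration_for(spec_or_truth) -> Calibration:
    return Calibration(cm_per_px=spec_or_truth.cm_per_px, source="config")


def spec_to_json(spec: PhantomSpec, path) -> None:
    """Serialize a phantom spec to JSON (lossless round trip)."""
    from dataclasses import asdict
    from pathlib import Path
    import json

    Path(path).write_text(json.dumps(asdict(spec), indent=2))


def spec_from_json(path) -> PhantomSpec:
    from pathlib import Path
    import json

    raw = json.loads(Path(path).read_text())
    raw["descriptor"] = ScanDescriptor(**raw["descriptor"])
    raw["shape"] = tuple(raw["shape"])
    raw["interfaces"] = tuple(Interface(**i) for i in raw["interfaces"])
    raw["zone_intensities"] = tuple(raw["zone_intensities"])
    if raw.get("inclusion") is not None:
        raw["inclusion"] = EllipseInclusion(**raw["inclusion"])
    return PhantomSpec(**raw)
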