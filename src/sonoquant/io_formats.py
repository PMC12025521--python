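"""Image readers, scan-code parsing, template libraries, and the
flat-file measurement store.

Supported raster formats are PNG/JPEG/BMP (via Pillow) and DICOM (via
pydicom).  Measurement records are persisted as a CSV table with a JSON
provenance sidecar — a deliberately file-based stand-in for a clinical
results database.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
import pydicom

from . import anatomy
from .errors import (
    ImageReadError,
    ScanCodeError,
    TemplateLibraryError,
    UnsupportedFormatError,
)
from .preprocess import to_grayscale

RASTER_EXTENSIONS = {".png", ".jpg", ".jpeg", ".bmp"}
DICOM_EXTENSIONS = {".dcm"}
SUPPORTED_EXTENSIONS = RASTER_EXTENSIONS | DICOM_EXTENSIONS

_CODE_RE = re.compile(r"^.*_(ab|leg)_([lt])$", re.IGNORECASE)

_REGION_BY_TOKEN = {"ab": anatomy.ABDOMEN, "leg": anatomy.LEG}
_PLANE_BY_TOKEN = {"l": anatomy.LONGITUDINAL, "t": anatomy.TRANSVERSE}


@dataclass(frozen=True)
class ScanDescriptor:
    """Scan category: body region x imaging plane.

    The four categories (abdomen/leg x longitudinal/transverse) drive
    which template set and which measurement variables apply.
    """

    region: str
    plane: str
    code: str = ""

    def __post_init__(self) -> None:
        if self.region not in anatomy.REGIONS:
            raise ValueError(f"region must be one of {anatomy.REGIONS}, got {self.region!r}")
        if self.plane not in anatomy.PLANES:
            raise ValueError(f"plane must be one of {anatomy.PLANES}, got {self.plane!r}")

    @property
    def key(self) -> tuple[str, str]:
        return (self.region, self.plane)


@dataclass
class UltrasoundImage:
    """A single-channel B-mode scan plus acquisition metadata."""

    pixels: np.ndarray
    pixel_spacing_cm: float | None = None
    source_path: str = ""
    descriptor: ScanDescriptor | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("UltrasoundImage pixels must be 2-D")
        if self.height_px < 32 or self.width_px < 32:
            raise ValueError(
                f"image too small ({self.height_px}x{self.width_px}); minimum is 32x32"
            )
        if not np.all(np.isfinite(np.asarray(self.pixels, dtype=np.float64))):
            raise ValueError("image contains non-finite intensities")
        if self.pixel_spacing_cm is not None and self.pixel_spacing_cm <= 0:
            raise ValueError("pixel_spacing_cm must be positive when present")

    @property
    def height_px(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width_px(self) -> int:
        return int(self.pixels.shape[1])


@dataclass(frozen=True)
class TemplateEntry:
    structure_id: str
    descriptor: ScanDescriptor
    patch: np.ndarray
    order_index: int


@dataclass
class TemplateSet:
    """Library of reference patches, one per anatomical interface.

    ``order_index`` encodes the superficial-to-deep anatomical order and
    is unique per (descriptor, structure_id).
    """

    entries: list[TemplateEntry] = field(default_factory=list)

    def for_descriptor(self, descriptor: ScanDescriptor) -> list[TemplateEntry]:
        """Entries applicable to one scan category, superficial first."""
        sel = [e for e in self.entries if e.descriptor.key == descriptor.key]
        return sorted(sel, key=lambda e: e.order_index)

    def order_index_of(self, descriptor: ScanDescriptor, structure_id: str) -> int:
        for e in self.for_descriptor(descriptor):
            if e.structure_id == structure_id:
                return e.order_index
        raise KeyError(structure_id)


@dataclass
class MeasurementRecord:
    """One image's worth of output: Table-style length/area variables,
    texture features, and provenance.

    Variables that could not be measured are simply absent from
    ``values`` (never imputed as zero); ``flags`` records why.
    """

    image_id: str
    descriptor: ScanDescriptor | None
    values: dict[str, float] = field(default_factory=dict)
    units: str = "px"
    texture: dict[str, float] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    @property
    def incomplete(self) -> bool:
        return any(f.startswith(("incomplete", "failed")) for f in self.flags)


def parse_scan_code(name: str, mapping: dict[str, tuple[str, str]] | None = None) -> ScanDescriptor:
    """Parse the scan-type code embedded in a filename.

    The default grammar is ``<anything>_<AB|LEG>_<L|T>[.<ext>]``,
    case-insensitive (AB = abdomen, LEG = leg; L = longitudinal,
    T = transverse).  ``mapping`` overrides it with site-specific codes:
    a dict from code suffix to ``(region, plane)``, matched against the
    end of the filename stem.
    """
    if not name:
        raise ScanCodeError("empty image name")
    stem = Path(name).name
    suffix = Path(stem).suffix.lower()
    if suffix in SUPPORTED_EXTENSIONS:
        stem = Path(stem).stem

    if mapping:
        low = stem.lower()
        for code, (region, plane) in mapping.items():
            if low.endswith(code.lower()):
                return ScanDescriptor(region=region, plane=plane, code=code)

    m = _CODE_RE.match(stem)
    if m is None:
        raise ScanCodeError(
            f"no scan-type code in {name!r}; expected a name matching "
            "'<anything>_<AB|LEG>_<L|T>' (case-insensitive) or a "
            "configured code mapping"
        )
    return ScanDescriptor(
        region=_REGION_BY_TOKEN[m.group(1).lower()],
        plane=_PLANE_BY_TOKEN[m.group(2).lower()],
        code=f"{m.group(1)}_{m.group(2)}".upper(),
    )


def _read_dicom(path: Path) -> tuple[np.ndarray, float | None]:
    ds = pydicom.dcmread(path)
    pixels = np.asarray(ds.pixel_array)
    if pixels.ndim == 3:
        pixels = to_grayscale(pixels)
    # MONOCHROME1 stores inverted video; normalize so brighter = stronger echo
    if getattr(ds, "PhotometricInterpretation", "MONOCHROME2") == "MONOCHROME1":
        pixels = pixels.max() - pixels
    spacing_cm: float | None = None
    spacing = getattr(ds, "PixelSpacing", None)
    if spacing is not None and len(spacing) >= 1:
        # DICOM PixelSpacing is millimetres (row, col); isotropic assumed
        spacing_cm = float(spacing[0]) / 10.0
    return pixels, spacing_cm


def read_image(path, pixel_spacing_override: float | None = None) -> UltrasoundImage:
    """Read a PNG/JPEG/BMP/DICOM file into a grayscale UltrasoundImage.

    Color inputs are collapsed with the Rec. 601 luma weights.  The scan
    descriptor is parsed from the filename when the code grammar
    matches, else left as None for the caller to resolve.
    """
    path = Path(path)
    ext = path.suffix.lower()
    if ext not in SUPPORTED_EXTENSIONS:
        raise UnsupportedFormatError(
            f"{path}: unsupported extension {ext!r}; supported: "
            + ", ".join(sorted(SUPPORTED_EXTENSIONS))
        )
    if not path.exists():
        raise ImageReadError(f"{path}: no such file")

    spacing: float | None = None
    try:
        if ext in DICOM_EXTENSIONS:
            pixels, spacing = _read_dicom(path)
        else:
            with Image.open(path) as im:
                if im.mode not in ("L", "I;16", "I", "RGB"):
                    im = im.convert("RGB")
                pixels = np.asarray(im)
            pixels = to_grayscale(pixels)
    except (OSError, ValueError, KeyError, pydicom.errors.InvalidDicomError) as exc:
        raise ImageReadError(f"{path}: cannot decode image ({exc})") from exc

    if pixel_spacing_override is not None:
        spacing = float(pixel_spacing_override)
    try:
        descriptor = parse_scan_code(path.name)
    except ScanCodeError:
        descriptor = None
    return UltrasoundImage(
        pixels=pixels,
        pixel_spacing_cm=spacing,
        source_path=str(path),
        descriptor=descriptor,
    )


MANIFEST_NAME = "manifest.tsv"
MANIFEST_COLUMNS = ["structure_id", "region", "plane", "order_index", "filename"]
#: Largest patch dimension a library may declare; patches are meant to be
#: small local interface signatures, not whole-image masks.
MAX_PATCH_PX = 128


def load_template_library(root) -> TemplateSet:
    """Load a template directory: grayscale PNG patches + manifest.tsv."""
    root = Path(root)
    manifest_path = root / MANIFEST_NAME
    if not manifest_path.exists():
        raise TemplateLibraryError(f"{root}: missing {MANIFEST_NAME}")
    manifest = pd.read_csv(manifest_path, sep="\t", dtype={"structure_id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise TemplateLibraryError(f"{manifest_path}: missing columns {missing}")
    if len(manifest) == 0:
        raise TemplateLibraryError(f"{manifest_path}: empty manifest")

    entries: list[TemplateEntry] = []
    seen: set[tuple[str, str, str]] = set()
    seen_order: set[tuple[str, str, int]] = set()
    for row in manifest.itertuples(index=False):
        descriptor = ScanDescriptor(region=row.region, plane=row.plane)
        key = (row.region, row.plane, row.structure_id)
        if key in seen:
            raise TemplateLibraryError(f"duplicate template entry {key}")
        okey = (row.region, row.plane, int(row.order_index))
        if okey in seen_order:
            raise TemplateLibraryError(f"duplicate order_index {okey}")
        seen.add(key)
        seen_order.add(okey)
        patch_path = root / str(row.filename)
        try:
            with Image.open(patch_path) as im:
                patch = np.asarray(im.convert("L"))
        except OSError as exc:
            raise TemplateLibraryError(f"{patch_path}: unreadable patch ({exc})") from exc
        if max(patch.shape) > MAX_PATCH_PX:
            raise TemplateLibraryError(
                f"{patch_path}: patch {patch.shape} exceeds maximum {MAX_PATCH_PX} px"
            )
        entries.append(
            TemplateEntry(
                structure_id=str(row.structure_id),
                descriptor=descriptor,
                patch=patch,
                order_index=int(row.order_index),
            )
        )
    return TemplateSet(entries=entries)


def save_template_library(templates: TemplateSet, root) -> Path:
    """Write a TemplateSet as PNG patches + manifest.tsv (lossless)."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    rows = []
    for e in templates.entries:
        fname = f"{e.descriptor.region}_{e.descriptor.plane}_{e.structure_id}.png"
        Image.fromarray(np.asarray(e.patch, dtype=np.uint8), mode="L").save(root / fname)
        rows.append(
            {
                "structure_id": e.structure_id,
                "region": e.descriptor.region,
                "plane": e.descriptor.plane,
                "order_index": e.order_index,
                "filename": fname,
            }
        )
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(
        root / MANIFEST_NAME, sep="\t", index=False
    )
    return root


_META_COLUMNS = ["image_id", "region", "plane", "units"]


def measurement_columns(records: list[MeasurementRecord]) -> list[str]:
    """Stable column order: metadata, applicable length/area variables
    in canonical order, then texture features."""
    present: set[str] = set()
    for r in records:
        present.update(r.values)
    var_cols = [v for v in anatomy.ALL_VARIABLES if v in present]
    # keep any non-canonical extras, alphabetically, after the canon
    extras = sorted(present - set(var_cols))
    tex_cols = [t for t in anatomy.TEXTURE_VARIABLES if any(t in r.texture for r in records)]
    return _META_COLUMNS + var_cols + extras + tex_cols + ["flags"]


def write_measurements(records: list[MeasurementRecord], path) -> Path:
    """Persist records as CSV (full float precision) + JSON provenance
    sidecar at ``<path>.provenance.json``.

    Lengths are cm and areas cm^2 when calibrated; the ``units`` column
    says which scale each row uses ("cm" or "px").
    """
    if not records:
        raise ValueError("write_measurements requires at least one record")
    path = Path(path)
    cols = measurement_columns(records)
    rows = []
    prov = {}
    for r in records:
        row: dict[str, object] = {
            "image_id": r.image_id,
            "region": r.descriptor.region if r.descriptor else "",
            "plane": r.descriptor.plane if r.descriptor else "",
            "units": r.units,
            "flags": ";".join(r.flags),
        }
        row.update(r.values)
        row.update(r.texture)
        rows.append(row)
        prov[r.image_id] = r.provenance
    frame = pd.DataFrame(rows, columns=cols)
    try:
        frame.to_csv(path, index=False, float_format=None)
        sidecar = path.with_name(path.name + ".provenance.json")
        sidecar.write_text(json.dumps(prov, indent=2, sort_keys=True, default=str))
    except OSError as exc:
        raise ImageReadError(f"{path}: cannot write measurements ({exc})") from exc
    return path


def read_measurements(path) -> pd.DataFrame:
    """Read a measurement CSV back into a DataFrame (image_id as str)."""
    return pd.read_csv(Path(path), dtype={"image_id": str}, float_precision="round_trip")
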