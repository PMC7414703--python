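"""Reading and writing en-face OCTA rasters, binary masks and visit manifests.

Physical bookkeeping is the point of this module: every raster carries its
lateral pixel size in millimetres so downstream areas are computed in physical
units (``pixel count × pixel_size_mm²``) and the pipeline stays
resolution-independent.  Coordinate convention throughout the package:
row-major, origin top-left, 0-based indices.

Images are single-channel 8- or 16-bit TIFF or PNG.  Metadata lives in a JSON
sidecar with the same basename and a ``.json`` suffix (so PNG and TIFF inputs
are symmetric); intensities are never rescaled at read time — normalisation is
an explicit pipeline step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .errors import ContractError, FormatError, ManifestError, MetadataError

__all__ = [
    "EnFaceImage",
    "BinaryMask",
    "VisitRecord",
    "VisitManifest",
    "MASK_ROLES",
    "PLEXUSES",
    "TIMEPOINTS",
    "read_enface",
    "read_mask",
    "write_mask",
    "load_manifest",
]

PLEXUSES = ("SCP", "DCP", "unspecified")
TIMEPOINTS = ("T0", "T1", "T2", "T3")
EYES = ("OD", "OS")
MASK_ROLES = (
    "vessel",
    "large_vessel",
    "ischemia_candidate",
    "ischemia_final",
    "grader_edit_add",
    "grader_edit_remove",
)


@dataclass(frozen=True)
class EnFaceImage:
    """A 2-D en-face OCTA slab projection with physical pixel size.

    Parameters
    ----------
    pixels
        Nonnegative (or, after high-pass filtering, signed) intensities in
        arbitrary device units; stored as float64.
    pixel_size_mm
        Lateral pixel edge length in millimetres (> 0).
    field_mm
        Optional ``(height_mm, width_mm)`` of the scan field.  Must agree with
        ``shape × pixel_size_mm`` to within one pixel.
    plexus
        "SCP", "DCP" or "unspecified".
    source_id
        Free-text provenance string.
    """

    pixels: np.ndarray
    pixel_size_mm: float
    field_mm: tuple[float, float] | None = None
    plexus: str = "unspecified"
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        object.__setattr__(self, "pixels", px)
        if px.ndim != 2 or px.shape[0] < 2 or px.shape[1] < 2:
            raise ContractError(
                f"en-face raster must be 2-D with >= 2 rows and columns, got shape {px.shape}"
            )
        if not np.all(np.isfinite(px)):
            raise ContractError("en-face raster contains non-finite intensities")
        if not (self.pixel_size_mm > 0):
            raise MetadataError(f"pixel_size_mm must be > 0, got {self.pixel_size_mm}")
        if self.plexus not in PLEXUSES:
            raise MetadataError(f"plexus must be one of {PLEXUSES}, got {self.plexus!r}")
        if self.field_mm is not None:
            h, w = self.field_mm
            object.__setattr__(self, "field_mm", (float(h), float(w)))
            tol = self.pixel_size_mm  # one pixel
            if abs(px.shape[0] * self.pixel_size_mm - h) > tol or abs(
                px.shape[1] * self.pixel_size_mm - w
            ) > tol:
                raise MetadataError(
                    f"field_mm {self.field_mm} inconsistent with shape {px.shape} "
                    f"at {self.pixel_size_mm} mm/px (tolerance: one pixel)"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def scan_area_mm2(self) -> float:
        """Physical area covered by the raster, in mm²."""
        r, c = self.pixels.shape
        return r * c * self.pixel_size_mm**2

    def with_pixels(self, pixels: np.ndarray) -> "EnFaceImage":
        """Same metadata, new raster (used by pipeline stages)."""
        return replace(self, pixels=pixels)


@dataclass(frozen=True)
class BinaryMask:
    """A strictly binary raster aligned with a parent :class:`EnFaceImage`."""

    pixels: np.ndarray
    pixel_size_mm: float
    role: str = "vessel"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ContractError(f"mask must be 2-D, got shape {px.shape}")
        if px.dtype != np.uint8:
            vals = np.unique(px)
            if not np.all(np.isin(vals, (0, 1))):
                raise ContractError(f"mask values must be in {{0, 1}}, found {vals[:10]}")
            px = px.astype(np.uint8)
        elif px.size and px.max() > 1:
            raise ContractError("uint8 mask values must be in {0, 1}")
        object.__setattr__(self, "pixels", px)
        if not (self.pixel_size_mm > 0):
            raise MetadataError(f"pixel_size_mm must be > 0, got {self.pixel_size_mm}")
        if self.role not in MASK_ROLES:
            raise ContractError(f"unknown mask role {self.role!r}; expected one of {MASK_ROLES}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def astype_bool(self) -> np.ndarray:
        return self.pixels.astype(bool)

    @property
    def pixel_count(self) -> int:
        return int(self.pixels.sum())

    @property
    def area_mm2(self) -> float:
        return self.pixel_count * self.pixel_size_mm**2


@dataclass(frozen=True)
class VisitRecord:
    patient_id: str
    eye: str
    plexus: str
    timepoint: str
    image_path: Path
    edit_mask_paths: tuple[Path, ...] = ()

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (self.patient_id, self.eye, self.plexus, self.timepoint)


@dataclass(frozen=True)
class VisitManifest:
    """Validated list of visit records; keys (patient, eye, plexus, timepoint) unique."""

    records: tuple[VisitRecord, ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "patient_id": r.patient_id,
                    "eye": r.eye,
                    "plexus": r.plexus,
                    "timepoint": r.timepoint,
                    "image_path": str(r.image_path),
                }
                for r in self.records
            ]
        )


def _read_raster(path: Path) -> np.ndarray:
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    elif suffix == ".png":
        with Image.open(path) as im:
            if im.mode not in ("L", "I", "I;16", "1"):
                raise FormatError(
                    f"{path}: expected single-channel grayscale PNG, got mode {im.mode!r}"
                )
            arr = np.asarray(im)
    else:
        raise FormatError(f"{path}: unsupported image format {suffix!r} (use TIFF or PNG)")
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected single-channel 2-D raster, got shape {arr.shape}")
    if arr.size == 0 or min(arr.shape) < 2:
        raise FormatError(f"{path}: zero-sized or degenerate raster of shape {arr.shape}")
    return arr


def read_enface(
    path: str | Path,
    sidecar: str | Path | None = None,
    *,
    pixel_size_mm: float | None = None,
    plexus: str | None = None,
) -> EnFaceImage:
    """Read an 8/16-bit single-channel TIFF or PNG as an :class:`EnFaceImage`.

    The JSON sidecar (explicit path, or ``<basename>.json`` next to the image
    if present) supplies ``pixel_size_mm`` and optionally ``field_mm`` and
    ``plexus``.  If no sidecar is available, ``pixel_size_mm`` must be passed.
    Intensities are cast to float64 but never rescaled.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    arr = _read_raster(path)

    meta: dict = {}
    sidecar_path = Path(sidecar) if sidecar is not None else path.with_suffix(".json")
    if sidecar is not None and not sidecar_path.exists():
        raise FileNotFoundError(f"sidecar not found: {sidecar_path}")
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())

    ps = pixel_size_mm if pixel_size_mm is not None else meta.get("pixel_size_mm")
    if ps is None:
        raise MetadataError(
            f"{path}: no pixel_size_mm in sidecar and none passed by caller"
        )
    if not (float(ps) > 0):
        raise MetadataError(f"{path}: pixel_size_mm must be positive, got {ps}")
    field_mm = meta.get("field_mm")
    if field_mm is not None:
        field_mm = (float(field_mm[0]), float(field_mm[1]))
    px = plexus if plexus is not None else meta.get("plexus", "unspecified")
    return EnFaceImage(
        pixels=arr.astype(np.float64),
        pixel_size_mm=float(ps),
        field_mm=field_mm,
        plexus=px,
        source_id=str(path),
    )


def write_enface(image: EnFaceImage, path: str | Path) -> None:
    """Write an image as 16-bit TIFF plus its JSON sidecar (for phantoms)."""
    path = Path(path)
    px = image.pixels
    lo, hi = float(px.min()), float(px.max())
    scale = 65535.0 / (hi - lo) if hi > lo else 1.0
    arr = np.round((px - lo) * scale).astype(np.uint16)
    tifffile.imwrite(path, arr)
    meta = {"pixel_size_mm": image.pixel_size_mm, "plexus": image.plexus}
    if image.field_mm is not None:
        meta["field_mm"] = list(image.field_mm)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a binary mask as an 8-bit PNG with 0/255 encoding (lossless)."""
    path = Path(path)
    arr = (mask.pixels.astype(np.uint8) * 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path, format="PNG")


def read_mask(path: str | Path, pixel_size_mm: float, role: str = "vessel") -> BinaryMask:
    """Read an 8-bit 0/255 PNG mask written by :func:`write_mask`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask not found: {path}")
    with Image.open(path) as im:
        if im.mode != "L":
            raise FormatError(f"{path}: mask PNG must be 8-bit grayscale, got mode {im.mode!r}")
        arr = np.asarray(im)
    bad = np.setdiff1d(np.unique(arr), (0, 255))
    if bad.size:
        raise FormatError(f"{path}: mask values must be 0 or 255, found {bad[:10]}")
    return BinaryMask(pixels=(arr == 255).astype(np.uint8), pixel_size_mm=pixel_size_mm, role=role)


_REQUIRED_COLUMNS = ("patient_id", "eye", "plexus", "timepoint", "image_path")


def load_manifest(path: str | Path, *, check_paths: bool = True) -> VisitManifest:
    """Load and validate a visit manifest CSV.

    Required columns: patient_id, eye (OD/OS), plexus (SCP/DCP), timepoint
    (T0–T3), image_path.  Optional column ``edit_mask_paths`` holds
    semicolon-separated grader-edit mask paths.  Relative paths resolve
    against the manifest's directory.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"{path}: missing required columns {missing}")

    base = path.parent
    records: list[VisitRecord] = []
    seen: set[tuple[str, str, str, str]] = set()
    for i, row in df.iterrows():
        eye, plexus, tp = row["eye"], row["plexus"], row["timepoint"]
        if eye not in EYES:
            raise ManifestError(f"{path} row {i}: eye must be one of {EYES}, got {eye!r}")
        if plexus not in ("SCP", "DCP"):
            raise ManifestError(f"{path} row {i}: plexus must be SCP or DCP, got {plexus!r}")
        if tp not in TIMEPOINTS:
            raise ManifestError(f"{path} row {i}: timepoint must be one of {TIMEPOINTS}, got {tp!r}")
        img = Path(row["image_path"])
        if not img.is_absolute():
            img = base / img
        if check_paths and not img.exists():
            raise ManifestError(f"{path} row {i}: image path not resolvable: {img}")
        edits: tuple[Path, ...] = ()
        if "edit_mask_paths" in df.columns and row["edit_mask_paths"]:
            edit_list = []
            for p in row["edit_mask_paths"].split(";"):
                ep = Path(p.strip())
                if not ep.is_absolute():
                    ep = base / ep
                if check_paths and not ep.exists():
                    raise ManifestError(f"{path} row {i}: edit mask path not resolvable: {ep}")
                edit_list.append(ep)
            edits = tuple(edit_list)
        rec = VisitRecord(row["patient_id"], eye, plexus, tp, img, edits)
        if rec.key in seen:
            raise ManifestError(f"{path} row {i}: duplicate key {rec.key}")
        seen.add(rec.key)
        records.append(rec)
    return VisitManifest(records=tuple(records))
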