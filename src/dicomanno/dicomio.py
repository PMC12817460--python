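"""DICOM ingestion: header extraction, polarity normalization, PNG export.

Reads standard Part-10 files with pydicom, pulls the header fields the
annotation pipeline uses (notably Body Part Examined, (0018,0015)) into a
flat record, and converts pixel data to 8-bit grayscale PNG.  Radiographs
arrive in two polarities — MONOCHROME2 (dark background) and MONOCHROME1 or
ad-hoc inverted scans (light background) — and are normalized to dark
background before any downstream processing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import pydicom
from PIL import Image

logger = logging.getLogger(__name__)

HEADER_COLUMNS = [
    "sop_uid",
    "modality",
    "body_part_examined",
    "photometric_interpretation",
    "manufacturer",
    "acquisition_date",
    "path",
]


class DicomReadError(IOError):
    """File could not be parsed as DICOM."""


class MissingPixelDataError(DicomReadError):
    """Parsable DICOM without pixel data (e.g. a structured report)."""


@dataclass(frozen=True)
class DicomHeaderRecord:
    sop_uid: str
    modality: str | None = None
    body_part_examined_raw: str | None = None
    photometric_interpretation: str | None = None
    manufacturer: str | None = None
    acquisition_date: str | None = None


@dataclass
class ImageRecord:
    """A decoded image plus its header; labels are attached by annotation."""

    header: DicomHeaderRecord
    pixels: np.ndarray
    labels_examined: object | None = None
    labels_visible: set = field(default_factory=set)


def _get(ds: pydicom.Dataset, keyword: str) -> str | None:
    value = getattr(ds, keyword, None)
    if value is None or value == "":
        return None
    return str(value)


def read_image(path: str | Path) -> ImageRecord:
    """Read a Part-10 DICOM file into an :class:`ImageRecord`.

    Absent header tags stay ``None`` — they are never invented.  Pixel values
    are decoded at native bit depth (no rescale loss).
    """
    try:
        ds = pydicom.dcmread(str(path))
    except Exception as exc:  # pydicom raises several error types
        raise DicomReadError(f"cannot parse {path}: {exc}") from exc
    if "PixelData" not in ds:
        raise MissingPixelDataError(f"{path} has no pixel data")
    header = DicomHeaderRecord(
        sop_uid=_get(ds, "SOPInstanceUID") or str(path),
        modality=_get(ds, "Modality"),
        body_part_examined_raw=_get(ds, "BodyPartExamined"),
        photometric_interpretation=_get(ds, "PhotometricInterpretation"),
        manufacturer=_get(ds, "Manufacturer"),
        acquisition_date=_get(ds, "AcquisitionDate"),
    )
    pixels = ds.pixel_array
    if pixels.ndim != 2:
        pixels = np.squeeze(pixels)
    return ImageRecord(header=header, pixels=pixels)


def _looks_inverted(pixels: np.ndarray) -> bool:
    """Border heuristic: light background ⇒ inverted.

    An image is deemed inverted when the median of a 5%-wide border frame
    exceeds the median of the central half of the image (the subject region).
    Used only when Photometric Interpretation is absent.
    """
    h, w = pixels.shape
    b = max(1, int(round(0.05 * min(h, w))))
    border = np.concatenate(
        [
            pixels[:b, :].ravel(),
            pixels[-b:, :].ravel(),
            pixels[b:-b, :b].ravel(),
            pixels[b:-b, -b:].ravel(),
        ]
    )
    center = pixels[h // 4 : h - h // 4, w // 4 : w - w // 4]
    return float(np.median(border)) > float(np.median(center))


def normalize_polarity(rec: ImageRecord) -> ImageRecord:
    """Return a record whose background is dark (idempotent).

    MONOCHROME1 images are intensity-complemented (v -> max - v) and
    relabeled MONOCHROME2; when the tag is absent, a light-background border
    heuristic decides.  Applying twice equals applying once.
    """
    pi = rec.header.photometric_interpretation
    if pi is not None:
        inverted = pi.upper() == "MONOCHROME1"
    else:
        inverted = _looks_inverted(rec.pixels)
    if not inverted:
        return rec
    flipped = rec.pixels.max() - rec.pixels
    header = replace(rec.header, photometric_interpretation="MONOCHROME2")
    return ImageRecord(
        header=header,
        pixels=flipped,
        labels_examined=rec.labels_examined,
        labels_visible=set(rec.labels_visible),
    )


def headers_to_table(paths: list[str | Path]) -> pd.DataFrame:
    """Extract headers from many files into one table (one row per image).

    Unreadable files are logged and skipped; absent tags become empty cells.
    Column order is fixed (:data:`HEADER_COLUMNS`).
    """
    rows = []
    for path in paths:
        try:
            rec = read_image(path)
        except DicomReadError as exc:
            logger.warning("skipping unreadable file: %s", exc)
            continue
        h = rec.header
        rows.append(
            {
                "sop_uid": h.sop_uid,
                "modality": h.modality or "",
                "body_part_examined": h.body_part_examined_raw or "",
                "photometric_interpretation": h.photometric_interpretation or "",
                "manufacturer": h.manufacturer or "",
                "acquisition_date": h.acquisition_date or "",
                "path": str(path),
            }
        )
    return pd.DataFrame(rows, columns=HEADER_COLUMNS)


def to_uint8(pixels: np.ndarray) -> np.ndarray:
    """Min-max scale to 8-bit; a constant image maps to mid-gray (128)."""
    pixels = np.asarray(pixels, dtype=float)
    lo, hi = pixels.min(), pixels.max()
    if hi == lo:
        return np.full(pixels.shape, 128, dtype=np.uint8)
    return np.round((pixels - lo) / (hi - lo) * 255.0).astype(np.uint8)


def export_png(rec: ImageRecord | np.ndarray, path: str | Path) -> Path:
    """Write the image as an 8-bit grayscale PNG (deterministic bytes)."""
    pixels = rec.pixels if isinstance(rec, ImageRecord) else rec
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(to_uint8(pixels), mode="L").save(path, format="PNG")
    return path


def ingest(
    in_dir: str | Path,
    out_table: str | Path | None = None,
    out_png: str | Path | None = None,
    normalize: bool = True,
) -> pd.DataFrame:
    """Directory walker: header table + optional PNG conversion for a corpus."""
    paths = sorted(p for p in Path(in_dir).rglob("*.dcm"))
    table = headers_to_table(paths)
    if out_png is not None:
        out_png = Path(out_png)
        for path in table["path"]:
            rec = read_image(path)
            if normalize:
                rec = normalize_polarity(rec)
            export_png(rec, out_png / (Path(path).stem + ".png"))
    if out_table is not None:
        table.to_csv(out_table, index=False)
    return table
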