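"""Image, timestamp, annotation and tabular I/O.

All file-format dialects of the package live here: JPEG/PNG images in,
PNG overlays out, CSV dialects for manual flowering-panicle counts (FPN),
per-image detection summaries and per-region rectangles.

Timestamps are resolved EXIF-first (``DateTimeOriginal``), falling back to a
strftime-style pattern matched against the file name, and are simply absent
when neither source parses.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image as PILImage
from PIL import ExifTags, UnidentifiedImageError

__all__ = [
    "Image",
    "CountAnnotation",
    "load_image",
    "save_image",
    "to_luminance",
    "resize_image",
    "parse_timestamp",
    "read_annotations",
    "write_annotations",
    "write_detection_summary",
    "write_regions",
]

#: Default strftime-style pattern searched for inside file names.
DEFAULT_TIMESTAMP_PATTERN = "%Y%m%d_%H%M"

# Rec.601 luma weights; the conversion is deliberately kept in real values.
_LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])

_EXIF_DATETIME_ORIGINAL = 36867


@dataclass
class Image:
    """An RGB raster with its derived luminance plane and optional timestamp.

    Attributes
    ----------
    pixels : ndarray of uint8, shape (H, W, 3)
    luminance : ndarray of float64, shape (H, W)
        Rec.601 luma, real-valued in [0, 255]; never re-quantized.
    timestamp : datetime or None
        Acquisition instant at minute resolution, if known.
    source_path : str
    """

    pixels: np.ndarray
    luminance: np.ndarray
    timestamp: datetime | None = None
    source_path: str = ""

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @classmethod
    def from_pixels(
        cls,
        pixels: np.ndarray,
        timestamp: datetime | None = None,
        source_path: str = "",
    ) -> "Image":
        pixels = np.asarray(pixels, dtype=np.uint8)
        return cls(
            pixels=pixels,
            luminance=to_luminance(pixels),
            timestamp=timestamp,
            source_path=source_path,
        )


@dataclass(frozen=True)
class CountAnnotation:
    """A manually counted number of flowering panicles (FPN) at one instant."""

    timestamp: datetime
    fpn: int

    def __post_init__(self) -> None:
        if self.fpn < 0:
            raise ValueError(f"fpn must be >= 0, got {self.fpn}")


def to_luminance(pixels: np.ndarray) -> np.ndarray:
    """Rec.601 luminance 0.299*R + 0.587*G + 0.114*B as float64."""
    pixels = np.asarray(pixels)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB raster, got shape {pixels.shape}")
    return pixels.astype(np.float64) @ _LUMA_WEIGHTS


def _pattern_to_regex(pattern: str) -> re.Pattern:
    """Translate a strftime-style filename template into a search regex."""
    widths = {"Y": 4, "m": 2, "d": 2, "H": 2, "M": 2, "S": 2, "y": 2, "j": 3}
    out = []
    i = 0
    while i < len(pattern):
        ch = pattern[i]
        if ch == "%" and i + 1 < len(pattern):
            code = pattern[i + 1]
            if code not in widths:
                raise ValueError(f"unsupported strftime code %{code} in pattern {pattern!r}")
            out.append(r"\d{%d}" % widths[code])
            i += 2
        else:
            out.append(re.escape(ch))
            i += 1
    return re.compile("".join(out))


def _timestamp_from_filename(path: Path, pattern: str) -> datetime | None:
    m = _pattern_to_regex(pattern).search(path.name)
    if m is None:
        return None
    try:
        return datetime.strptime(m.group(0), pattern)
    except ValueError:
        return None


def _timestamp_from_exif(pil_img: PILImage.Image) -> datetime | None:
    try:
        exif = pil_img.getexif()
        value = exif.get_ifd(ExifTags.IFD.Exif).get(_EXIF_DATETIME_ORIGINAL)
        if value is None:
            value = exif.get(_EXIF_DATETIME_ORIGINAL)
        if not value:
            return None
        return datetime.strptime(str(value).strip(), "%Y:%m:%d %H:%M:%S")
    except Exception:
        return None


def parse_timestamp(path: str | Path, pattern: str = DEFAULT_TIMESTAMP_PATTERN) -> datetime | None:
    """Resolve an acquisition instant for an image file, or ``None``.

    EXIF ``DateTimeOriginal`` takes precedence; the filename pattern is the
    fallback. Never raises on unparseable sources.
    """
    path = Path(path)
    if path.exists():
        try:
            with PILImage.open(path) as img:
                ts = _timestamp_from_exif(img)
            if ts is not None:
                return ts
        except Exception:
            pass
    return _timestamp_from_filename(path, pattern)


def load_image(path: str | Path, timestamp_pattern: str = DEFAULT_TIMESTAMP_PATTERN) -> Image:
    """Load a JPEG/PNG file into an :class:`Image` (converting to RGB)."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"image file not found: {path}")
    try:
        with PILImage.open(path) as img:
            ts = _timestamp_from_exif(img)
            rgb = img.convert("RGB")
            pixels = np.asarray(rgb, dtype=np.uint8)
    except UnidentifiedImageError as exc:
        raise IOError(f"unreadable image file: {path}") from exc
    except OSError as exc:
        raise IOError(f"failed to read image file: {path}") from exc
    if ts is None:
        ts = _timestamp_from_filename(path, timestamp_pattern)
    return Image(
        pixels=pixels,
        luminance=to_luminance(pixels),
        timestamp=ts,
        source_path=str(path),
    )


def save_image(img: Image | np.ndarray, path: str | Path) -> None:
    """Write an RGB raster to disk (format chosen from the suffix)."""
    pixels = img.pixels if isinstance(img, Image) else np.asarray(img, dtype=np.uint8)
    PILImage.fromarray(pixels, mode="RGB").save(path)


def resize_image(img: Image, factor: float) -> Image:
    """Bilinear resize to floor(H*factor) x floor(W*factor); timestamp kept.

    ``factor`` must lie in (0, 1]; 1.0 is the exact identity.
    """
    if not 0.0 < factor <= 1.0:
        raise ValueError(f"resize factor must be in (0, 1], got {factor}")
    if factor == 1.0:
        return replace(img, pixels=img.pixels.copy(), luminance=img.luminance.copy())
    new_h = int(img.height * factor)
    new_w = int(img.width * factor)
    if new_h < 1 or new_w < 1:
        raise ValueError(
            f"resize factor {factor} collapses a {img.height}x{img.width} image"
        )
    pil = PILImage.fromarray(img.pixels, mode="RGB")
    resized = np.asarray(pil.resize((new_w, new_h), PILImage.Resampling.BILINEAR), dtype=np.uint8)
    return Image(
        pixels=resized,
        luminance=to_luminance(resized),
        timestamp=img.timestamp,
        source_path=img.source_path,
    )


# ---------------------------------------------------------------------------
# CSV dialects
# ---------------------------------------------------------------------------

def _read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_annotations(path: str | Path) -> list[CountAnnotation]:
    """Read the FPN annotation CSV (``timestamp,fpn``; ISO-8601 timestamps)."""
    df = _read_csv(path)
    missing = {"timestamp", "fpn"} - set(df.columns)
    if missing:
        raise ValueError(f"annotation file {path} lacks columns: {sorted(missing)}")
    anns = [
        CountAnnotation(timestamp=datetime.fromisoformat(str(row.timestamp)), fpn=int(row.fpn))
        for row in df.itertuples()
    ]
    seen: dict[datetime, int] = {}
    for a in anns:
        seen[a.timestamp] = seen.get(a.timestamp, 0) + 1
    dupes = sorted(t for t, c in seen.items() if c > 1)
    if dupes:
        raise ValueError(f"duplicate annotation timestamps in {path}: {dupes}")
    return anns


def _write_csv(df: pd.DataFrame, path: str | Path, header_comment: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)


def write_annotations(annotations: list[CountAnnotation], path: str | Path,
                      header_comment: str | None = None) -> None:
    df = pd.DataFrame(
        {
            "timestamp": [a.timestamp.isoformat() for a in annotations],
            "fpn": [a.fpn for a in annotations],
        }
    )
    _write_csv(df, path, header_comment)


def write_detection_summary(rows: list[dict], path: str | Path,
                            header_comment: str | None = None) -> None:
    """Per-image detection CSV: ``timestamp,image,fbn,fcbn``."""
    df = pd.DataFrame(rows, columns=["timestamp", "image", "fbn", "fcbn"])
    _write_csv(df, path, header_comment)


def write_regions(rows: list[dict], path: str | Path,
                  header_comment: str | None = None) -> None:
    """Per-region CSV: ``image,region_id,x_min,y_min,x_max,y_max``.

    Coordinates are 0-based, half-open pixel rectangles.
    """
    df = pd.DataFrame(
        rows, columns=["image", "region_id", "x_min", "y_min", "x_max", "y_max"]
    )
    _write_csv(df, path, header_comment)
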