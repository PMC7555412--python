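"""Image and table I/O.

Images are read from TIFF or PNG into ``RgbImage`` with intensities normalized
to [0, 1] by the dtype maximum (the 0.72 threshold and 0.43137 reference mean
are defined on that scale).  Grayscale inputs are replicated to three channels
and an alpha channel, if present, is dropped, so the blue-channel extraction
step is always well defined.

Tables travel as delimited text (TSV by default) with explicit schemas:
diffable, mergeable, and exactly round-trippable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .errors import ImageFormatError, SchemaError

log = logging.getLogger("mgmorph.io")

# ---------------------------------------------------------------------------
# Images


@dataclass(frozen=True)
class RgbImage:
    """A 3-channel raster with all intensities in [0, 1], channel order R,G,B."""

    pixels: np.ndarray  # (H, W, 3) float64 in [0, 1]
    source_path: str = "<memory>"
    bit_depth_origin: int = 8

    def __post_init__(self) -> None:
        p = self.pixels
        if p.ndim != 3 or p.shape[2] != 3:
            raise ImageFormatError(f"RgbImage needs shape (H, W, 3), got {p.shape}")
        if p.shape[0] < 1 or p.shape[1] < 1:
            raise ImageFormatError("image must be at least 1x1")
        if p.min() < 0.0 or p.max() > 1.0:
            raise ImageFormatError("RgbImage intensities must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


def _dtype_max(arr: np.ndarray) -> float:
    if np.issubdtype(arr.dtype, np.integer):
        return float(np.iinfo(arr.dtype).max)
    if np.issubdtype(arr.dtype, np.floating):
        # float images are assumed already on [0, 1]
        return 1.0
    raise ImageFormatError(f"unsupported image dtype {arr.dtype}")


def read_image(path: str | Path) -> RgbImage:
    """Read a TIFF or PNG as an RgbImage normalized to [0, 1].

    1-channel images are replicated to RGB; a 4th (alpha) channel is dropped.
    """
    path = Path(path)
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            raw = tifffile.imread(path)
        else:
            raw = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - decoding failures become I/O errors
        raise IOError(f"cannot read image {path}: {exc}") from exc

    raw = np.asarray(raw)
    bit_depth = 16 if raw.dtype.itemsize >= 2 and np.issubdtype(raw.dtype, np.integer) else 8
    scaled = raw.astype(np.float64) / _dtype_max(raw)

    if scaled.ndim == 2:
        scaled = np.stack([scaled] * 3, axis=-1)
    elif scaled.ndim == 3 and scaled.shape[2] == 4:
        scaled = scaled[:, :, :3]
    elif scaled.ndim == 3 and scaled.shape[2] == 3:
        pass
    else:
        raise ImageFormatError(
            f"{path}: expected 1, 3, or 4 channels, got shape {raw.shape}"
        )
    scaled = np.clip(scaled, 0.0, 1.0)
    log.info("read %s: %dx%d, origin %d-bit", path, *scaled.shape[:2], bit_depth)
    return RgbImage(pixels=scaled, source_path=str(path), bit_depth_origin=bit_depth)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write an integer label mask (or boolean mask) as 16-bit TIFF/PNG."""
    path = Path(path)
    arr = np.asarray(mask)
    if arr.dtype == bool:
        arr = arr.astype(np.uint16)
    if arr.max(initial=0) > np.iinfo(np.uint16).max:
        raise ImageFormatError("label values exceed 16-bit range")
    arr = arr.astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


def read_mask(path: str | Path) -> np.ndarray:
    """Read an integer label mask written by :func:`write_mask`."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    return np.asarray(arr).astype(np.int64)


# ---------------------------------------------------------------------------
# Tables

#: The 10-measurement shape panel recorded for every detected object.
FEATURE_PANEL: tuple[str, ...] = (
    "area_px",
    "perimeter_px",
    "radius_max",
    "radius_min",
    "radius_mean",
    "radius_sd",
    "centroid_row",
    "centroid_col",
    "eccentricity",
    "angle",
)

#: Panel columns describing intrinsic morphology: position (centroid) and
#: in-plane orientation (angle) are excluded, since neither should influence
#: a cell's activation-state assignment.
MORPHOLOGY_PANEL: tuple[str, ...] = tuple(
    c for c in FEATURE_PANEL if not c.startswith("centroid") and c != "angle"
)

FEATURE_TABLE_COLUMNS: tuple[str, ...] = ("object_id", "image_id", *FEATURE_PANEL)
LABEL_TABLE_COLUMNS: tuple[str, ...] = (
    "cell_id",
    "genotype",
    "cell_type",
    "embed_x",
    "embed_y",
)
OBJECT_LABEL_COLUMNS: tuple[str, ...] = ("object_id", "image_id", "label")


def write_table(rows: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    """Write a DataFrame as delimited UTF-8 text with a header row."""
    rows.to_csv(path, sep=sep, index=False, encoding="utf-8")


def read_table(
    path: str | Path,
    schema: Sequence[str] | None = None,
    sep: str = "\t",
) -> pd.DataFrame:
    """Read a delimited table, optionally enforcing that the header contains
    exactly the ``schema`` columns (order-insensitive beyond the schema prefix).

    Raises ``SchemaError`` listing missing and extra columns on mismatch.
    """
    df = pd.read_csv(path, sep=sep, encoding="utf-8")
    if schema is not None:
        missing = [c for c in schema if c not in df.columns]
        extra = [c for c in df.columns if c not in schema]
        if missing or extra:
            raise SchemaError(
                f"{path}: header mismatch; missing columns {missing}, extra columns {extra}"
            )
        df = df[list(schema)]
    return df


def check_feature_table(df: pd.DataFrame, require_panel: bool = True) -> None:
    """Validate the structural invariants of an object feature table."""
    needed = FEATURE_TABLE_COLUMNS if require_panel else ("object_id", "image_id")
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"feature table missing columns {missing}")
    if require_panel and len(df):
        if df[list(FEATURE_PANEL)].isna().any().any():
            raise SchemaError("feature table contains missing values in the panel")
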