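"""Iba1 object detection: blue channel -> intensity scaling -> negative
threshold -> hole filling -> connected-component labeling -> shape features
-> area gate.

The stained (dark, DAB-positive) structures are segmented by scaling the blue
channel by ``1.55 * m / 0.43137`` (``m`` = mean blue intensity), taking the
photographic negative, and keeping pixels strictly brighter than 0.72 in the
negative — i.e. the stained objects.  Holes inside objects are filled, and
connected components become candidate objects for which the 10-measurement
shape panel (area, perimeter, radius min/max/mean/SD, centroid, eccentricity,
angle) is recorded.  Only objects strictly between 50 and 3,000 pixels in
area are kept for classification.

Conventions (chosen once, used everywhere):

* Coordinates are 0-based (row, col), origin at the top-left.
* Perimeter is the count of object pixels with at least one background
  4-neighbor; the raster border counts as background.
* Radii are Euclidean distances from the centroid (mean of all object pixels)
  to each perimeter pixel; the SD uses the population (n) denominator.
* Eccentricity and angle derive from the central second moments of the pixel
  set: with mu20/mu02/mu11 (x = column, y = row), the covariance eigenvalues
  l1 >= l2 give eccentricity sqrt(1 - l2/l1), and the angle is
  0.5*atan2(2*mu11, mu20 - mu02), measured from the column axis, in
  (-pi/2, pi/2].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import PipelineConfig
from .errors import ImageFormatError
from .io import FEATURE_TABLE_COLUMNS, RgbImage

log = logging.getLogger("mgmorph.segmentation")

__all__ = [
    "GrayImage",
    "extract_blue_channel",
    "scale_intensity",
    "negative_threshold",
    "fill_holes",
    "label_objects",
    "extract_features",
    "size_filter",
    "run_detection",
]


@dataclass(frozen=True)
class GrayImage:
    """Single-channel raster in [0, 1] at a named pipeline stage."""

    pixels: np.ndarray
    stage: str  # "blue" | "scaled" | "negative"

    def __post_init__(self) -> None:
        p = self.pixels
        if p.ndim != 2:
            raise ImageFormatError(f"GrayImage needs a 2-D raster, got shape {p.shape}")
        if p.size and (p.min() < 0.0 or p.max() > 1.0):
            raise ImageFormatError("GrayImage intensities must lie in [0, 1]")


def extract_blue_channel(image: RgbImage) -> GrayImage:
    """Step 1: return the blue plane (channel index 2 of R,G,B)."""
    return GrayImage(pixels=image.pixels[:, :, 2].copy(), stage="blue")


def scale_intensity(gray: GrayImage, cfg: PipelineConfig) -> GrayImage:
    """Step 2: multiply by ``scale_numerator * m / scale_reference_mean`` where
    ``m`` is the mean intensity of the input plane; clip to [0, 1]."""
    if gray.stage != "blue":
        raise ValueError(f"scale_intensity expects stage 'blue', got {gray.stage!r}")
    m = float(gray.pixels.mean())
    factor = cfg.scale_numerator * m / cfg.scale_reference_mean
    if m == 0.0:
        log.warning("scale_intensity: all-zero image (m=0); returning zeros")
    log.info("scale_intensity: m=%.6f factor=%.6f", m, factor)
    scaled = np.clip(gray.pixels * factor, 0.0, 1.0)
    return GrayImage(pixels=scaled, stage="scaled")


def negative_threshold(gray: GrayImage, cfg: PipelineConfig) -> np.ndarray:
    """Step 3: photographic negative, then keep pixels strictly above the
    threshold as foreground — the stained (dark) structures."""
    if gray.stage != "scaled":
        raise ValueError(f"negative_threshold expects stage 'scaled', got {gray.stage!r}")
    negative = 1.0 - gray.pixels
    return negative > cfg.negative_threshold


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Step 4: fill every background region not connected to the raster border
    (EBImage's fillHull semantics).  Monotone and idempotent."""
    return ndimage.binary_fill_holes(np.asarray(mask, dtype=bool))


def _structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(2, 2 if connectivity == 8 else 1)


def label_objects(mask: np.ndarray, cfg: PipelineConfig) -> np.ndarray:
    """Step 5: label connected components 1..K in raster-scan order of each
    component's first pixel; 0 is background."""
    labeled, _ = ndimage.label(np.asarray(mask, dtype=bool), structure=_structure(cfg.connectivity))
    return labeled.astype(np.int64)


def _perimeter_mask(obj: np.ndarray) -> np.ndarray:
    """Object pixels with >=1 background 4-neighbor; border = background."""
    padded = np.pad(obj, 1, mode="constant", constant_values=False)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    return obj & ~interior


def extract_features(labeled: np.ndarray, image_id: str = "image") -> pd.DataFrame:
    """Record the 10-measurement shape panel for every labeled object.

    Returns one row per object (columns ``FEATURE_TABLE_COLUMNS``); an empty
    mask yields an empty table with the full header.
    """
    labeled = np.asarray(labeled)
    n_objects = int(labeled.max(initial=0))
    rows = []
    slices = ndimage.find_objects(labeled, max_label=n_objects)
    for obj_label in range(1, n_objects + 1):
        sl = slices[obj_label - 1]
        if sl is None:
            continue
        local = labeled[sl] == obj_label
        offset = np.array([sl[0].start, sl[1].start], dtype=np.float64)

        coords = np.argwhere(local).astype(np.float64)  # (N, 2) rows, cols
        area = coords.shape[0]
        centroid = coords.mean(axis=0)

        perim = np.argwhere(_perimeter_mask(local)).astype(np.float64)
        perimeter = perim.shape[0]
        radii = np.hypot(perim[:, 0] - centroid[0], perim[:, 1] - centroid[1])

        # central second moments; x = col, y = row
        d = coords - centroid
        mu20 = float(np.mean(d[:, 1] ** 2))
        mu02 = float(np.mean(d[:, 0] ** 2))
        mu11 = float(np.mean(d[:, 0] * d[:, 1]))
        trace = mu20 + mu02
        det = mu20 * mu02 - mu11**2
        disc = max(trace * trace / 4.0 - det, 0.0)
        l1 = trace / 2.0 + np.sqrt(disc)
        l2 = trace / 2.0 - np.sqrt(disc)
        eccentricity = float(np.sqrt(max(1.0 - l2 / l1, 0.0))) if l1 > 0 else 0.0
        angle = 0.5 * float(np.arctan2(2.0 * mu11, mu20 - mu02))
        if angle <= -np.pi / 2:
            angle += np.pi

        rows.append(
            {
                "object_id": obj_label,
                "image_id": image_id,
                "area_px": area,
                "perimeter_px": perimeter,
                "radius_max": float(radii.max()),
                "radius_min": float(radii.min()),
                "radius_mean": float(radii.mean()),
                "radius_sd": float(radii.std(ddof=0)),
                "centroid_row": float(centroid[0] + offset[0]),
                "centroid_col": float(centroid[1] + offset[1]),
                "eccentricity": eccentricity,
                "angle": angle,
            }
        )
    if not rows:
        return pd.DataFrame(columns=list(FEATURE_TABLE_COLUMNS))
    return pd.DataFrame(rows, columns=list(FEATURE_TABLE_COLUMNS))


def size_filter(features: pd.DataFrame, cfg: PipelineConfig) -> pd.DataFrame:
    """Keep objects with ``min_area_px < area < max_area_px`` (both strict)."""
    if not len(features):
        return features.copy()
    keep = (features["area_px"] > cfg.min_area_px) & (features["area_px"] < cfg.max_area_px)
    removed = int((~keep).sum())
    log.info("size_filter: kept %d, removed %d objects", int(keep.sum()), removed)
    return features.loc[keep].reset_index(drop=True)


def run_detection(
    image: RgbImage, cfg: PipelineConfig, image_id: str = "image"
) -> tuple[np.ndarray, pd.DataFrame]:
    """Full detection: steps 1-5, feature extraction, and the area gate.

    Returns the labeled mask (all objects, pre-gate) and the gated feature
    table.  Deterministic: no randomness anywhere in this path.
    """
    blue = extract_blue_channel(image)
    scaled = scale_intensity(blue, cfg)
    mask = negative_threshold(scaled, cfg)
    filled = fill_holes(mask)
    labeled = label_objects(filled, cfg)
    features = extract_features(labeled, image_id=image_id)
    gated = size_filter(features, cfg)
    log.info(
        "run_detection[%s]: %d objects, %d pass the (%d, %d) area gate",
        image_id, len(features), len(gated), cfg.min_area_px, cfg.max_area_px,
    )
    return labeled, gated
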