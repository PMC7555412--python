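"""Ground-truthed synthetic inputs for every pipeline stage.

The generator emulates the statistical structure each analysis stage assumes,
not histology appearance:

* ``generate_ihc_image`` renders a DAB/hematoxylin-like RGB frame containing
  planted microglia of three morphological archetypes — ``round`` (filled
  quasi-circular soma; activated), ``bushy`` (soma plus 2-4 short thick
  processes; activating), ``dendritic`` (small soma plus >=4 long thin
  branched processes; homeostatic) — plus debris in three flavors: specks
  below the 50-px gate, blobs above the 3,000-px gate, and mid-size irregular
  shapes that pass the gate and must be removed by the classifier.  Stain is
  rendered as a LOW blue-channel intensity (DAB brown has a weak blue
  component) so the blue-extraction / negation convention of the detection
  pipeline applies directly.  Every planted pixel set is recorded.
* ``generate_feature_training_set`` draws labeled cell / non-cell feature
  vectors from two multivariate Gaussians whose mean difference scales with a
  ``separation`` parameter (0 = exchangeable classes).
* ``generate_label_table`` draws genotype-stratified cell-type labels with
  stated proportions and per-type isotropic Gaussian embedding clouds.
* ``generate_slide_annotation`` draws quadrant positivity (Bernoulli) and
  CD3 counts (Poisson) for the histomorphometry arithmetic.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import draw as skdraw

from ._rng import stage_rng
from .errors import CapacityError, ConfigurationError
from .io import FEATURE_PANEL, FEATURE_TABLE_COLUMNS, LABEL_TABLE_COLUMNS, RgbImage

log = logging.getLogger("mgmorph.synthetic")

CELL_ARCHETYPES = ("round", "bushy", "dendritic")
DEBRIS_ARCHETYPES = ("debris_small", "debris_large", "debris_irregular")

#: archetype -> morphological state it is planted to represent
ARCHETYPE_STATE = {"round": "activated", "bushy": "activating", "dendritic": "homeostatic"}

# Defaults for the area gate the synthetic geometry is designed around.
_MIN_AREA, _MAX_AREA = 50, 3000


@dataclass(frozen=True)
class PlantedObject:
    object_id: int
    archetype: str
    centroid: tuple[float, float]  # (row, col)
    pixels: np.ndarray  # (N, 2) int rows/cols


@dataclass(frozen=True)
class SyntheticGroundTruth:
    """Registry of every planted object, paired with its generated image."""

    objects: list[PlantedObject]
    image_params: dict
    seed: int

    def by_archetype(self, *archetypes: str) -> list[PlantedObject]:
        return [o for o in self.objects if o.archetype in archetypes]

    @property
    def cells(self) -> list[PlantedObject]:
        return self.by_archetype(*CELL_ARCHETYPES)


@dataclass(frozen=True)
class SlideAnnotation:
    """Expert annotations for one slide: quadrant grid, positivity, CD3 counts,
    and optional myelin / white-matter masks."""

    slide_id: str
    genotype: str
    grid_rows: int
    grid_cols: int
    positive_quadrants: frozenset[tuple[int, int]]
    cd3_counts: np.ndarray  # (grid_rows, grid_cols) non-negative ints
    myelin_mask: np.ndarray | None = None
    white_matter_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        for (r, c) in self.positive_quadrants:
            if not (0 <= r < self.grid_rows and 0 <= c < self.grid_cols):
                raise ConfigurationError(f"positive quadrant ({r},{c}) outside grid")
        if self.cd3_counts.shape != (self.grid_rows, self.grid_cols):
            raise ConfigurationError("cd3_counts shape must match the grid")
        if (self.cd3_counts < 0).any():
            raise ConfigurationError("cd3_counts must be non-negative")


# ---------------------------------------------------------------------------
# archetype stamps (boolean canvases, later cropped to their bounding box)

_DISK1 = ndimage.generate_binary_structure(2, 2)  # 3x3 for width-3 dilation


def _line(canvas: np.ndarray, r0: float, c0: float, r1: float, c1: float) -> None:
    rr, cc = skdraw.line(int(round(r0)), int(round(c0)), int(round(r1)), int(round(c1)))
    ok = (rr >= 0) & (rr < canvas.shape[0]) & (cc >= 0) & (cc < canvas.shape[1])
    canvas[rr[ok], cc[ok]] = True


def _crop(canvas: np.ndarray) -> np.ndarray:
    rows = np.any(canvas, axis=1)
    cols = np.any(canvas, axis=0)
    return canvas[rows.argmax(): len(rows) - rows[::-1].argmax(),
                  cols.argmax(): len(cols) - cols[::-1].argmax()]


def _stamp_round(rng: np.random.Generator) -> np.ndarray:
    r = rng.uniform(9.0, 12.0)
    n = 2 * int(math.ceil(r)) + 3
    canvas = np.zeros((n, n), dtype=bool)
    rr, cc = skdraw.disk((n // 2, n // 2), r, shape=canvas.shape)
    canvas[rr, cc] = True
    return _crop(canvas)


def _stamp_bushy(rng: np.random.Generator) -> np.ndarray:
    soma = rng.uniform(7.5, 8.5)
    n_proc = int(rng.integers(3, 5))  # 3-4 short thick processes
    reach = soma + 13 + 2
    n = 2 * int(math.ceil(reach)) + 3
    canvas = np.zeros((n, n), dtype=bool)
    center = n // 2
    angles = rng.uniform(0, 2 * np.pi) + np.arange(n_proc) * 2 * np.pi / n_proc
    angles = angles + rng.uniform(-0.25, 0.25, size=n_proc)
    proc = np.zeros_like(canvas)
    for a in angles:
        length = soma + rng.uniform(9.0, 13.0)
        _line(proc, center, center, center + length * np.sin(a), center + length * np.cos(a))
    proc = ndimage.binary_dilation(proc, structure=_DISK1)  # width ~3
    rr, cc = skdraw.disk((center, center), soma, shape=canvas.shape)
    canvas[rr, cc] = True
    canvas |= proc
    return _crop(canvas)


def _stamp_dendritic(rng: np.random.Generator) -> np.ndarray:
    soma = rng.uniform(3.5, 5.0)
    n_proc = int(rng.integers(4, 7))  # >=4 long thin branched processes
    reach = soma + 30 + 2
    n = 2 * int(math.ceil(reach)) + 3
    canvas = np.zeros((n, n), dtype=bool)
    center = n // 2
    angles = rng.uniform(0, 2 * np.pi) + np.arange(n_proc) * 2 * np.pi / n_proc
    angles = angles + rng.uniform(-0.25, 0.25, size=n_proc)
    for a in angles:
        length = rng.uniform(18.0, 30.0)
        tip_r = center + length * np.sin(a)
        tip_c = center + length * np.cos(a)
        _line(canvas, center, center, tip_r, tip_c)
        # one branch per process from ~60% along, 30-55 degrees off
        frac = rng.uniform(0.5, 0.7)
        base_r = center + frac * length * np.sin(a)
        base_c = center + frac * length * np.cos(a)
        ba = a + rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 0.95)
        blen = rng.uniform(0.4, 0.6) * length
        _line(canvas, base_r, base_c, base_r + blen * np.sin(ba), base_c + blen * np.cos(ba))
    rr, cc = skdraw.disk((center, center), soma, shape=canvas.shape)
    canvas[rr, cc] = True
    return _crop(canvas)


def _stamp_debris_small(rng: np.random.Generator) -> np.ndarray:
    r = rng.uniform(1.0, 3.2)
    n = 2 * int(math.ceil(r)) + 3
    canvas = np.zeros((n, n), dtype=bool)
    rr, cc = skdraw.disk((n // 2, n // 2), r, shape=canvas.shape)
    canvas[rr, cc] = True
    return _crop(canvas)


def _stamp_debris_large(rng: np.random.Generator) -> np.ndarray:
    r = rng.uniform(32.5, 38.0)
    n = 2 * int(math.ceil(r)) + 3
    canvas = np.zeros((n, n), dtype=bool)
    rr, cc = skdraw.disk((n // 2, n // 2), r, shape=canvas.shape)
    canvas[rr, cc] = True
    return _crop(canvas)


def _stamp_debris_irregular(rng: np.random.Generator) -> np.ndarray:
    """Mid-size non-cell shape that passes the area gate: a gently curved thin
    fiber (stain streak / vessel fragment), near-unit eccentricity and no
    soma — systematically unlike any of the three cell archetypes."""
    n = 200
    canvas = np.zeros((n, n), dtype=bool)
    r, c = n / 2.0, n / 2.0
    heading = rng.uniform(0, 2 * np.pi)
    for _ in range(int(rng.integers(4, 6))):
        length = rng.uniform(25.0, 40.0)
        r1 = r + length * np.sin(heading)
        c1 = c + length * np.cos(heading)
        _line(canvas, r, c, r1, c1)
        r, c = r1, c1
        heading += rng.choice([-1.0, 1.0]) * rng.uniform(0.1, 0.3)
    return _crop(canvas)


_STAMPS = {
    "round": _stamp_round,
    "bushy": _stamp_bushy,
    "dendritic": _stamp_dendritic,
    "debris_small": _stamp_debris_small,
    "debris_large": _stamp_debris_large,
    "debris_irregular": _stamp_debris_irregular,
}


def _make_stamp(archetype: str, rng: np.random.Generator) -> np.ndarray:
    """Draw a stamp and enforce its archetype's area contract (retry a few
    times — random geometry occasionally lands on a bound)."""
    for _ in range(20):
        stamp = _STAMPS[archetype](rng)
        area = int(stamp.sum())
        if archetype in CELL_ARCHETYPES or archetype == "debris_irregular":
            if _MIN_AREA < area < _MAX_AREA:
                return stamp
        elif archetype == "debris_small":
            if area <= _MIN_AREA:
                return stamp
        elif archetype == "debris_large":
            if area >= _MAX_AREA:
                return stamp
    raise RuntimeError(f"could not draw a valid {archetype} stamp")  # pragma: no cover


def _split_debris(n_debris: int) -> list[str]:
    """Split a debris budget across the three flavors (~40/20/40)."""
    n_small = int(round(0.4 * n_debris))
    n_large = int(round(0.2 * n_debris))
    n_irregular = n_debris - n_small - n_large
    return (["debris_small"] * n_small + ["debris_large"] * n_large
            + ["debris_irregular"] * n_irregular)


def generate_ihc_image(
    n_round: int = 5,
    n_bushy: int = 5,
    n_dendritic: int = 5,
    n_debris: int = 30,
    size: tuple[int, int] = (768, 768),
    stain_level: float = 0.10,
    background_level: float = 0.45,
    noise_sd: float = 0.02,
    seed: int = 0,
    max_attempts: int = 500,
) -> tuple[RgbImage, SyntheticGroundTruth]:
    """Render an IHC-like RGB frame with planted objects and full ground truth.

    Stained pixels carry blue intensity ``stain_level`` and background
    ``background_level`` (stain < background so objects are dark in blue,
    bright after negation); i.i.d. Gaussian noise of ``noise_sd`` is added to
    every channel and the result clipped to [0, 1].  Placement is
    rejection-sampled so planted objects never touch (>=3 px clearance).
    """
    if stain_level >= background_level:
        raise ConfigurationError("stain_level must be below background_level on the blue channel")
    rng = stage_rng(seed, "ihc-image")
    h, w = size

    spec = (["round"] * n_round + ["bushy"] * n_bushy + ["dendritic"] * n_dendritic
            + _split_debris(n_debris))
    stamps = [_make_stamp(a, rng) for a in spec]

    # place the big stamps first; report objects in canonical spec order
    order = sorted(range(len(spec)), key=lambda i: -stamps[i].size)
    boxes: list[tuple[int, int, int, int]] = []  # (r0, c0, r1, c1) expanded by 3
    placements: dict[int, tuple[int, int]] = {}
    margin = 3
    for i in order:
        sh, sw = stamps[i].shape
        if sh + 2 * margin >= h or sw + 2 * margin >= w:
            raise CapacityError(
                f"object of size {sh}x{sw} cannot fit a {h}x{w} frame; use a larger frame"
            )
        for _ in range(max_attempts):
            r0 = int(rng.integers(margin, h - sh - margin))
            c0 = int(rng.integers(margin, w - sw - margin))
            cand = (r0 - margin, c0 - margin, r0 + sh + margin, c0 + sw + margin)
            if all(cand[2] <= b[0] or b[2] <= cand[0] or cand[3] <= b[1] or b[3] <= cand[1]
                   for b in boxes):
                boxes.append(cand)
                placements[i] = (r0, c0)
                break
        else:
            raise CapacityError(
                f"could not place all {len(spec)} objects in a {h}x{w} frame "
                f"after {max_attempts} attempts each; use a larger frame"
            )

    stain = np.zeros((h, w), dtype=bool)
    objects: list[PlantedObject] = []
    for idx, (arch, stamp) in enumerate(zip(spec, stamps)):
        r0, c0 = placements[idx]
        coords = np.argwhere(stamp) + np.array([r0, c0])
        stain[coords[:, 0], coords[:, 1]] = True
        objects.append(
            PlantedObject(
                object_id=idx + 1,
                archetype=arch,
                centroid=(float(coords[:, 0].mean()), float(coords[:, 1].mean())),
                pixels=coords,
            )
        )

    # planted pixel sets are disjoint by construction; assert anyway
    assert sum(len(o.pixels) for o in objects) == int(stain.sum())

    # DAB brown: strong red, medium green, weak blue; hematoxylin-ish background
    channels = {"r": (0.75, 0.55), "g": (0.65, 0.40), "b": (background_level, stain_level)}
    planes = []
    for name in ("r", "g", "b"):
        bg, fg = channels[name]
        plane = np.full((h, w), bg, dtype=np.float64)
        plane[stain] = fg
        plane += rng.normal(0.0, noise_sd, size=(h, w))
        planes.append(np.clip(plane, 0.0, 1.0))
    pixels = np.stack(planes, axis=-1)

    params = dict(n_round=n_round, n_bushy=n_bushy, n_dendritic=n_dendritic,
                  n_debris=n_debris, size=size, stain_level=stain_level,
                  background_level=background_level, noise_sd=noise_sd)
    truth = SyntheticGroundTruth(objects=objects, image_params=params, seed=seed)
    log.info("generate_ihc_image: %d objects planted in %dx%d frame", len(objects), h, w)
    return RgbImage(pixels=pixels, source_path=f"<synthetic:seed={seed}>"), truth


# ---------------------------------------------------------------------------
# feature-space training set

def generate_feature_training_set(
    n_cells: int = 277,
    n_noncells: int = 277,
    separation: float = 4.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Labeled feature vectors from two unit-variance Gaussians whose means
    differ by ``separation`` along the area axis.  ``separation=0`` makes the
    classes exchangeable; large separations make them linearly separable.
    """
    if n_cells < 1 or n_noncells < 1:
        raise ConfigurationError("n_cells and n_noncells must be >= 1")
    if separation < 0:
        raise ConfigurationError("separation must be >= 0")
    rng = stage_rng(seed, "feature-training-set")
    p = len(FEATURE_PANEL)
    delta = np.zeros(p)
    delta[0] = separation  # all displacement on one axis: worst case for mtry=3
    cells = rng.normal(0.0, 1.0, size=(n_cells, p)) + delta
    noncells = rng.normal(0.0, 1.0, size=(n_noncells, p))
    X = np.vstack([cells, noncells])
    df = pd.DataFrame(X, columns=list(FEATURE_PANEL))
    df.insert(0, "image_id", "synthetic")
    df.insert(0, "object_id", np.arange(1, len(df) + 1))
    df["label"] = ["cell"] * n_cells + ["noncell"] * n_noncells
    return df[list(FEATURE_TABLE_COLUMNS) + ["label"]]


# ---------------------------------------------------------------------------
# genotype-stratified cell-label tables

_DEFAULT_PROPORTIONS = {
    "WT": {"monocytes": 0.25, "macrophages": 0.45, "dendritic_cells": 0.10,
           "neutrophils": 0.20},
    "cKO": {"monocytes": 0.35, "macrophages": 0.25, "dendritic_cells": 0.10,
            "neutrophils": 0.30},
}


def generate_label_table(
    n_per_genotype: int = 3000,
    type_proportions: dict[str, dict[str, float]] | None = None,
    cloud_centers: dict[str, tuple[float, float]] | None = None,
    cloud_sd: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Genotype-stratified cell labels with per-type Gaussian embedding clouds.

    Default proportions plant the enrichment pattern the bootstrap comparison
    is meant to detect (monocytes/neutrophils enriched in cKO, macrophages in
    WT).
    """
    props = type_proportions if type_proportions is not None else _DEFAULT_PROPORTIONS
    all_types = sorted({t for m in props.values() for t in m})
    if cloud_centers is None:
        angles = np.linspace(0, 2 * np.pi, len(all_types), endpoint=False)
        cloud_centers = {t: (5.0 * np.cos(a), 5.0 * np.sin(a))
                         for t, a in zip(all_types, angles)}
    rows = []
    for genotype in props:
        pmap = props[genotype]
        total = sum(pmap.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"proportions for genotype {genotype!r} sum to {total}, not 1"
            )
        types = sorted(pmap)
        probs = np.array([pmap[t] for t in types])
        rng = stage_rng(seed, "label-table", genotype)
        drawn = rng.choice(len(types), size=n_per_genotype, p=probs)
        for i, k in enumerate(drawn):
            t = types[k]
            cx, cy = cloud_centers[t]
            x = cx + rng.normal(0.0, cloud_sd)
            y = cy + rng.normal(0.0, cloud_sd)
            rows.append((f"{genotype}_{i + 1}", genotype, t, x, y))
    return pd.DataFrame(rows, columns=list(LABEL_TABLE_COLUMNS))


# ---------------------------------------------------------------------------
# slide annotations

def generate_slide_annotation(
    grid_rows: int = 4,
    grid_cols: int = 5,
    p_positive: float = 0.25,
    cd3_rate: float = 3.0,
    seed: int = 0,
    slide_id: str = "slide",
    genotype: str = "WT",
) -> SlideAnnotation:
    """Quadrant grid with Bernoulli positivity and Poisson CD3 counts."""
    if not (0.0 <= p_positive <= 1.0):
        raise ConfigurationError("p_positive must lie in [0, 1]")
    if cd3_rate < 0:
        raise ConfigurationError("cd3_rate must be >= 0")
    rng = stage_rng(seed, "slide-annotation", slide_id)
    positive = rng.random((grid_rows, grid_cols)) < p_positive
    cd3 = rng.poisson(cd3_rate, size=(grid_rows, grid_cols))
    quads = frozenset((int(r), int(c)) for r, c in np.argwhere(positive))
    return SlideAnnotation(
        slide_id=slide_id, genotype=genotype,
        grid_rows=grid_rows, grid_cols=grid_cols,
        positive_quadrants=quads, cd3_counts=cd3,
    )


def generate_myelin_masks(
    size: tuple[int, int] = (128, 128),
    plaque_fraction: float = 0.25,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """A white-matter disk with a contained myelinated-plaque disk whose area
    is approximately ``plaque_fraction`` of the white matter."""
    rng = stage_rng(seed, "myelin-masks")
    h, w = size
    wm = np.zeros((h, w), dtype=bool)
    r_wm = min(h, w) * 0.4
    center = (h // 2, w // 2)
    rr, cc = skdraw.disk(center, r_wm, shape=(h, w))
    wm[rr, cc] = True
    r_pl = r_wm * math.sqrt(plaque_fraction)
    jitter = (center[0] + rng.uniform(-2, 2), center[1] + rng.uniform(-2, 2))
    plaque = np.zeros((h, w), dtype=bool)
    rr, cc = skdraw.disk(jitter, r_pl, shape=(h, w))
    plaque[rr, cc] = True
    plaque &= wm  # containment invariant
    return plaque, wm
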