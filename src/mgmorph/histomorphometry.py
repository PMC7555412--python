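"""Quadrant-based histology scoring and the myelin-area ratio.

A slide is divided into an equally sized quadrant grid; the fraction of
quadrants positive for inflammatory pockets is expressed as a percentage of
the total, and CD3+ cells are totalled over quadrants by the same strategy.
Demyelination is quantified as the ratio of the myelinated plaque area to the
total white-matter area.  All three parameters are summarized as mean +- SD
per genotype (sample SD, n-1 denominator).  Positivity calls, CD3 counts and
the two masks are expert annotations supplied as inputs; only the arithmetic
lives here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AnnotationError, DegenerateInputError, MetadataError
from .synthetic import SlideAnnotation

log = logging.getLogger("mgmorph.histomorphometry")

__all__ = ["QuadrantScore", "MyelinScore", "score_quadrants", "myelin_ratio",
           "summarize_by_genotype"]


@dataclass(frozen=True)
class QuadrantScore:
    slide_id: str
    n_quadrants: int
    n_positive: int
    percent_positive: float
    cd3_total: int


@dataclass(frozen=True)
class MyelinScore:
    slide_id: str
    plaque_area_px: int
    white_matter_area_px: int
    ratio: float


def score_quadrants(annotation: SlideAnnotation) -> QuadrantScore:
    """Percent of positive quadrants and the CD3 total for one slide."""
    n_quadrants = annotation.grid_rows * annotation.grid_cols
    if n_quadrants < 1:
        raise AnnotationError("grid must be at least 1x1")
    for (r, c) in annotation.positive_quadrants:
        if not (0 <= r < annotation.grid_rows and 0 <= c < annotation.grid_cols):
            raise AnnotationError(f"positive quadrant ({r},{c}) outside the grid")
    n_positive = len(annotation.positive_quadrants)
    return QuadrantScore(
        slide_id=annotation.slide_id,
        n_quadrants=n_quadrants,
        n_positive=n_positive,
        percent_positive=100.0 * n_positive / n_quadrants,
        cd3_total=int(annotation.cd3_counts.sum()),
    )


def myelin_ratio(
    myelin_mask: np.ndarray, white_matter_mask: np.ndarray, slide_id: str = "slide"
) -> MyelinScore:
    """Myelinated plaque area over total white-matter area (both pixel counts)."""
    myelin = np.asarray(myelin_mask, dtype=bool)
    wm = np.asarray(white_matter_mask, dtype=bool)
    if myelin.shape != wm.shape:
        raise AnnotationError(
            f"mask shapes differ: {myelin.shape} vs {wm.shape}"
        )
    wm_area = int(wm.sum())
    if wm_area == 0:
        raise DegenerateInputError("white-matter mask is empty")
    if (myelin & ~wm).any():
        raise AnnotationError("myelin pixels found outside the white-matter mask")
    plaque = int(myelin.sum())
    return MyelinScore(
        slide_id=slide_id,
        plaque_area_px=plaque,
        white_matter_area_px=wm_area,
        ratio=plaque / wm_area,
    )


def summarize_by_genotype(
    scores: list[QuadrantScore | MyelinScore],
    genotypes: dict[str, str],
) -> pd.DataFrame:
    """Per-genotype n / mean / SD for each measure carried by the scores.

    Quadrant scores contribute ``percent_positive`` and ``cd3_total``; myelin
    scores contribute ``ratio``.  SD is NaN at n=1.  The summary is invariant
    to slide order.
    """
    values: dict[tuple[str, str], list[float]] = {}
    for s in scores:
        if s.slide_id not in genotypes:
            raise MetadataError(f"slide {s.slide_id!r} has no genotype mapping")
        g = genotypes[s.slide_id]
        if isinstance(s, QuadrantScore):
            values.setdefault((g, "percent_positive"), []).append(s.percent_positive)
            values.setdefault((g, "cd3_total"), []).append(float(s.cd3_total))
        elif isinstance(s, MyelinScore):
            values.setdefault((g, "myelin_ratio"), []).append(s.ratio)
        else:  # pragma: no cover
            raise AnnotationError(f"unknown score type {type(s).__name__}")
    rows = []
    for (g, measure) in sorted(values):
        vals = np.asarray(values[(g, measure)], dtype=np.float64)
        rows.append(
            {
                "genotype": g,
                "measure": measure,
                "n": len(vals),
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
            }
        )
    return pd.DataFrame(rows, columns=["genotype", "measure", "n", "mean", "sd"])
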