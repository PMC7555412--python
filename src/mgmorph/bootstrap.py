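"""Genotype-stratified bootstrap of cell-type composition and embedding density.

Because genotype group sizes are unbalanced, composition is compared by
resampling: for each genotype independently, ``boot_n`` cells (default 2,000)
are drawn uniformly with replacement from that genotype's cells and their
cell types tallied; this is repeated ``boot_reps`` times (default 500).  The
same resampling drives a binned two-dimensional density of the embedding
coordinates on a ``density_bins`` x ``density_bins`` grid (default 800x800)
over an extent shared by all genotypes, with the per-bin mean over replicates
reported.

Each genotype draws from its own namespaced random stream, so permuting the
rows of one genotype never changes another genotype's replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import stage_rng
from .config import PipelineConfig
from .errors import DegenerateInputError, SchemaError

log = logging.getLogger("mgmorph.bootstrap")

__all__ = ["BootstrapCountResult", "DensityGrid", "bootstrap_celltype_counts",
           "bootstrap_density", "compare_genotypes"]


@dataclass(frozen=True)
class BootstrapCountResult:
    """Replicate-level counts plus per-genotype, per-type summaries."""

    replicates: np.ndarray          # (reps, n_genotypes, n_types)
    genotypes: tuple[str, ...]
    cell_types: tuple[str, ...]
    summary: pd.DataFrame           # genotype, cell_type, mean, sd, q2.5, q97.5
    boot_n: int
    boot_reps: int
    seed: int


@dataclass(frozen=True)
class DensityGrid:
    """Mean binned density per genotype over bootstrap replicates."""

    grids: dict[str, np.ndarray]    # genotype -> (bins, bins) mean counts
    extent: tuple[float, float, float, float]  # x_min, x_max, y_min, y_max
    bins: int
    boot_n: int
    boot_reps: int
    seed: int


def _check_table(table: pd.DataFrame) -> None:
    needed = ("cell_id", "genotype", "cell_type", "embed_x", "embed_y")
    missing = [c for c in needed if c not in table.columns]
    if missing:
        raise SchemaError(f"cell label table missing columns {missing}")


def bootstrap_celltype_counts(
    table: pd.DataFrame, cfg: PipelineConfig
) -> BootstrapCountResult:
    """Tally cell types of ``boot_n`` cells resampled with replacement from
    each genotype, repeated ``boot_reps`` times."""
    _check_table(table)
    genotypes = tuple(sorted(table["genotype"].unique()))
    if not genotypes:
        raise DegenerateInputError("cell label table is empty")
    cell_types = tuple(sorted(table["cell_type"].unique()))
    type_index = {t: i for i, t in enumerate(cell_types)}

    reps = np.zeros((cfg.boot_reps, len(genotypes), len(cell_types)), dtype=np.int64)
    for gi, genotype in enumerate(genotypes):
        codes = np.array(
            [type_index[t] for t in table.loc[table["genotype"] == genotype, "cell_type"]],
            dtype=np.int64,
        )
        if len(codes) == 0:
            raise DegenerateInputError(f"genotype {genotype!r} has no cells")
        rng = stage_rng(cfg.seed, "bootstrap-counts", genotype)
        for r in range(cfg.boot_reps):
            draw = codes[rng.integers(0, len(codes), size=cfg.boot_n)]
            reps[r, gi, :] = np.bincount(draw, minlength=len(cell_types))
    # conservation: every replicate resamples exactly boot_n cells per genotype
    assert (reps.sum(axis=2) == cfg.boot_n).all()

    rows = []
    for gi, genotype in enumerate(genotypes):
        for ti, cell_type in enumerate(cell_types):
            vals = reps[:, gi, ti].astype(np.float64)
            rows.append(
                {
                    "genotype": genotype,
                    "cell_type": cell_type,
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
                    "q2.5": float(np.percentile(vals, 2.5)),
                    "q97.5": float(np.percentile(vals, 97.5)),
                }
            )
    summary = pd.DataFrame(rows)
    log.info("bootstrap_celltype_counts: %d reps x %d genotypes x %d types",
             cfg.boot_reps, len(genotypes), len(cell_types))
    return BootstrapCountResult(
        replicates=reps, genotypes=genotypes, cell_types=cell_types,
        summary=summary, boot_n=cfg.boot_n, boot_reps=cfg.boot_reps, seed=cfg.seed,
    )


def bootstrap_density(table: pd.DataFrame, cfg: PipelineConfig) -> DensityGrid:
    """Mean binned 2-D embedding density per genotype over bootstrap replicates.

    The binning extent is the pooled coordinate range over all genotypes, so
    the per-genotype grids are directly comparable; the top edge of each axis
    is right-closed, so every sampled point lands in a bin and each
    replicate's histogram mass is exactly ``boot_n``.
    """
    _check_table(table)
    x = table["embed_x"].to_numpy(dtype=np.float64)
    y = table["embed_y"].to_numpy(dtype=np.float64)
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise SchemaError("embedding coordinates must be finite")
    x_min, x_max = float(x.min()), float(x.max())
    y_min, y_max = float(y.min()), float(y.max())
    if x_min == x_max or y_min == y_max:
        raise DegenerateInputError("zero coordinate range on an embedding axis")
    x_edges = np.linspace(x_min, x_max, cfg.density_bins + 1)
    y_edges = np.linspace(y_min, y_max, cfg.density_bins + 1)

    grids: dict[str, np.ndarray] = {}
    for genotype in sorted(table["genotype"].unique()):
        sub = table.loc[table["genotype"] == genotype]
        gx = sub["embed_x"].to_numpy(dtype=np.float64)
        gy = sub["embed_y"].to_numpy(dtype=np.float64)
        rng = stage_rng(cfg.seed, "bootstrap-density", genotype)
        acc = np.zeros((cfg.density_bins, cfg.density_bins), dtype=np.float64)
        for _ in range(cfg.boot_reps):
            idx = rng.integers(0, len(gx), size=cfg.boot_n)
            hist, _, _ = np.histogram2d(gx[idx], gy[idx], bins=[x_edges, y_edges])
            assert hist.sum() == cfg.boot_n  # right-closed top edge: mass conserved
            acc += hist
        grids[genotype] = acc / cfg.boot_reps
    log.info("bootstrap_density: %dx%d bins, %d reps, extent x[%g,%g] y[%g,%g]",
             cfg.density_bins, cfg.density_bins, cfg.boot_reps,
             x_min, x_max, y_min, y_max)
    return DensityGrid(
        grids=grids, extent=(x_min, x_max, y_min, y_max), bins=cfg.density_bins,
        boot_n=cfg.boot_n, boot_reps=cfg.boot_reps, seed=cfg.seed,
    )


def compare_genotypes(
    result: BootstrapCountResult,
    reference: str = "WT",
    contrast: str = "cKO",
) -> pd.DataFrame:
    """Per-cell-type difference of bootstrap counts (contrast - reference).

    Pairs replicate i of one genotype with replicate i of the other, and
    reports the mean difference, the 2.5-97.5 percentile interval of the
    replicate-wise difference, and the fraction of pairs with a positive
    difference.
    """
    if len(result.genotypes) < 2:
        raise DegenerateInputError("need at least two genotypes to compare")
    if result.boot_reps < 1:
        raise DegenerateInputError("need at least one replicate")
    for g in (reference, contrast):
        if g not in result.genotypes:
            raise SchemaError(f"genotype {g!r} not in bootstrap result {result.genotypes}")
    ref_i = result.genotypes.index(reference)
    con_i = result.genotypes.index(contrast)
    rows = []
    for ti, cell_type in enumerate(result.cell_types):
        diff = (result.replicates[:, con_i, ti] - result.replicates[:, ref_i, ti]).astype(
            np.float64
        )
        rows.append(
            {
                "cell_type": cell_type,
                "mean_diff": float(diff.mean()),
                "q2.5": float(np.percentile(diff, 2.5)),
                "q97.5": float(np.percentile(diff, 97.5)),
                "frac_positive": float((diff > 0).mean()),
                "contrast": f"{contrast}-{reference}",
            }
        )
    return pd.DataFrame(rows)
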