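"""Three-state morphological classification of screened cells.

Measurements are scaled by ranking each of them across all objects (ties
averaged), pooled over every image in the run.  Rank-scaled cells are then
clustered by agglomerative hierarchical clustering with complete linkage
(inter-cluster distance = maximum pairwise member distance, Euclidean on the
rank scale), and the dendrogram is cut into three clusters.  Clusters are
mapped to activation states by a ramification score — the mean over members
of ``(rank(perimeter^2/area) + rank(radius_sd)) / 2`` — whose ordering tracks
process complexity: lowest = activated (round), middle = activating (bushy),
highest = homeostatic (dendritic/ramified).  A config override map supports
expert relabeling.

The merge loop is written out explicitly so tie-breaking is fully specified:
among equal inter-cluster distances the pair with the smallest indices merges
first, giving bit-reproducible dendrograms on the integer-valued distances
that rank-scaled features produce.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from scipy.stats import rankdata

from .config import PipelineConfig
from .errors import DegenerateInputError, LabelingError, MetadataError, SchemaError
from .io import FEATURE_PANEL, MORPHOLOGY_PANEL

log = logging.getLogger("mgmorph.morphostate")

__all__ = ["StateAssignment", "rank_scale", "cluster_states",
           "assign_state_labels", "summarize_counts", "STATES"]

#: activation states ordered from least to most ramified
STATES = ("activated", "activating", "homeostatic")


@dataclass(frozen=True)
class StateAssignment:
    """Per-object cluster ids (1..k), state labels, and per-cluster scores."""

    cluster: np.ndarray
    state: np.ndarray | None = None
    cluster_scores: dict[int, float] = field(default_factory=dict)


def rank_scale(features: pd.DataFrame, columns: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Replace each feature column with its rank across all objects.

    Ties get the mean of the ranks they span, so each column's values are the
    average ranks of 1..N; ranking is invariant under strictly increasing
    transforms of the raw column.
    """
    if len(features) < 1:
        raise DegenerateInputError("rank_scale needs at least one object")
    if columns is None:
        columns = tuple(c for c in FEATURE_PANEL if c in features.columns)
    out = features.copy()
    for col in columns:
        vals = features[col].to_numpy(dtype=np.float64)
        if np.isnan(vals).any():
            raise SchemaError(f"column {col!r} contains missing values")
        out[col] = rankdata(vals, method="average")
    return out


def _complete_linkage_labels(X: np.ndarray, k: int) -> np.ndarray:
    """Agglomerate rows of X under complete linkage until k clusters remain.

    Ties break toward the smallest (i, j) pair in current cluster order;
    merged clusters keep the smaller index.  Returns labels 1..k numbered by
    each cluster's smallest member row.
    """
    n = X.shape[0]
    members: list[list[int]] = [[i] for i in range(n)]
    if n <= k:
        labels = np.arange(1, n + 1)
        return labels
    D = squareform(pdist(X, metric="euclidean"))
    np.fill_diagonal(D, np.inf)
    D = np.triu(D) + np.tril(np.full_like(D, np.inf))
    while len(members) > k:
        flat = int(np.argmin(D))  # first minimum in row-major order = smallest (i, j)
        i, j = divmod(flat, D.shape[1])
        merged = np.maximum(
            np.minimum(D[i, :], D[:, i]), np.minimum(D[j, :], D[:, j])
        )  # complete linkage: max of the two clusters' distances to every other
        members[i] = members[i] + members[j]
        del members[j]
        D[i, :] = np.inf
        D[:, i] = np.inf
        keep = np.arange(D.shape[0]) != j
        D = D[np.ix_(keep, keep)]
        merged = merged[keep]
        i_new = i  # i < j, so i's index is unchanged after deleting j
        D[i_new, i_new + 1:] = merged[i_new + 1:]
        D[:i_new, i_new] = merged[:i_new]
    labels = np.empty(n, dtype=np.int64)
    order = sorted(range(len(members)), key=lambda c: min(members[c]))
    for new_id, c in enumerate(order, start=1):
        labels[members[c]] = new_id
    return labels


def cluster_states(
    ranked: pd.DataFrame,
    cfg: PipelineConfig,
    columns: tuple[str, ...] = MORPHOLOGY_PANEL,
) -> StateAssignment:
    """Cut the complete-linkage dendrogram of the rank-scaled features into
    ``cfg.n_clusters`` clusters.

    Centroid coordinates and the orientation angle are excluded by default
    (neither position nor rotation is morphology, and including them would
    make state assignment sensitive to where and how a cell lies in the
    frame); pass ``columns`` to override.
    """
    if len(ranked) < cfg.n_clusters:
        raise DegenerateInputError(
            f"need at least {cfg.n_clusters} objects, got {len(ranked)}"
        )
    missing = [c for c in columns if c not in ranked.columns]
    if missing:
        raise SchemaError(f"ranked table missing columns {missing}")
    X = ranked[list(columns)].to_numpy(dtype=np.float64)
    labels = _complete_linkage_labels(X, cfg.n_clusters)
    log.info("cluster_states: %d objects -> %d clusters (complete linkage)",
             len(ranked), cfg.n_clusters)
    return StateAssignment(cluster=labels)


def assign_state_labels(
    assignment: StateAssignment,
    features: pd.DataFrame,
    cfg: PipelineConfig,
) -> StateAssignment:
    """Map the three clusters onto activation states by ramification score.

    The score per cluster is the member mean of
    ``(rank(perimeter^2/area) + rank(radius_sd)) / 2`` over the pooled
    objects; the least ramified cluster becomes ``activated`` (round), the
    middle ``activating`` (bushy), the most ramified ``homeostatic``
    (dendritic).  ``cfg.state_override`` (cluster id -> state) replaces the
    automatic mapping when supplied.
    """
    clusters = assignment.cluster
    k = len(np.unique(clusters))
    if k != 3 and not cfg.state_override:
        raise LabelingError(
            f"automatic state labeling needs exactly 3 clusters, got {k}; "
            "supply state_override in the config"
        )
    ratio = features["perimeter_px"].to_numpy(dtype=np.float64) ** 2 / features[
        "area_px"
    ].to_numpy(dtype=np.float64)
    score_per_object = 0.5 * (
        rankdata(ratio, method="average")
        + rankdata(features["radius_sd"].to_numpy(dtype=np.float64), method="average")
    )
    scores = {
        int(c): float(score_per_object[clusters == c].mean()) for c in np.unique(clusters)
    }

    if cfg.state_override:
        missing = [c for c in scores if c not in cfg.state_override]
        if missing:
            raise LabelingError(f"state_override missing clusters {missing}")
        mapping = {int(c): cfg.state_override[int(c)] for c in scores}
    else:
        ordered = sorted(scores, key=lambda c: scores[c])
        if len(set(scores.values())) < len(scores):
            raise LabelingError(
                "tied ramification scores between clusters; supply state_override "
                "in the config to label them manually"
            )
        mapping = {c: STATES[i] for i, c in enumerate(ordered)}

    state = np.array([mapping[int(c)] for c in clusters], dtype=object)
    log.info("assign_state_labels: scores %s -> mapping %s", scores, mapping)
    return StateAssignment(cluster=clusters, state=state, cluster_scores=scores)


def summarize_counts(
    assignment: StateAssignment,
    image_ids: pd.Series | np.ndarray,
    genotypes: dict[str, str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-image state counts and per-genotype mean +- SD of those counts.

    SD uses the sample (n-1) denominator and is reported as NaN for a single
    image.  Totals across states equal the number of classified cells.
    """
    image_ids = np.asarray(image_ids, dtype=object)
    if len(image_ids) == 0:
        empty_img = pd.DataFrame(columns=["image_id", "genotype", *STATES])
        empty_gen = pd.DataFrame(columns=["genotype", "state", "n_images", "mean", "sd"])
        return empty_img, empty_gen
    if assignment.state is None:
        raise SchemaError("assignment has no state labels; run assign_state_labels first")
    df = pd.DataFrame({"image_id": image_ids, "state": assignment.state})
    per_image = (
        df.groupby(["image_id", "state"], sort=True).size().unstack(fill_value=0)
    )
    for s in STATES:
        if s not in per_image.columns:
            per_image[s] = 0
    per_image = per_image[list(STATES)].reset_index()

    missing = [i for i in per_image["image_id"] if i not in genotypes]
    if missing:
        raise MetadataError(f"images without genotype: {missing}")
    per_image.insert(1, "genotype", [genotypes[i] for i in per_image["image_id"]])

    rows = []
    for genotype, grp in per_image.groupby("genotype", sort=True):
        for s in STATES:
            vals = grp[s].to_numpy(dtype=np.float64)
            rows.append(
                {
                    "genotype": genotype,
                    "state": s,
                    "n_images": len(vals),
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
                }
            )
    per_genotype = pd.DataFrame(rows)
    return per_image, per_genotype
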