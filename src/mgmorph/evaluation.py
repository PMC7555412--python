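"""Recovery experiments on ground-truthed synthetic data.

These functions quantify how well the full analysis chain recovers what the
generator planted: the fraction of planted cells surviving detection + area
gate + classifier, the fraction of retained objects that are not cells, and
the adjusted Rand index between the three-state clustering and the planted
archetypes.  They are the basis of the repository's push-button validation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .classification import classify_objects, make_balanced_split, train_forest
from .config import PipelineConfig
from .morphostate import assign_state_labels, cluster_states, rank_scale
from .pipeline import label_from_ground_truth, match_to_ground_truth
from .segmentation import run_detection
from .synthetic import CELL_ARCHETYPES, generate_feature_training_set, generate_ihc_image

log = logging.getLogger("mgmorph.evaluation")

__all__ = ["planted_recovery_experiment", "classifier_brackets"]


def planted_recovery_experiment(
    seed: int,
    n_images: int = 20,
    n_train_images: int = 5,
    n_round: int = 5,
    n_bushy: int = 5,
    n_dendritic: int = 5,
    n_debris: int = 30,
    noise_sd: float = 0.02,
    cfg: PipelineConfig | None = None,
) -> dict:
    """Generate images, train the cell filter on the first block's ground
    truth, and measure recovery on the remaining images.

    Returns cell retention, the retained non-cell fraction, and the adjusted
    Rand index of the three-state clustering against planted archetypes.
    """
    cfg = (cfg or PipelineConfig()).replace(seed=seed)
    detections = []
    for i in range(n_images):
        image, truth = generate_ihc_image(
            n_round=n_round, n_bushy=n_bushy, n_dendritic=n_dendritic,
            n_debris=n_debris, noise_sd=noise_sd, seed=seed * 1009 + i,
        )
        labeled, gated = run_detection(image, cfg, image_id=f"img{i:02d}")
        detections.append((truth, labeled, gated))

    # train the forest on ground-truth labels from the training block
    train_parts = []
    for truth, labeled, gated in detections[:n_train_images]:
        part = gated.copy()
        part["label"] = label_from_ground_truth(gated, labeled, truth).to_numpy()
        train_parts.append(part)
    train_df = pd.concat(train_parts, ignore_index=True)
    counts = train_df["label"].value_counts()
    n_per_class = min(cfg.train_per_class, max(1, int(0.8 * counts.min())))
    split = make_balanced_split(train_df, train_df["label"].to_numpy(),
                                n_per_class=n_per_class, seed=cfg.seed)
    model = train_forest(split, cfg)

    # evaluate on the held-out images
    n_planted_cells = 0
    kept_truth: list[str] = []
    kept_arch: list[str] = []
    cell_parts = []
    for truth, labeled, gated in detections[n_train_images:]:
        n_planted_cells += len(truth.cells)
        cells, annotated = classify_objects(model, gated)
        matches = match_to_ground_truth(labeled, truth).set_index("object_id")
        for _, row in annotated.iterrows():
            if not row["is_cell"]:
                continue
            m = matches.loc[int(row["object_id"])]
            is_cell = (m["archetype"] in CELL_ARCHETYPES
                       and m["intersection_px"] >= 0.5 * m["detected_area_px"])
            kept_truth.append("cell" if is_cell else "noncell")
            kept_arch.append(m["archetype"])
        cell_parts.append(cells)

    n_kept = len(kept_truth)
    n_cells_kept = sum(t == "cell" for t in kept_truth)
    retention = n_cells_kept / n_planted_cells if n_planted_cells else 0.0
    noncell_fraction = (n_kept - n_cells_kept) / n_kept if n_kept else 0.0

    # three-state clustering of the retained cells vs planted archetypes
    cells_df = pd.concat(cell_parts, ignore_index=True)
    ranked = rank_scale(cells_df)
    assignment = cluster_states(ranked, cfg)
    assignment = assign_state_labels(assignment, cells_df, cfg)
    arch = np.array(kept_arch, dtype=object)
    is_true_cell = np.array([t == "cell" for t in kept_truth])
    ari = float(adjusted_rand_score(arch[is_true_cell],
                                    assignment.cluster[is_true_cell]))
    state_match = float(
        np.mean([
            {"round": "activated", "bushy": "activating", "dendritic": "homeostatic"}[a] == s
            for a, s in zip(arch[is_true_cell], np.asarray(assignment.state)[is_true_cell])
        ])
    )
    result = {
        "n_planted_cells": n_planted_cells,
        "n_retained": n_kept,
        "cell_retention": retention,
        "noncell_retained_fraction": noncell_fraction,
        "ari_vs_planted": ari,
        "state_label_match": state_match,
        "validation_accuracy": model.validation_accuracy,
    }
    log.info("planted_recovery_experiment(seed=%d): %s", seed, result)
    return result


def classifier_brackets(seed: int, n_validation_target: int = 1000) -> dict:
    """Accuracy brackets any correct forest must satisfy on synthetic features.

    Separable classes (mean separation 10 standard deviations) must classify
    nearly perfectly; exchangeable classes (separation 0) must sit at chance.
    Both use the balanced 277 + 277 training protocol with the remainder held
    out for validation.
    """
    cfg = PipelineConfig(seed=seed)
    half = 277 + n_validation_target // 2
    out = {}
    for name, separation in (("separable", 10.0), ("null", 0.0)):
        table = generate_feature_training_set(
            n_cells=half, n_noncells=half, separation=separation, seed=seed
        )
        split = make_balanced_split(table, table["label"].to_numpy(),
                                    n_per_class=277, seed=seed)
        model = train_forest(split, cfg)
        out[f"{name}_accuracy"] = model.validation_accuracy
        out[f"{name}_n_validation"] = int((split.split == "validation").sum())
    return out
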