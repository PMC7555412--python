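"""End-to-end orchestration: manifest-driven runs and the self-checking demo.

``run_all`` executes the full analysis in the Methods order — detection and
area gate per image, random-forest screening, rank scaling, three-state
complete-linkage clustering, per-image / per-genotype summaries — and, when a
cell label table or slide annotations are supplied, the genotype-stratified
bootstraps and histomorphometry arithmetic.  Every intermediate table is
written so each stage is independently auditable, and a JSON report records
the effective config, seed, per-stage object counts, and package version.

``demo`` generates a complete synthetic dataset, runs ``run_all`` on it, and
verifies the generator-pipeline recovery properties; it is the repository's
push-button entry point, fully reproducible from one seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classification import (classify_objects, load_model, make_balanced_split,
                             save_model, train_forest)
from .config import PipelineConfig, load_config
from .errors import ManifestError
from .histomorphometry import (myelin_ratio, score_quadrants, summarize_by_genotype)
from .io import (OBJECT_LABEL_COLUMNS, LABEL_TABLE_COLUMNS, read_image,
                 read_table, write_mask, write_table)
from .morphostate import assign_state_labels, cluster_states, rank_scale, summarize_counts
from .segmentation import run_detection
from .synthetic import (CELL_ARCHETYPES, SlideAnnotation, SyntheticGroundTruth,
                        generate_ihc_image, generate_label_table,
                        generate_myelin_masks, generate_slide_annotation)

log = logging.getLogger("mgmorph.pipeline")

__all__ = ["RunManifest", "load_manifest", "run_all", "demo",
           "match_to_ground_truth", "label_from_ground_truth"]


# ---------------------------------------------------------------------------
# ground-truth matching (synthetic-data evaluation)

def match_to_ground_truth(
    labeled_mask: np.ndarray,
    truth: SyntheticGroundTruth,
) -> pd.DataFrame:
    """Match detected objects to planted objects by pixel overlap.

    One row per detected label: the planted object with the largest
    intersection, the intersection size, and the detected / planted areas.
    Unmatched detections get planted_id 0.
    """
    planted = np.zeros_like(labeled_mask, dtype=np.int64)
    areas = {}
    for obj in truth.objects:
        planted[obj.pixels[:, 0], obj.pixels[:, 1]] = obj.object_id
        areas[obj.object_id] = len(obj.pixels)
    arch = {obj.object_id: obj.archetype for obj in truth.objects}

    rows = []
    n_labels = int(labeled_mask.max(initial=0))
    for lab in range(1, n_labels + 1):
        sel = labeled_mask == lab
        detected_area = int(sel.sum())
        if detected_area == 0:
            continue
        under = planted[sel]
        under = under[under > 0]
        if len(under):
            vals, counts = np.unique(under, return_counts=True)
            best = int(vals[counts.argmax()])
            inter = int(counts.max())
        else:
            best, inter = 0, 0
        rows.append(
            {
                "object_id": lab,
                "planted_id": best,
                "archetype": arch.get(best, "none"),
                "intersection_px": inter,
                "detected_area_px": detected_area,
                "planted_area_px": areas.get(best, 0),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["object_id", "planted_id", "archetype", "intersection_px",
                 "detected_area_px", "planted_area_px"],
    )


def label_from_ground_truth(
    features: pd.DataFrame,
    labeled_mask: np.ndarray,
    truth: SyntheticGroundTruth,
    min_overlap: float = 0.5,
) -> pd.Series:
    """Cell / non-cell labels for detected objects, from the planted registry.

    An object is a ``cell`` when most of its pixels (>= ``min_overlap``) lie
    on a planted cell archetype; everything else (debris, noise blobs) is
    ``noncell``.
    """
    matches = match_to_ground_truth(labeled_mask, truth).set_index("object_id")
    labels = []
    for oid in features["object_id"]:
        m = matches.loc[int(oid)]
        is_cell = (
            m["archetype"] in CELL_ARCHETYPES
            and m["intersection_px"] >= min_overlap * m["detected_area_px"]
        )
        labels.append("cell" if is_cell else "noncell")
    return pd.Series(labels, index=features.index, name="label")


# ---------------------------------------------------------------------------
# manifest

@dataclass(frozen=True)
class RunManifest:
    """Inputs of one pipeline run: images with metadata, optional tables."""

    images: tuple[dict, ...]            # each: {path, image_id, genotype}
    out_dir: str
    model_path: str | None = None       # trained classifier, or
    object_labels_path: str | None = None  # manual labels to train one
    label_table_path: str | None = None    # single-cell labels for bootstraps
    annotations_path: str | None = None    # quadrant annotations table
    config_path: str | None = None
    seed: int | None = None             # overrides config seed when set

    def validate(self) -> None:
        ids = [e["image_id"] for e in self.images]
        if len(set(ids)) != len(ids):
            raise ManifestError(f"duplicate image_ids in manifest: {ids}")
        for e in self.images:
            if not Path(e["path"]).exists():
                raise ManifestError(f"image not found: {e['path']}")
            if "genotype" not in e:
                raise ManifestError(f"image {e['image_id']} lacks a genotype")
        for p in (self.model_path, self.object_labels_path,
                  self.label_table_path, self.annotations_path, self.config_path):
            if p is not None and not Path(p).exists():
                raise ManifestError(f"referenced path not found: {p}")
        if self.model_path is None and self.object_labels_path is None:
            raise ManifestError("manifest needs either a trained model or object labels")


def load_manifest(path: str | Path) -> RunManifest:
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "images" not in doc:
        raise ManifestError(f"{path}: manifest must be a mapping with an 'images' list")
    return RunManifest(
        images=tuple(doc["images"]),
        out_dir=doc.get("out_dir", "."),
        model_path=doc.get("model"),
        object_labels_path=doc.get("object_labels"),
        label_table_path=doc.get("label_table"),
        annotations_path=doc.get("annotations"),
        config_path=doc.get("config"),
        seed=doc.get("seed"),
    )


# ---------------------------------------------------------------------------
# annotations on disk (delimited text round-trip)

ANNOTATION_COLUMNS = ("slide_id", "genotype", "grid_rows", "grid_cols",
                      "positive_quadrants", "cd3_counts")


def annotations_to_table(annotations: list[SlideAnnotation]) -> pd.DataFrame:
    rows = []
    for a in annotations:
        quads = ";".join(f"{r},{c}" for r, c in sorted(a.positive_quadrants))
        cd3 = ";".join(str(int(v)) for v in a.cd3_counts.ravel())
        rows.append((a.slide_id, a.genotype, a.grid_rows, a.grid_cols, quads, cd3))
    return pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS))


def table_to_annotations(df: pd.DataFrame) -> list[SlideAnnotation]:
    out = []
    for _, row in df.iterrows():
        quads = frozenset(
            tuple(int(v) for v in pair.split(","))
            for pair in str(row["positive_quadrants"]).split(";")
            if pair and pair != "nan"
        )
        cd3 = np.array([int(v) for v in str(row["cd3_counts"]).split(";")],
                       dtype=np.int64).reshape(int(row["grid_rows"]), int(row["grid_cols"]))
        out.append(
            SlideAnnotation(
                slide_id=str(row["slide_id"]), genotype=str(row["genotype"]),
                grid_rows=int(row["grid_rows"]), grid_cols=int(row["grid_cols"]),
                positive_quadrants=quads, cd3_counts=cd3,
            )
        )
    return out


# ---------------------------------------------------------------------------
# run_all

def _effective_train_size(cfg: PipelineConfig, labels: pd.Series) -> int:
    """Training-set size per class: the configured protocol size, clamped so
    a validation remainder exists for small labeled pools."""
    counts = labels.value_counts()
    smallest = int(counts.min())
    n_eff = min(cfg.train_per_class, max(1, int(0.8 * smallest)))
    if n_eff < cfg.train_per_class:
        log.info("train set clamped to %d per class (smallest class has %d)",
                 n_eff, smallest)
    return n_eff


def run_all(manifest: RunManifest) -> dict:
    """Execute the full pipeline described by the manifest; return the report."""
    manifest.validate()  # fail fast: no partial outputs on a bad manifest
    out = Path(manifest.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = load_config(manifest.config_path)
    if manifest.seed is not None:
        cfg = cfg.replace(seed=int(manifest.seed))

    report: dict = {
        "mgmorph_version": __version__,
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "stages": {},
    }

    # --- detection --------------------------------------------------------
    genotypes = {e["image_id"]: e["genotype"] for e in manifest.images}
    feature_tables = []
    for entry in manifest.images:
        image = read_image(entry["path"])
        labeled, gated = run_detection(image, cfg, image_id=entry["image_id"])
        write_mask(labeled, out / f"{entry['image_id']}_labels.tif")
        feature_tables.append(gated)
    features = pd.concat(feature_tables, ignore_index=True) if feature_tables else pd.DataFrame()
    write_table(features, out / "objects_gated.tsv")
    report["stages"]["detection"] = {
        "n_images": len(manifest.images),
        "n_gated_objects": int(len(features)),
    }

    # --- classification ---------------------------------------------------
    if manifest.model_path is not None:
        model = load_model(manifest.model_path)
    else:
        labeled_df = read_table(manifest.object_labels_path, schema=OBJECT_LABEL_COLUMNS)
        merged = features.merge(labeled_df, on=["object_id", "image_id"], how="inner")
        n_eff = _effective_train_size(cfg, merged["label"])
        split = make_balanced_split(merged, merged["label"].to_numpy(),
                                    n_per_class=n_eff, seed=cfg.seed)
        model = train_forest(split, cfg)
        save_model(model, out / "classifier.joblib")
    cells, annotated = classify_objects(model, features)
    write_table(annotated, out / "objects_classified.tsv")
    report["stages"]["classification"] = {
        "n_trees": model.n_trees,
        "features_per_split": model.features_per_split,
        "validation_accuracy": model.validation_accuracy,
        "n_cells": int(len(cells)),
        "n_screened_out": int(len(annotated) - len(cells)),
    }

    # --- morphological states --------------------------------------------
    if len(cells) >= cfg.n_clusters:
        ranked = rank_scale(cells)
        assignment = cluster_states(ranked, cfg)
        assignment = assign_state_labels(assignment, cells, cfg)
        cells_out = cells.copy()
        cells_out["cluster"] = assignment.cluster
        cells_out["state"] = assignment.state
        write_table(cells_out, out / "cells_states.tsv")
        per_image, per_genotype = summarize_counts(
            assignment, cells["image_id"], genotypes
        )
        write_table(per_image, out / "state_counts_per_image.tsv")
        write_table(per_genotype, out / "state_counts_per_genotype.tsv")
        report["stages"]["morphostate"] = {
            "n_clusters": cfg.n_clusters,
            "cluster_scores": {str(k): v for k, v in sorted(assignment.cluster_scores.items())},
            "state_totals": {
                s: int((assignment.state == s).sum()) for s in np.unique(assignment.state)
            },
        }
    else:
        report["stages"]["morphostate"] = {"skipped": f"only {len(cells)} cells"}

    # --- bootstraps -------------------------------------------------------
    if manifest.label_table_path is not None:
        from .bootstrap import (bootstrap_celltype_counts, bootstrap_density,
                                compare_genotypes)

        label_table = read_table(manifest.label_table_path, schema=LABEL_TABLE_COLUMNS)
        counts = bootstrap_celltype_counts(label_table, cfg)
        write_table(counts.summary, out / "bootstrap_counts.tsv")
        density = bootstrap_density(label_table, cfg)
        for genotype, grid in density.grids.items():
            np.savetxt(out / f"density_{genotype}.tsv", grid, fmt="%.6g", delimiter="\t")
        with open(out / "density_extent.json", "w", encoding="utf-8") as fh:
            json.dump({"extent": density.extent, "bins": density.bins}, fh, sort_keys=True)
        report["stages"]["bootstrap"] = {
            "genotypes": list(counts.genotypes),
            "cell_types": list(counts.cell_types),
            "boot_n": counts.boot_n,
            "boot_reps": counts.boot_reps,
            "density_bins": density.bins,
        }
        if len(counts.genotypes) >= 2:
            gs = list(counts.genotypes)
            ref = "WT" if "WT" in gs else gs[0]
            con = "cKO" if "cKO" in gs else next(g for g in gs if g != ref)
            write_table(compare_genotypes(counts, reference=ref, contrast=con),
                        out / "bootstrap_comparison.tsv")

    # --- histomorphometry -------------------------------------------------
    if manifest.annotations_path is not None:
        ann_table = read_table(manifest.annotations_path, schema=ANNOTATION_COLUMNS)
        annotations = table_to_annotations(ann_table)
        scores = [score_quadrants(a) for a in annotations]
        slide_genotypes = {a.slide_id: a.genotype for a in annotations}
        summary = summarize_by_genotype(scores, slide_genotypes)
        write_table(summary, out / "histo_summary.tsv")
        report["stages"]["histomorphometry"] = {"n_slides": len(annotations)}

    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


# ---------------------------------------------------------------------------
# demo

@dataclass
class DemoResult:
    report: dict
    failures: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failures


def demo(seed: int = 0, out_dir: str | Path = "demo_out",
         n_train_images: int = 4, n_test_images: int = 8) -> DemoResult:
    """Generate a synthetic dataset, run the full pipeline, verify recovery.

    Checks: >= 90% of planted cells retained after detection + gate +
    classifier; <= 10% of retained objects are non-cells; three-state
    clustering vs planted archetypes reaches adjusted Rand index >= 0.8;
    bootstrap replicate conservation (asserted inside the bootstrap itself).
    """
    from sklearn.metrics import adjusted_rand_score

    out = Path(out_dir)
    data_dir = out / "data"
    data_dir.mkdir(parents=True, exist_ok=True)
    cfg = PipelineConfig(seed=seed)

    # -- synthesize images; train on the first block, analyze the rest
    image_entries = []
    truths: dict[str, SyntheticGroundTruth] = {}
    masks: dict[str, np.ndarray] = {}
    gated: dict[str, pd.DataFrame] = {}
    n_images = n_train_images + n_test_images
    from .io import RgbImage  # noqa: F401  (type only)
    import tifffile

    for i in range(n_images):
        image_id = f"img{i:02d}"
        genotype = "WT" if i % 2 == 0 else "cKO"
        image, truth = generate_ihc_image(
            n_round=5, n_bushy=5, n_dendritic=5, n_debris=18,
            seed=seed * 1009 + i,
        )
        path = data_dir / f"{image_id}.tif"
        tifffile.imwrite(path, (image.pixels * 65535).astype("uint16"))
        image_entries.append({"path": str(path), "image_id": image_id,
                              "genotype": genotype})
        truths[image_id] = truth
        labeled, feats = run_detection(image, cfg, image_id=image_id)
        masks[image_id] = labeled
        gated[image_id] = feats

    # -- ground-truth object labels for the training images
    label_rows = []
    for entry in image_entries[:n_train_images]:
        iid = entry["image_id"]
        lbl = label_from_ground_truth(gated[iid], masks[iid], truths[iid])
        for oid, lab in zip(gated[iid]["object_id"], lbl):
            label_rows.append((int(oid), iid, lab))
    object_labels = pd.DataFrame(label_rows, columns=list(OBJECT_LABEL_COLUMNS))
    write_table(object_labels, data_dir / "object_labels.tsv")

    # -- single-cell label table and slide annotations
    label_table = generate_label_table(seed=seed)
    write_table(label_table, data_dir / "cell_labels.tsv")
    annotations = [
        generate_slide_annotation(seed=seed, slide_id=f"slide{j}",
                                  genotype="WT" if j % 2 == 0 else "cKO")
        for j in range(6)
    ]
    write_table(annotations_to_table(annotations), data_dir / "annotations.tsv")
    plaque, wm = generate_myelin_masks(seed=seed)
    write_mask(plaque, data_dir / "slide0_myelin.tif")
    write_mask(wm, data_dir / "slide0_wm.tif")

    manifest = RunManifest(
        images=tuple(image_entries),
        out_dir=str(out / "results"),
        object_labels_path=str(data_dir / "object_labels.tsv"),
        label_table_path=str(data_dir / "cell_labels.tsv"),
        annotations_path=str(data_dir / "annotations.tsv"),
        seed=seed,
    )
    report = run_all(manifest)

    # -- recovery checks on the analysis images
    failures: list[str] = []
    classified = read_table(Path(manifest.out_dir) / "objects_classified.tsv")
    test_ids = [e["image_id"] for e in image_entries[n_train_images:]]
    truth_labels, truth_arch, kept_flags = [], [], []
    for iid in test_ids:
        matches = match_to_ground_truth(masks[iid], truths[iid]).set_index("object_id")
        sub = classified.loc[classified["image_id"] == iid]
        for _, row in sub.iterrows():
            m = matches.loc[int(row["object_id"])]
            is_cell = (m["archetype"] in CELL_ARCHETYPES
                       and m["intersection_px"] >= 0.5 * m["detected_area_px"])
            truth_labels.append("cell" if is_cell else "noncell")
            truth_arch.append(m["archetype"])
            kept_flags.append(bool(row["is_cell"]))
    truth_labels = np.array(truth_labels)
    kept_flags = np.array(kept_flags)
    n_planted_cells = sum(
        len(truths[iid].cells) for iid in test_ids
    )
    n_cells_kept = int((kept_flags & (truth_labels == "cell")).sum())
    retention = n_cells_kept / n_planted_cells if n_planted_cells else 0.0
    if retention < 0.9:
        failures.append(f"cell retention {retention:.3f} < 0.9")
    n_kept = int(kept_flags.sum())
    n_noncells_kept = int((kept_flags & (truth_labels == "noncell")).sum())
    noncell_frac = n_noncells_kept / n_kept if n_kept else 0.0
    if noncell_frac > 0.1:
        failures.append(f"retained non-cell fraction {noncell_frac:.3f} > 0.1")

    cells_states = read_table(Path(manifest.out_dir) / "cells_states.tsv")
    arch_by_key = {}
    for iid in test_ids:
        matches = match_to_ground_truth(masks[iid], truths[iid]).set_index("object_id")
        for oid, m in matches.iterrows():
            arch_by_key[(iid, int(oid))] = m["archetype"]
    mask_rows = [
        (row["image_id"], int(row["object_id"])) in arch_by_key
        and arch_by_key[(row["image_id"], int(row["object_id"]))] in CELL_ARCHETYPES
        for _, row in cells_states.iterrows()
    ]
    matched = cells_states.loc[mask_rows]
    if len(matched) >= 10:
        planted_states = [arch_by_key[(r["image_id"], int(r["object_id"]))]
                          for _, r in matched.iterrows()]
        ari = adjusted_rand_score(planted_states, matched["cluster"])
        report["stages"]["morphostate"]["ari_vs_planted"] = float(ari)
        if ari < 0.8:
            failures.append(f"state ARI {ari:.3f} < 0.8")
    else:
        failures.append("too few matched cells for the ARI check")

    report["demo_checks"] = {
        "cell_retention": retention,
        "noncell_retained_fraction": noncell_frac,
        "failures": failures,
    }
    with open(out / "demo_report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    if failures:
        log.error("demo checks failed: %s", failures)
    return DemoResult(report=report, failures=failures)
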