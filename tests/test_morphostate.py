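"""Rank scaling, complete-linkage clustering, and state labeling."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster, linkage

from mgmorph.config import PipelineConfig
from mgmorph.errors import DegenerateInputError, LabelingError, MetadataError
from mgmorph.io import FEATURE_PANEL, MORPHOLOGY_PANEL
from mgmorph.morphostate import (StateAssignment, assign_state_labels,
                                 cluster_states, rank_scale, summarize_counts)

from _oracles import complete_linkage_oracle


def feature_frame(X: np.ndarray) -> pd.DataFrame:
    """Wrap a numeric matrix as a feature table over the morphology panel."""
    reps = int(np.ceil(len(MORPHOLOGY_PANEL) / X.shape[1]))
    wide = np.tile(X, (1, reps))[:, : len(MORPHOLOGY_PANEL)]
    df = pd.DataFrame(wide, columns=list(MORPHOLOGY_PANEL))
    df.insert(0, "image_id", "img")
    df.insert(0, "object_id", np.arange(1, len(df) + 1))
    return df


def partitions_equal(a: np.ndarray, b: np.ndarray) -> bool:
    return len(set(zip(a, b))) == len(set(a)) == len(set(b))


class TestRankScale:
    def test_simple_and_tied_ranks(self):
        df = pd.DataFrame({"area_px": [10.0, 30.0, 20.0], "radius_sd": [5.0, 5.0, 7.0]})
        out = rank_scale(df, columns=("area_px", "radius_sd"))
        assert list(out["area_px"]) == [1.0, 3.0, 2.0]
        assert list(out["radius_sd"]) == [1.5, 1.5, 3.0]

    def test_monotone_transform_invariance(self, rng):
        df = pd.DataFrame({"area_px": rng.random(40) * 100 + 1})
        logged = df.assign(area_px=np.log(df["area_px"]))
        a = rank_scale(df, columns=("area_px",))
        b = rank_scale(logged, columns=("area_px",))
        np.testing.assert_array_equal(a["area_px"], b["area_px"])

    def test_rank_multiset_is_1_to_n(self, rng):
        df = pd.DataFrame({"area_px": rng.integers(0, 10, size=25).astype(float)})
        out = rank_scale(df, columns=("area_px",))
        assert out["area_px"].sum() == 25 * 26 / 2  # average ranks conserve the sum

    def test_empty_rejected(self):
        with pytest.raises(DegenerateInputError):
            rank_scale(pd.DataFrame({"area_px": []}))


class TestClusterStates:
    def test_three_separated_clouds_recovered(self, cfg, rng):
        # clouds whose per-feature orderings differ, as the archetypes' do
        # (e.g. ramified cells are small in area but large in perimeter), so
        # rank scaling keeps them apart
        centers = np.array([
            [0, 0, 0, 0, 0, 0, 0],
            [100, -100, 100, -100, 100, -100, 100],
            [-100, 100, 100, 100, -100, 100, -100],
        ], dtype=float)
        X = np.vstack([c + rng.normal(0, 1, size=(20, 7)) for c in centers])
        truth = np.repeat([1, 2, 3], 20)
        df = pd.DataFrame(X, columns=list(MORPHOLOGY_PANEL))
        labels = cluster_states(rank_scale(df), cfg).cluster
        assert partitions_equal(labels, truth)

    def test_n_equals_k_gives_singletons(self, cfg):
        ranked = rank_scale(feature_frame(np.array([[0.0], [10.0], [20.0]])))
        labels = cluster_states(ranked, cfg).cluster
        assert sorted(labels) == [1, 2, 3]

    def test_duplicates_co_clustered(self, cfg, rng):
        X = rng.normal(size=(10, 3))
        X[7] = X[2]  # exact duplicate: zero distance merges first
        ranked = rank_scale(feature_frame(X))
        labels = cluster_states(ranked, cfg).cluster
        assert labels[7] == labels[2]

    def test_too_few_objects_rejected(self, cfg):
        with pytest.raises(DegenerateInputError):
            cluster_states(rank_scale(feature_frame(np.zeros((2, 2)))), cfg)

    def test_matches_brute_force_oracle(self, cfg, rng):
        for trial in range(25):
            n = int(rng.integers(5, 30))
            X = rng.normal(size=(n, 4))
            ranked = rank_scale(feature_frame(X))
            Xr = ranked[list(MORPHOLOGY_PANEL)].to_numpy(float)
            ours = cluster_states(ranked, cfg).cluster
            np.testing.assert_array_equal(ours, complete_linkage_oracle(Xr, 3))

    def test_matches_scipy_on_continuous_data(self, cfg, rng):
        """Independent cross-check: on tie-free continuous data the complete
        linkage partition is unique, so scipy must agree."""
        for _ in range(15):
            n = int(rng.integers(8, 35))
            df = feature_frame(rng.normal(size=(n, 5)))
            ours = cluster_states(df, cfg).cluster  # raw continuous features
            Z = linkage(df[list(MORPHOLOGY_PANEL)].to_numpy(float), method="complete")
            theirs = fcluster(Z, t=3, criterion="maxclust")
            assert partitions_equal(ours, theirs)

    def test_rank_then_monotone_transform_preserves_clusters(self, cfg, rng):
        df = feature_frame(rng.normal(size=(30, 4)))
        cubed = df.copy()
        for c in MORPHOLOGY_PANEL:
            cubed[c] = cubed[c] ** 3  # strictly increasing on all reals
        a = cluster_states(rank_scale(df), cfg).cluster
        b = cluster_states(rank_scale(cubed), cfg).cluster
        np.testing.assert_array_equal(a, b)


class TestStateLabels:
    def make_archetype_frame(self):
        """Disk-like, star-like, and intermediate rows with known ramification
        ordering via perimeter^2/area and radius_sd."""
        rows = []
        for i in range(10):  # round: compact, tiny radius spread
            rows.append(dict(area_px=300 + i, perimeter_px=60, radius_sd=0.3))
        for i in range(10):  # bushy: intermediate
            rows.append(dict(area_px=320 + i, perimeter_px=110, radius_sd=4.5))
        for i in range(10):  # dendritic: boundary-dominated, wide radius spread
            rows.append(dict(area_px=200 + i, perimeter_px=170, radius_sd=7.0))
        df = pd.DataFrame(rows)
        for c in MORPHOLOGY_PANEL:
            if c not in df.columns:
                df[c] = 1.0
        return df

    def test_ramification_ordering_maps_states(self, cfg):
        df = self.make_archetype_frame()
        clusters = np.repeat([1, 2, 3], 10)
        out = assign_state_labels(StateAssignment(cluster=clusters), df, cfg)
        assert set(out.state[:10]) == {"activated"}
        assert set(out.state[10:20]) == {"activating"}
        assert set(out.state[20:]) == {"homeostatic"}
        scores = out.cluster_scores
        assert scores[1] < scores[2] < scores[3]

    def test_manual_override_echoed(self):
        cfg = PipelineConfig(state_override={1: "homeostatic", 2: "activated",
                                            3: "activating"})
        df = self.make_archetype_frame()
        clusters = np.repeat([1, 2, 3], 10)
        out = assign_state_labels(StateAssignment(cluster=clusters), df, cfg)
        assert set(out.state[:10]) == {"homeostatic"}

    def test_score_tie_requires_override(self, cfg):
        df = self.make_archetype_frame()
        df.iloc[10:20] = df.iloc[:10].to_numpy()  # clusters 1 and 2 identical
        clusters = np.repeat([1, 2, 3], 10)
        with pytest.raises(LabelingError, match="tie"):
            assign_state_labels(StateAssignment(cluster=clusters), df, cfg)
        # but an explicit override resolves it
        cfg_ov = cfg.replace(state_override={1: "activated", 2: "activating",
                                             3: "homeostatic"})
        out = assign_state_labels(StateAssignment(cluster=clusters), df, cfg_ov)
        assert set(out.state[:10]) == {"activated"}


class TestSummarizeCounts:
    def test_single_image_all_one_state(self):
        a = StateAssignment(cluster=np.ones(10, dtype=int),
                            state=np.array(["activated"] * 10, dtype=object))
        per_image, per_geno = summarize_counts(a, np.array(["img1"] * 10),
                                               {"img1": "WT"})
        row = per_image.iloc[0]
        assert (row["activated"], row["activating"], row["homeostatic"]) == (10, 0, 0)

    def test_genotype_mean_sd_hand_arithmetic(self):
        states = np.array(["activated"] * 4 + ["activated"] * 6, dtype=object)
        images = np.array(["a"] * 4 + ["b"] * 6)
        a = StateAssignment(cluster=np.ones(10, dtype=int), state=states)
        _, per_geno = summarize_counts(a, images, {"a": "WT", "b": "WT"})
        row = per_geno.loc[per_geno["state"] == "activated"].iloc[0]
        assert row["mean"] == 5.0
        np.testing.assert_allclose(row["sd"], np.sqrt(2.0))

    def test_totals_conserved(self, rng):
        n = 50
        states = rng.choice(["activated", "activating", "homeostatic"], size=n)
        images = rng.choice(["i1", "i2", "i3"], size=n)
        a = StateAssignment(cluster=np.ones(n, dtype=int), state=states.astype(object))
        per_image, _ = summarize_counts(
            a, images, {"i1": "WT", "i2": "WT", "i3": "cKO"}
        )
        assert per_image[["activated", "activating", "homeostatic"]].to_numpy().sum() == n

    def test_missing_genotype_rejected(self):
        a = StateAssignment(cluster=np.ones(2, dtype=int),
                            state=np.array(["activated"] * 2, dtype=object))
        with pytest.raises(MetadataError):
            summarize_counts(a, np.array(["x", "y"]), {"x": "WT"})

    def test_empty_assignment(self):
        a = StateAssignment(cluster=np.array([], dtype=int),
                            state=np.array([], dtype=object))
        per_image, per_geno = summarize_counts(a, np.array([]), {})
        assert len(per_image) == 0 and len(per_geno) == 0
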