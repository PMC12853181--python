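"""Posture features, the geometric rule, the forest classifier, and bouts."""

import numpy as np
import pandas as pd
import pytest

from kagenor import detection
from kagenor.core import CageLayout, ExplorationSeries, KeypointTrack, TrackFormatError
from kagenor.synthetic import simulate_session

from conftest import class_codes, short_config


def make_track(snout, ears_mid_offset=(6.0, 0.0), likelihood=1.0, n=1):
    """Single-posture track: snout at `snout`, head axis along -offset."""
    snout = np.tile(np.asarray(snout, dtype=float), (n, 1))
    off = np.asarray(ears_mid_offset, dtype=float)
    ears_mid = snout - off
    perp = np.array([-off[1], off[0]])
    perp = perp / max(np.linalg.norm(perp), 1e-9) * 5.0
    coords = {
        "snout": snout,
        "ear_left": ears_mid + perp,
        "ear_right": ears_mid - perp,
        "spine_1": ears_mid - off,
        "tail_base": ears_mid - 3 * off,
    }
    lik = {p: np.full(n, likelihood) for p in coords}
    return KeypointTrack.from_arrays(coords, lik)


class TestFeatures:
    def test_snout_at_window_center_gives_zero_distance(self, layout):
        win = layout.object_window_left
        feats = detection.extract_features(make_track((win.x, win.y)), layout)
        assert feats.table["dist_left_cm"].iloc[0] == pytest.approx(0.0)

    def test_pixel_to_cm_conversion(self, layout):
        win = layout.object_window_left
        feats = detection.extract_features(make_track((win.x + 10.0, win.y)), layout)
        assert feats.table["dist_left_cm"].iloc[0] == pytest.approx(2.0)  # 10 px at 5 px/cm

    def test_head_axis_at_object_gives_zero_alignment(self, layout):
        win = layout.object_window_left
        # snout 20 px right of the window, head axis pointing left at it
        feats = detection.extract_features(
            make_track((win.x + 20.0, win.y), ears_mid_offset=(-6.0, 0.0)), layout
        )
        assert feats.table["align_left_deg"].iloc[0] == pytest.approx(0.0, abs=1e-6)

    def test_missing_bodypart_named_in_error(self, layout):
        track = make_track((10, 10))
        track.data = track.data.drop(columns=["ear_left"], level=0)
        with pytest.raises(TrackFormatError, match="ear_left"):
            detection.extract_features(track, layout)


class TestRuleClassifier:
    def test_inside_both_thresholds_is_exploratory(self, layout):
        win = layout.object_window_left
        feats = detection.extract_features(
            make_track((win.x + 5.0, win.y), ears_mid_offset=(-6.0, 0.0)), layout
        )
        series = detection.rule_classify(feats)
        assert series.explore_left[0]

    def test_outside_distance_not_exploratory(self, layout):
        win = layout.object_window_left
        feats = detection.extract_features(
            make_track((win.x + 50.0, win.y), ears_mid_offset=(-6.0, 0.0)), layout
        )
        assert not detection.rule_classify(feats).any_explore[0]

    def test_unreliable_frame_outside_bout_is_false(self, layout):
        win = layout.object_window_left
        feats = detection.extract_features(
            make_track((win.x + 5.0, win.y), ears_mid_offset=(-6.0, 0.0), likelihood=0.1),
            layout,
        )
        assert not detection.rule_classify(feats).any_explore[0]

    def test_shrinking_thresholds_never_adds_frames(self, features):
        loose = detection.rule_classify(features, 3.0, 45.0).any_explore
        for dist, ang in [(2.0, 45.0), (3.0, 30.0), (1.5, 20.0)]:
            tight = detection.rule_classify(features, dist, ang).any_explore
            assert not np.any(tight & ~loose)

    def test_invalid_thresholds(self, features):
        with pytest.raises(ValueError):
            detection.rule_classify(features, -1.0, 45.0)


class TestForest:
    def test_holdout_accuracy_on_synthetic_geometry(self, session, features):
        model = detection.train_forest(features, session.labels, seed=0)
        assert model.holdout_balanced_accuracy is not None
        assert model.holdout_balanced_accuracy >= 0.9

    def test_forest_at_least_matches_rule_baseline(self, session, features, rule_series):
        from sklearn.metrics import balanced_accuracy_score

        model = detection.train_forest(features, session.labels, seed=0)
        pred = detection.predict(model, features)
        truth = class_codes(session.labels)
        ba_forest = balanced_accuracy_score(truth, class_codes(pred))
        ba_rule = balanced_accuracy_score(truth, class_codes(rule_series))
        assert ba_forest >= ba_rule - 0.02

    def test_permuted_labels_destroy_information(self, session, features):
        rng = np.random.default_rng(0)
        perm = rng.permutation(session.labels.n_frames)
        shuffled = ExplorationSeries(
            session.labels.explore_left[perm], session.labels.explore_right[perm]
        )
        model = detection.train_forest(features, shuffled, seed=0)
        # chance level for the three classes (none / left / right) is 1/3
        assert model.holdout_balanced_accuracy == pytest.approx(1 / 3, abs=0.15)

    def test_determinism(self, session, features):
        m1 = detection.train_forest(features, session.labels, seed=5)
        m2 = detection.train_forest(features, session.labels, seed=5)
        p1 = detection.predict(m1, features)
        p2 = detection.predict(m2, features)
        assert np.array_equal(p1.explore_left, p2.explore_left)
        assert np.array_equal(p1.explore_right, p2.explore_right)

    def test_generalizes_across_sessions(self, session, features):
        model = detection.train_forest(features, session.labels, seed=0)
        other = simulate_session(short_config(seed=777))
        feats_b = detection.extract_features(other.keypoints, other.layout)
        pred = detection.predict(model, feats_b)
        truth_frames = np.flatnonzero(other.labels.any_explore)
        pred_frames = np.flatnonzero(pred.any_explore)
        overlap = np.isin(truth_frames, pred_frames).mean()
        assert overlap >= 0.8

    def test_single_class_labels_rejected(self, features):
        n = features.n_frames
        empty = ExplorationSeries(np.zeros(n, bool), np.zeros(n, bool))
        with pytest.raises(ValueError):
            detection.train_forest(features, empty)

    def test_empty_features_give_empty_series(self, session, features):
        model = detection.train_forest(features, session.labels, seed=0)
        empty = detection.PostureFeatures(
            table=features.table.iloc[:0], reliable=np.zeros(0, bool), frame_rate=2.0
        )
        assert detection.predict(model, empty).n_frames == 0

    def test_all_unreliable_gives_all_false(self, session, features):
        model = detection.train_forest(features, session.labels, seed=0)
        gated = detection.PostureFeatures(
            table=features.table, reliable=np.zeros(features.n_frames, bool), frame_rate=2.0
        )
        assert not detection.predict(model, gated).any_explore.any()

    def test_schema_mismatch_lists_missing(self, session, features):
        model = detection.train_forest(features, session.labels, seed=0)
        broken = detection.PostureFeatures(
            table=features.table.drop(columns=["speed_cm_s"]),
            reliable=features.reliable,
            frame_rate=2.0,
        )
        with pytest.raises(TrackFormatError, match="speed_cm_s"):
            detection.predict(model, broken)


class TestBouts:
    def test_run_length_encoding(self):
        left = np.array([True, True, False, True])
        series = ExplorationSeries(left, np.zeros(4, bool), frame_rate=2.0)
        bouts = detection.segment_bouts(series)
        assert list(bouts["duration_s"]) == [1.0, 0.5]
        assert list(bouts["side"]) == ["left", "left"]

    def test_all_false_gives_empty_table(self):
        series = ExplorationSeries(np.zeros(10, bool), np.zeros(10, bool))
        assert len(detection.segment_bouts(series)) == 0

    def test_duration_conservation(self, rule_series):
        bouts = detection.segment_bouts(rule_series)
        assert bouts["duration_s"].sum() == pytest.approx(
            rule_series.any_explore.sum() * 0.5
        )

    def test_postprocess_closes_gaps_and_drops_short_bouts(self):
        left = np.array([True, True, False, True, True, False, False, True, False])
        series = ExplorationSeries(left, np.zeros(9, bool), frame_rate=2.0)
        out = detection.postprocess_series(series, max_gap_frames=1, min_bout_frames=2)
        # the 1-frame gap closes into one 5-frame bout; the isolated frame drops
        assert np.array_equal(out.explore_left, [True] * 5 + [False] * 4)
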