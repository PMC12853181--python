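"""Per-frame exploration classification from keypoint posture.

Object exploration is the posture where the animal faces the object with its
snout close to it.  Two classifiers expose that definition:

* ``rule_classify`` — a transparent geometric baseline: a frame is
  exploratory on a side iff the snout sits within ``max_distance_cm`` of that
  side's object window and the head axis (ears-midpoint -> snout) points at
  the window within ``max_angle_deg``.
* ``train_forest`` / ``predict`` — a random-forest classifier on the same
  posture features, mirroring the production pipeline where exploration is
  identified by a custom-trained ensemble.

Both emit an :class:`~kagenor.core.ExplorationSeries`; ``segment_bouts``
converts frame labels into an event table of maximal same-side runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import balanced_accuracy_score

from .core import CageLayout, ExplorationSeries, KeypointTrack, TrackFormatError

__all__ = [
    "PostureFeatures",
    "ForestModel",
    "extract_features",
    "rule_classify",
    "train_forest",
    "predict",
    "postprocess_series",
    "segment_bouts",
    "DEFAULT_MAX_DISTANCE_CM",
    "DEFAULT_MAX_ANGLE_DEG",
    "DEFAULT_CONFIDENCE_FLOOR",
]

DEFAULT_MAX_DISTANCE_CM = 3.0
DEFAULT_MAX_ANGLE_DEG = 45.0
DEFAULT_CONFIDENCE_FLOOR = 0.6

REQUIRED_PARTS = ("snout", "ear_left", "ear_right", "tail_base")

FEATURE_COLUMNS = (
    "dist_left_cm",
    "dist_right_cm",
    "align_left_deg",
    "align_right_deg",
    "elongation_cm",
    "speed_cm_s",
)


@dataclass
class PostureFeatures:
    """Per-frame, per-side posture features plus a reliability flag.

    ``table`` columns: snout-object distance and heading alignment for each
    side, body elongation (snout to tail base) and body-centre speed, all in
    cm / cm s^-1 / degrees.  ``reliable`` flags frames whose snout confidence
    reaches the configured floor.
    """

    table: pd.DataFrame
    reliable: np.ndarray
    frame_rate: float

    @property
    def n_frames(self) -> int:
        return len(self.table)


def _angle_deg(v1: np.ndarray, v2: np.ndarray) -> np.ndarray:
    """Angle between row vectors in degrees; zero-length vectors give 0."""
    n1 = np.linalg.norm(v1, axis=1)
    n2 = np.linalg.norm(v2, axis=1)
    denom = n1 * n2
    cos = np.einsum("ij,ij->i", v1, v2)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = np.where(denom > 1e-9, cos / np.maximum(denom, 1e-9), 1.0)
    return np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))


def extract_features(
    track: KeypointTrack,
    layout: CageLayout,
    confidence_floor: float = DEFAULT_CONFIDENCE_FLOOR,
) -> PostureFeatures:
    """Compute the posture feature table from a keypoint track."""
    track.require_bodyparts(REQUIRED_PARTS)
    snout = track.xy("snout")
    ears_mid = 0.5 * (track.xy("ear_left") + track.xy("ear_right"))
    tail = track.xy("tail_base")
    spine_parts = [p for p in track.bodyparts if p.startswith("spine")]
    if spine_parts:
        body_center = np.mean([track.xy(p) for p in spine_parts], axis=0)
    else:
        body_center = 0.5 * (ears_mid + tail)

    head_axis = snout - ears_mid
    cols: dict[str, np.ndarray] = {}
    for side in ("left", "right"):
        win = layout.object_window(side)
        to_obj = win.center[None, :] - snout
        cols[f"dist_{side}_cm"] = layout.px_to_cm(np.linalg.norm(to_obj, axis=1))
        cols[f"align_{side}_deg"] = _angle_deg(head_axis, to_obj)
    cols["elongation_cm"] = layout.px_to_cm(np.linalg.norm(snout - tail, axis=1))
    disp = np.vstack([np.zeros((1, 2)), np.diff(body_center, axis=0)])
    cols["speed_cm_s"] = layout.px_to_cm(np.linalg.norm(disp, axis=1)) * track.frame_rate

    reliable = track.likelihood("snout") >= confidence_floor
    return PostureFeatures(
        table=pd.DataFrame(cols), reliable=reliable, frame_rate=track.frame_rate
    )


def _inherit_unreliable(left: np.ndarray, right: np.ndarray, reliable: np.ndarray) -> None:
    """In place: an unreliable frame inherits the previous frame's label only
    when that frame is inside a bout; otherwise it stays non-exploratory."""
    for i in np.flatnonzero(~reliable):
        if i > 0:
            left[i] = left[i - 1]
            right[i] = right[i - 1]
        else:
            left[i] = right[i] = False


def rule_classify(
    features: PostureFeatures,
    max_distance_cm: float = DEFAULT_MAX_DISTANCE_CM,
    max_angle_deg: float = DEFAULT_MAX_ANGLE_DEG,
) -> ExplorationSeries:
    """Geometric baseline classifier.

    A side qualifies when distance <= ``max_distance_cm`` and alignment
    <= ``max_angle_deg``; if both sides qualify on one frame the nearer
    object wins (the cage geometry makes dual exploration impossible).
    """
    if max_distance_cm <= 0 or max_angle_deg <= 0:
        raise ValueError("thresholds must be positive")
    t = features.table
    ok_l = (t["dist_left_cm"].to_numpy() <= max_distance_cm) & (
        t["align_left_deg"].to_numpy() <= max_angle_deg
    )
    ok_r = (t["dist_right_cm"].to_numpy() <= max_distance_cm) & (
        t["align_right_deg"].to_numpy() <= max_angle_deg
    )
    both = ok_l & ok_r
    nearer_left = t["dist_left_cm"].to_numpy() <= t["dist_right_cm"].to_numpy()
    left = ok_l & (~both | nearer_left)
    right = ok_r & (~both | ~nearer_left)
    left = left & features.reliable
    right = right & features.reliable
    left, right = left.copy(), right.copy()
    _inherit_unreliable(left, right, features.reliable)
    return ExplorationSeries(left, right, frame_rate=features.frame_rate)


def _labels_to_classes(series: ExplorationSeries) -> np.ndarray:
    """0 = none, 1 = left, 2 = right."""
    return np.where(series.explore_left, 1, np.where(series.explore_right, 2, 0))


@dataclass
class ForestModel:
    """Trained random-forest exploration classifier with its feature schema."""

    estimator: RandomForestClassifier
    feature_columns: tuple[str, ...]
    frame_rate: float
    holdout_balanced_accuracy: float | None = None


def train_forest(
    features: PostureFeatures,
    labels: ExplorationSeries,
    n_estimators: int = 100,
    max_depth: int | None = None,
    holdout_fraction: float = 0.2,
    seed: int = 0,
) -> ForestModel:
    """Train the ensemble classifier on posture features.

    The last ``holdout_fraction`` of frames is held out to report a balanced
    accuracy (a temporal split avoids leakage between adjacent frames of one
    bout).  Deterministic under a fixed seed.
    """
    y = _labels_to_classes(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    X = features.table[list(FEATURE_COLUMNS)].to_numpy()
    n = len(y)
    cut = int(round(n * (1.0 - holdout_fraction)))
    clf = RandomForestClassifier(
        n_estimators=n_estimators, max_depth=max_depth, random_state=seed, n_jobs=1
    )
    clf.fit(X[:cut], y[:cut])
    ba = None
    if cut < n and len(np.unique(y[cut:])) > 1:
        ba = float(balanced_accuracy_score(y[cut:], clf.predict(X[cut:])))
    return ForestModel(
        estimator=clf,
        feature_columns=FEATURE_COLUMNS,
        frame_rate=features.frame_rate,
        holdout_balanced_accuracy=ba,
    )


def _close_gaps(mask: np.ndarray, max_gap: int) -> np.ndarray:
    if max_gap <= 0:
        return mask
    out = mask.copy()
    runs = _runs(~mask)
    for start, end in runs:
        if start > 0 and end < len(mask) and (end - start) <= max_gap:
            out[start:end] = True
    return out


def _drop_short(mask: np.ndarray, min_len: int) -> np.ndarray:
    if min_len <= 1:
        return mask
    out = mask.copy()
    for start, end in _runs(mask):
        if (end - start) < min_len:
            out[start:end] = False
    return out


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) index runs of True."""
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts, ends))


def postprocess_series(
    series: ExplorationSeries, max_gap_frames: int = 1, min_bout_frames: int = 2
) -> ExplorationSeries:
    """Close single-frame gaps and drop sub-minimum bouts, per side.

    Smooths label flicker at 2 fps; gap closing runs first so a bout split by
    one dropped frame survives the minimum-duration filter.
    """
    out = {}
    for side in ("left", "right"):
        mask = series.side(side).copy()
        mask = _close_gaps(mask, max_gap_frames)
        mask = _drop_short(mask, min_bout_frames)
        out[side] = mask
    both = out["left"] & out["right"]
    out["right"][both] = False  # gap closing may collide across sides; left wins
    return ExplorationSeries(out["left"], out["right"], frame_rate=series.frame_rate)


def predict(
    model: ForestModel,
    features: PostureFeatures,
    max_gap_frames: int = 1,
    min_bout_frames: int = 2,
) -> ExplorationSeries:
    """Apply a trained forest; unreliable frames are forced non-exploratory
    before the gap-closing / minimum-bout post-processing."""
    missing = [c for c in model.feature_columns if c not in features.table.columns]
    if missing:
        raise TrackFormatError(f"feature schema mismatch, missing: {', '.join(missing)}")
    if features.n_frames == 0:
        empty = np.zeros(0, dtype=bool)
        return ExplorationSeries(empty, empty, frame_rate=features.frame_rate)
    X = features.table[list(model.feature_columns)].to_numpy()
    y = model.estimator.predict(X)
    y[~features.reliable] = 0
    series = ExplorationSeries(y == 1, y == 2, frame_rate=features.frame_rate)
    return postprocess_series(series, max_gap_frames, min_bout_frames)


def segment_bouts(series: ExplorationSeries) -> pd.DataFrame:
    """Event table of maximal same-side exploration runs.

    Durations are frame counts over the frame rate, so summed durations equal
    (1 / frame_rate) x number of true frames, exactly.
    """
    rows = []
    for side in ("left", "right"):
        for start, end in _runs(series.side(side)):
            rows.append(
                {
                    "side": side,
                    "start_frame": int(start),
                    "end_frame": int(end),
                    "start_s": start / series.frame_rate,
                    "end_s": end / series.frame_rate,
                    "duration_s": (end - start) / series.frame_rate,
                }
            )
    df = pd.DataFrame(
        rows, columns=["side", "start_frame", "end_frame", "start_s", "end_s", "duration_s"]
    )
    return df.sort_values("start_frame", kind="stable").reset_index(drop=True)
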