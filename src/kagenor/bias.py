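"""Nest-position and activity-history bias analyses.

Nest bias: the nest is where the mouse dwells longest, so its location is
the argmax of a dwell-time heatmap over the sample and retention phases.
Distances from the nest to the two object windows feed a k-means (k=2)
clustering of the cohort into nest-left and nest-right groups, whose
per-side object exploration is then compared.

Corridor bias: for every interval between two consecutive drinking-corridor
visits, the first object explored is scored 0 if it lies on the same side as
the exited corridor and 1 otherwise; a mean of 0.5 indicates no
proximity-based strategy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from . import stats
from .core import CageLayout, KeypointTrack, PhaseSchedule
from .synthetic import CorridorVisit

__all__ = [
    "NestResult",
    "CorridorScore",
    "dwell_heatmap",
    "locate_nest",
    "assign_nest_sides",
    "nest_bias_test",
    "corridor_scores",
]


@dataclass
class NestResult:
    """Dwell heatmap, detected nest cell, and object distances for one mouse."""

    heatmap: np.ndarray  # seconds per cell, indexed [iy, ix]
    x_edges: np.ndarray
    y_edges: np.ndarray
    nest_xy: tuple[float, float]  # centre of the maximum-dwell cell, px
    d_left_cm: float
    d_right_cm: float


def dwell_heatmap(
    track: KeypointTrack,
    layout: CageLayout,
    grid_cm: float = 1.0,
    schedule: PhaseSchedule | None = None,
    phases: Sequence[str] = ("sample", "retention"),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Dwell-time heatmap (seconds per grid cell) of the body centre.

    Restricted to the given phases when a schedule is supplied.  Total mass
    equals the tracked time used: each frame contributes 1/frame_rate s.
    """
    if track.n_frames == 0:
        raise ValueError("empty keypoint track")
    if grid_cm <= 0:
        raise ValueError("grid must be positive")
    spine_parts = [p for p in track.bodyparts if p.startswith("spine")]
    if spine_parts:
        center = np.mean([track.xy(p) for p in spine_parts], axis=0)
    else:
        center = track.xy("snout")
    mask = np.zeros(track.n_frames, dtype=bool)
    if schedule is not None:
        for name in phases:
            if schedule.has_phase(name):
                sl = schedule.frame_slice(name, track.frame_rate)
                mask[sl] = True
    else:
        mask[:] = True
    pts = center[mask]
    cell_px = grid_cm * layout.px_per_cm
    x_edges = np.arange(0.0, layout.width_px + cell_px, cell_px)
    y_edges = np.arange(0.0, layout.height_px + cell_px, cell_px)
    h, _, _ = np.histogram2d(
        np.clip(pts[:, 1], 0, layout.height_px - 1e-9),
        np.clip(pts[:, 0], 0, layout.width_px - 1e-9),
        bins=(y_edges, x_edges),
    )
    return h / track.frame_rate, x_edges, y_edges


def locate_nest(
    track: KeypointTrack,
    layout: CageLayout,
    grid_cm: float = 1.0,
    schedule: PhaseSchedule | None = None,
) -> NestResult:
    """Detect the nest as the maximum-dwell cell and measure its distance to
    each object window."""
    h, x_edges, y_edges = dwell_heatmap(track, layout, grid_cm, schedule)
    iy, ix = np.unravel_index(np.argmax(h), h.shape)
    nest = np.array(
        [(x_edges[ix] + x_edges[ix + 1]) / 2.0, (y_edges[iy] + y_edges[iy + 1]) / 2.0]
    )
    d_left = layout.px_to_cm(np.linalg.norm(nest - layout.object_window_left.center))
    d_right = layout.px_to_cm(np.linalg.norm(nest - layout.object_window_right.center))
    return NestResult(
        heatmap=h,
        x_edges=x_edges,
        y_edges=y_edges,
        nest_xy=(float(nest[0]), float(nest[1])),
        d_left_cm=float(d_left),
        d_right_cm=float(d_right),
    )


def assign_nest_sides(
    nest_results: Sequence[NestResult], seed: int = 0, n_restarts: int = 10
) -> list[str]:
    """Group mice into nest-left / nest-right via k-means on the
    (distance-to-left, distance-to-right) vectors.

    Cluster identity is resolved by comparing each cluster's mean distances;
    degenerate cohorts (a single mouse, identical nests, or clusters that
    both sit on one side) fall back to the per-mouse nearest-object rule.
    Exact equidistance breaks to 'left'.
    """
    d = np.array([[r.d_left_cm, r.d_right_cm] for r in nest_results], dtype=float)
    nearest = ["left" if dl <= dr else "right" for dl, dr in d]
    if len(nest_results) < 2 or np.allclose(d, d[0]):
        return nearest
    km = KMeans(n_clusters=2, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(d)
    if len(np.unique(labels)) < 2:
        return nearest
    centers = km.cluster_centers_
    # the cluster whose mean is closer to the left object is the left group
    side_of_cluster = {
        k: ("left" if centers[k, 0] <= centers[k, 1] else "right") for k in (0, 1)
    }
    if side_of_cluster[0] == side_of_cluster[1]:
        return nearest
    return [side_of_cluster[k] for k in labels]


def nest_bias_test(
    exploration_minutes: pd.DataFrame, side_groups: Sequence[str]
) -> pd.DataFrame:
    """Compare per-object exploration time between nest-side groups.

    ``exploration_minutes`` has one row per mouse with columns 'left' and
    'right' (minutes exploring each object).  For each object side, a
    two-sample t test contrasts nest-left vs nest-right mice; p-values are
    BH-adjusted across the two comparisons.  Empty groups are flagged.
    """
    groups = np.asarray(side_groups)
    rows = []
    for obj_side in ("left", "right"):
        a = exploration_minutes.loc[groups == "left", obj_side].to_numpy()
        b = exploration_minutes.loc[groups == "right", obj_side].to_numpy()
        if a.size == 0 or b.size == 0:
            res = stats.StatResult(float("nan"), float("nan"), flag="empty nest group")
        else:
            res = stats.two_sample_t(a, b)
        rows.append(
            {
                "object_side": obj_side,
                "mean_nest_left": float(a.mean()) if a.size else float("nan"),
                "mean_nest_right": float(b.mean()) if b.size else float("nan"),
                "t": res.statistic,
                "p": res.pvalue,
                "flag": res.flag,
            }
        )
    out = pd.DataFrame(rows)
    valid = out["p"].notna()
    adj = np.full(len(out), np.nan)
    if valid.any():
        adj[valid.to_numpy()] = stats.bh_adjust(out.loc[valid, "p"].to_numpy())
    out["p_bh"] = adj
    return out


@dataclass
class CorridorScore:
    """Per-interval same/opposite-side scores with the cohort summary."""

    scores: np.ndarray  # 0 = same side as exited corridor, 1 = opposite
    mean: float
    test_vs_half: stats.StatResult
    n_intervals_skipped: int


def corridor_scores(
    visits: Sequence[CorridorVisit],
    bouts: pd.DataFrame,
    schedule: PhaseSchedule | None = None,
    phases: Sequence[str] = ("sample", "retention"),
) -> CorridorScore:
    """Score which object is explored first after each corridor visit.

    For each interval between consecutive corridor visits (within the given
    phases), the first exploration bout starting in the interval scores 0 on
    the same side as the exited corridor and 1 on the opposite side;
    intervals without exploration are skipped.  The mean is tested against
    0.5 with a one-sample t test.
    """
    def in_phases(t: float) -> bool:
        if schedule is None:
            return True
        return any(
            schedule.phase(name).contains(t) for name in phases if schedule.has_phase(name)
        )

    starts = bouts["start_s"].to_numpy() if len(bouts) else np.empty(0)
    sides = bouts["side"].to_numpy() if len(bouts) else np.empty(0, dtype=object)
    scores = []
    skipped = 0
    usable = [v for v in visits if in_phases(v.end_s)]
    for v, nxt in zip(usable[:-1], usable[1:]):
        in_interval = (starts >= v.end_s) & (starts < nxt.start_s)
        idx = np.flatnonzero(in_interval)
        if idx.size == 0:
            skipped += 1
            continue
        first_side = sides[idx[0]]
        scores.append(0 if first_side == v.side else 1)
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        return CorridorScore(
            scores=arr,
            mean=float("nan"),
            test_vs_half=stats.StatResult(float("nan"), float("nan"), flag="no qualifying intervals"),
            n_intervals_skipped=skipped,
        )
    return CorridorScore(
        scores=arr,
        mean=float(arr.mean()),
        test_vs_half=stats.one_sample_t(arr, 0.5),
        n_intervals_skipped=skipped,
    )
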